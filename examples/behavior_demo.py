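"""Block-level performance measures from a serial reaction time task log.

A session is 16 blocks of 48 key presses.  Performance speed is the mean
response time over correct presses per block; accuracy is the percent of
correct presses.  Sequence (SEQ) practice follows an exponential learning
curve; random (RND) practice stays flat.
"""

from mvcs import block_performance, generate_behavior
from mvcs.behavior import fit_learning_curve
from mvcs.synthetic import BehaviorParams

params = BehaviorParams()  # A=350 ms, B=150 ms, lambda=0.35 per block
seq = generate_behavior("SEQ", 16, 48, params, seed=3)
rnd = generate_behavior("RND", 16, 48, params, seed=3)

perf_seq = block_performance(seq)
perf_rnd = block_performance(rnd)
print("block   SEQ mean RT   RND mean RT   SEQ accuracy")
for b in (1, 4, 8, 16):
    s = perf_seq[perf_seq["block"] == b].iloc[0]
    r = perf_rnd[perf_rnd["block"] == b].iloc[0]
    print(f"{b:5d}   {s.mean_rt_correct:8.1f} ms   {r.mean_rt_correct:8.1f} ms"
          f"   {s.accuracy:6.1f} %")

a, amp, lam = fit_learning_curve(perf_seq)
print(f"\nfitted SEQ learning curve: RT = {a:.0f} + {amp:.0f} "
      f"* exp(-{lam:.2f} * (block-1)) ms")
print(f"generator truth:           RT = {params.rt_baseline_ms:.0f} + "
      f"{params.rt_learning_ms:.0f} * exp(-{params.learning_rate:.2f} "
      "* (block-1)) ms")
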