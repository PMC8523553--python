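"""Sweep the pattern-persistence knob and watch the SI track it.

Two runs whose loading matrices share a fraction rho of their structure
(W_B = sqrt(rho) W_A + sqrt(1-rho) W_new) should yield a similarity
index that grows monotonically with rho: rho = 0 gives SI ~ 0
(independent structure), rho = 1 gives a near-perfect matrix correlation.
"""

import numpy as np

from mvcs import generate_roi_run
from mvcs.similarity import compute_mvcs, similarity_index
from mvcs.synthetic import mix_loadings, random_loadings

rng = np.random.default_rng(6)
print("rho    mean SI   (20 run pairs, 100 voxels, 150 volumes)")
for rho in (0.0, 0.25, 0.5, 0.75, 1.0):
    sis = []
    for _ in range(20):
        w_a = random_loadings(100, 5, rng)
        w_b = mix_loadings(w_a, rho, rng)
        a = generate_roi_run(100, 150, 2.0, w_a, rng=rng)
        b = generate_roi_run(100, 150, 2.0, w_b, rng=rng)
        sis.append(similarity_index(compute_mvcs(a), compute_mvcs(b)))
    print(f"{rho:.2f}   {np.mean(sis):+.3f}")
print("\nThe monotone increase is the core recovery property the")
print("similarity analysis relies on.")
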