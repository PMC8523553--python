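"""Serial reaction time task (SRTT) performance measures.

Performance speed and accuracy per practice block: the mean response
time over correct presses (ms) and the percentage of correct presses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.optimize

from .exceptions import ConfigError

__all__ = ["block_performance", "fit_learning_curve"]

_REQUIRED = ("block", "correct", "rt_ms")


def block_performance(
    log: pd.DataFrame, trim_sd: float | None = None
) -> pd.DataFrame:
    """Per-block speed and accuracy from a key-press log.

    Returns one row per block with ``mean_rt_correct`` (ms, NaN when the
    block has no correct press) and ``accuracy`` (percent).  No outlier
    trimming is applied by default; ``trim_sd`` optionally excludes
    correct presses beyond that many within-block SDs from the RT mean
    (accuracy is never affected).
    """
    for col in _REQUIRED:
        if col not in log.columns:
            raise ConfigError(f"key-press log is missing column {col!r}")
    if len(log) == 0:
        raise ConfigError("key-press log is empty")
    if (log["rt_ms"] <= 0).any():
        raise ConfigError("response times must be positive")
    rows = []
    for block, grp in log.groupby("block", sort=True):
        correct = grp[grp["correct"].astype(bool)]
        accuracy = 100.0 * len(correct) / len(grp)
        if len(correct) == 0:
            mean_rt = np.nan
        else:
            rt = correct["rt_ms"].to_numpy(dtype=float)
            if trim_sd is not None and len(rt) > 1 and rt.std(ddof=0) > 0:
                z = np.abs(rt - rt.mean()) / rt.std(ddof=0)
                rt = rt[z <= trim_sd]
            mean_rt = float(rt.mean()) if rt.size else np.nan
        rows.append((int(block), mean_rt, accuracy, len(correct)))
    return pd.DataFrame(
        rows, columns=["block", "mean_rt_correct", "accuracy", "n_correct"]
    )


def fit_learning_curve(
    perf: pd.DataFrame,
) -> tuple[float, float, float]:
    """Fit ``rt = A + B * exp(-lambda * (block - 1))`` to block means.

    Returns ``(A, B, lambda)``.  Intended for parameter-recovery checks
    on sequence-condition data; a flat (random) profile yields a small B.
    """
    d = perf.dropna(subset=["mean_rt_correct"])
    blocks = d["block"].to_numpy(dtype=float)
    rt = d["mean_rt_correct"].to_numpy(dtype=float)
    if blocks.size < 4:
        raise ConfigError("learning-curve fit needs at least 4 blocks")

    def model(b, a, amp, lam):
        return a + amp * np.exp(-lam * (b - 1))

    a0 = float(rt.min())
    amp0 = max(float(rt[0] - rt.min()), 1.0)
    popt, _ = scipy.optimize.curve_fit(
        model, blocks, rt, p0=(a0, amp0, 0.3),
        bounds=([0.0, 0.0, 1e-4], [np.inf, np.inf, 10.0]), maxfev=10000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
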