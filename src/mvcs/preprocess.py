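"""Pre-MVCS cleaning of ROI voxel time series.

The cleaning chain applied before any correlation-structure analysis is,
in order: detrend + discrete-cosine high-pass (cutoff 1/128 Hz), optional
down-sampling to the slower TR of a run pair, framewise-displacement
censoring (FD > 0.5 mm removes the offending volume and its successor),
gray-matter voxel selection (> 10% GM probability), nuisance regression
(six tissue principal components plus a 24-column motion expansion), and
volume-count matching around the middle of the longer run.

All thresholds are arguments with the conventional values as defaults.
Every operation preserves voxel order and keeps ``frame_index`` strictly
increasing, so matrices computed from different runs of the same ROI
remain comparable element-wise.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg

from .containers import FdTrace, MotionParams, NuisanceMatrix, RoiTimeSeries
from .exceptions import (
    ConfigError,
    PairUnusableError,
    RoiUnusableError,
    RunUnusableError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "detrend_highpass",
    "compute_fd",
    "censor_frames",
    "censor_mask",
    "resample_to_tr",
    "resample_motion",
    "build_motion_regressors",
    "extract_tissue_components",
    "regress_nuisance",
    "select_voxels_gm",
    "match_volumes",
]

#: Rotation-to-displacement conversion radius (mm) used in the framewise
#: displacement of Power et al.: arc length on a 50 mm sphere.
FD_ROTATION_RADIUS_MM = 50.0


def _dct_highpass_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine columns spanning frequencies strictly below cutoff.

    Mode ``k`` of the DCT-II basis over ``n`` samples at repetition time
    ``tr`` has frequency ``k / (2 n tr)``; the high-pass regressor set
    contains every mode with a period longer than ``1 / cutoff_hz``.
    """
    if cutoff_hz <= 0:
        raise ConfigError(f"cutoff_hz must be positive, got {cutoff_hz}")
    n_modes = int(np.floor(2.0 * n * tr * cutoff_hz))
    if n_modes >= n - 2:
        raise ConfigError(
            "high-pass cutoff would remove (nearly) the full signal space "
            f"({n_modes} modes for {n} volumes)"
        )
    t = np.arange(n)
    k = np.arange(1, n_modes + 1)
    if k.size == 0:
        return np.empty((n, 0))
    basis = np.cos(np.pi * np.outer(2 * t + 1, k) / (2.0 * n))
    return basis


def detrend_highpass(
    run: RoiTimeSeries, cutoff_hz: float = 1.0 / 128.0
) -> RoiTimeSeries:
    """Remove the mean, a linear trend, and all drift below ``cutoff_hz``.

    The drift space is the span of the discrete-cosine modes with periods
    longer than the cutoff period, plus an intercept and a linear ramp;
    the voxel-wise residual of a least-squares projection onto that space
    is returned.  As an orthogonal projection it can only reduce variance.
    """
    n = run.n_volumes
    if n < 8:
        raise ConfigError(f"detrending needs at least 8 volumes, got {n}")
    t = np.arange(n, dtype=float)
    ramp = (t - t.mean()) / max(t.max() - t.min(), 1.0)
    basis = _dct_highpass_basis(n, run.tr, cutoff_hz)
    X = np.column_stack([np.ones(n), ramp, basis])
    beta, *_ = np.linalg.lstsq(X, run.data, rcond=None)
    return run.with_data(run.data - X @ beta)


def compute_fd(motion: MotionParams) -> FdTrace:
    """Framewise displacement: Power-style backward-difference summary.

    ``FD[t] = sum |delta translations| + 50 mm * sum |delta rotations|``
    with ``FD[0] = 0``; rotations (radians) are converted to arc length
    on a 50 mm sphere.
    """
    if motion.n_volumes < 1:
        raise ConfigError("motion table must contain at least 1 volume")
    d = np.abs(np.diff(motion.values, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return FdTrace(np.concatenate([[0.0], fd]))


def censor_mask(fd: FdTrace, threshold_mm: float = 0.5) -> np.ndarray:
    """Boolean keep-mask implementing the scrubbing rule.

    A volume whose FD exceeds the threshold is removed together with the
    subsequent volume.
    """
    bad = fd.fd > threshold_mm
    drop = bad.copy()
    drop[1:] |= bad[:-1]
    return ~drop


def censor_frames(
    run: RoiTimeSeries, fd: FdTrace, threshold_mm: float = 0.5
) -> RoiTimeSeries:
    """Remove every volume with FD above threshold plus its successor."""
    if fd.fd.size != run.n_volumes:
        raise ConfigError(
            f"FD trace length {fd.fd.size} != run volume count {run.n_volumes}"
        )
    keep = censor_mask(fd, threshold_mm)
    if not keep.any():
        raise RunUnusableError("all volumes censored by the FD rule")
    return run.take_frames(np.flatnonzero(keep))


def _resample_columns(
    values: np.ndarray, tr: float, target_tr: float
) -> np.ndarray:
    n = values.shape[0]
    t_old = np.arange(n) * tr
    n_new = int(np.floor(t_old[-1] / target_tr)) + 1 if n > 1 else n
    t_new = np.arange(n_new) * target_tr
    out = np.empty((n_new, values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.interp(t_new, t_old, values[:, j])
    return out


def resample_to_tr(run: RoiTimeSeries, target_tr: float) -> RoiTimeSeries:
    """Linearly interpolate onto a slower TR grid (no upsampling).

    Down-sampling precedes censoring, so the input must still be on its
    full acquisition grid.  Block annotations are in seconds and carry
    over unchanged; the frame index is reset to the new grid.
    """
    if target_tr < run.tr:
        raise ConfigError(
            f"target TR {target_tr} s is faster than the run TR {run.tr} s; "
            "only down-sampling is supported"
        )
    if not np.array_equal(run.frame_index, np.arange(run.n_volumes)):
        raise ConfigError("resampling must be applied before censoring")
    if target_tr == run.tr:
        return run.with_data(run.data.copy())
    data = _resample_columns(run.data, run.tr, target_tr)
    return run.with_data(
        data, tr=target_tr, frame_index=np.arange(data.shape[0])
    )


def resample_motion(
    motion: MotionParams, tr: float, target_tr: float
) -> MotionParams:
    """Down-sample a motion table with the same operator as the data."""
    if target_tr < tr:
        raise ConfigError("only down-sampling is supported")
    if target_tr == tr:
        return MotionParams(motion.values.copy())
    return MotionParams(_resample_columns(motion.values, tr, target_tr))


def build_motion_regressors(motion: MotionParams) -> NuisanceMatrix:
    """Volterra-style 24-column motion expansion.

    Columns: the six realignment parameters, their squares, their
    backward-difference derivatives (zero first row), and the squared
    derivatives.
    """
    p = motion.values
    dp = np.vstack([np.zeros((1, 6)), np.diff(p, axis=0)])
    values = np.hstack([p, p**2, dp, dp**2])
    base = list(
        ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
    )
    labels = (
        [f"mot_{b}" for b in base]
        + [f"mot_{b}_sq" for b in base]
        + [f"mot_{b}_d" for b in base]
        + [f"mot_{b}_d_sq" for b in base]
    )
    return NuisanceMatrix(values, labels)


def _principal_components(pool: np.ndarray, k: int, prefix: str) -> NuisanceMatrix:
    x = pool - pool.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    k_eff = min(k, rank)
    if k_eff < k:
        logger.warning(
            "%s pool has rank %d < %d requested components; returning %d",
            prefix, rank, k, k_eff,
        )
    comps = u[:, :k_eff].copy()
    for j in range(k_eff):
        # sign convention: the largest-magnitude loading is positive
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            comps[:, j] = -comps[:, j]
    labels = [f"{prefix}_pc{j + 1}" for j in range(k_eff)]
    return NuisanceMatrix(comps, labels)


def extract_tissue_components(
    wm_pool: np.ndarray, csf_pool: np.ndarray, k: int = 3
) -> NuisanceMatrix:
    """First ``k`` principal-component time courses per tissue pool.

    Pools are column-demeaned; unit-norm component time courses are
    returned with a deterministic sign (largest-magnitude loading
    positive), WM components first.  A rank-deficient pool yields the
    available components with a logged warning.
    """
    wm_pool = np.asarray(wm_pool, dtype=float)
    csf_pool = np.asarray(csf_pool, dtype=float)
    if wm_pool.shape[0] != csf_pool.shape[0]:
        raise ConfigError("WM and CSF pools must cover the same volumes")
    for name, pool in (("WM", wm_pool), ("CSF", csf_pool)):
        if pool.ndim != 2 or pool.shape[1] < 1:
            raise ConfigError(f"{name} pool must be a time-by-signal matrix")
    return NuisanceMatrix.hstack(
        [
            _principal_components(wm_pool, k, "wm"),
            _principal_components(csf_pool, k, "csf"),
        ]
    )


def regress_nuisance(
    run: RoiTimeSeries, nuis: NuisanceMatrix
) -> RoiTimeSeries:
    """Voxel-wise least-squares residual on [intercept | nuisance].

    Regressor rows must already be censored with the run's frame mask.
    Collinear columns are detected with a pivoted QR on the unit-scaled
    matrix and dropped (logged); residuals are numerically orthogonal to
    every retained regressor.
    """
    n = run.n_volumes
    if nuis.n_regressors and nuis.values.shape[0] != n:
        raise ConfigError(
            f"nuisance rows ({nuis.values.shape[0]}) != run volumes ({n})"
        )
    if nuis.n_regressors == 0:
        return run.with_data(run.data - run.data.mean(axis=0, keepdims=True))
    cols = nuis.values - nuis.values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(cols, axis=0)
    keep = norms > 1e-12 * max(norms.max(), 1.0)
    scaled = np.zeros_like(cols)
    scaled[:, keep] = cols[:, keep] / norms[keep]
    # rank detection on the scaled columns
    q, r, piv = scipy.linalg.qr(scaled[:, keep], mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * max(scaled.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    kept_idx = np.flatnonzero(keep)[np.sort(piv[:rank])]
    dropped = [
        nuis.labels[j] for j in range(nuis.n_regressors) if j not in set(kept_idx)
    ]
    if dropped:
        logger.warning("dropping collinear nuisance columns: %s", dropped)
    X = np.column_stack([np.ones(n), scaled[:, kept_idx]])
    beta, *_ = np.linalg.lstsq(X, run.data, rcond=None)
    return run.with_data(run.data - X @ beta)


def select_voxels_gm(
    run: RoiTimeSeries, gm_prob: np.ndarray, threshold: float = 0.10
) -> RoiTimeSeries:
    """Keep voxels with GM probability strictly above the threshold."""
    gm_prob = np.asarray(gm_prob, dtype=float)
    if gm_prob.shape != (run.n_voxels,):
        raise ConfigError(
            f"gm_prob length {gm_prob.size} != voxel count {run.n_voxels}"
        )
    keep = np.flatnonzero(gm_prob > threshold)
    if keep.size == 0:
        raise RoiUnusableError(
            f"no voxel exceeds the GM probability threshold {threshold}"
        )
    return run.take_voxels(keep)


def match_volumes(
    a: RoiTimeSeries,
    b: RoiTimeSeries,
    min_volumes: int = 30,
) -> tuple[RoiTimeSeries, RoiTimeSeries]:
    """Cut the longer run to the shorter run's volume count.

    With ``x`` the smaller retained-volume count, the longer run keeps
    the ``x`` consecutive retained volumes starting at position
    ``floor((N - x) / 2)`` — the window around its middle volume.  Both
    runs must already be censored and on a common TR.
    """
    if a.tr != b.tr:
        raise ConfigError(
            f"runs must share a TR before volume matching ({a.tr} vs {b.tr})"
        )
    x = min(a.n_volumes, b.n_volumes)
    if x < min_volumes:
        raise PairUnusableError(
            f"only {x} matched volumes; fewer than the minimum {min_volumes}"
        )

    def _cut(run: RoiTimeSeries) -> RoiTimeSeries:
        n = run.n_volumes
        if n == x:
            return run
        start = (n - x) // 2
        return run.take_frames(np.arange(start, start + x))

    return _cut(a), _cut(b)
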