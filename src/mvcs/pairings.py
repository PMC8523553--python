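"""Run-pair assembly: from raw run bundles to similarity records.

For each subject x condition x ROI, similarity indices are computed for
three run pairings: (1) early vs. late task practice, (2) pre- vs.
post-task rest, and (3) the entire task run vs. post-task rest.  The
cleaning chain is applied per pairing because the down-sampling step
depends on the pair: whenever a pairing mixes TRs, the faster run is
down-sampled to the slower (task) TR before censoring.

Pipeline order per run: detrend/high-pass -> resample (if the pair mixes
TRs) -> FD censoring -> GM voxel selection -> nuisance regression (with
frame-matched regressors) -> early/late split where applicable -> volume
matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import NuisanceMatrix, RoiTimeSeries
from .exceptions import MvcsError, RunUnusableError
from .preprocess import (
    build_motion_regressors,
    censor_mask,
    compute_fd,
    detrend_highpass,
    extract_tissue_components,
    match_volumes,
    regress_nuisance,
    resample_motion,
    resample_to_tr,
    select_voxels_gm,
)
from .similarity import compute_mvcs, similarity_index, split_early_late
from .synthetic import PAIRINGS, RunBundle

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessSettings",
    "SimilarityRecord",
    "RunUsage",
    "PairingExclusion",
    "prepare_run",
    "assemble_pairings",
]


@dataclass(frozen=True)
class PreprocessSettings:
    """Thresholds of the cleaning chain (defaults as conventionally used)."""

    fd_threshold_mm: float = 0.5
    highpass_hz: float = 1.0 / 128.0
    gm_threshold: float = 0.10
    n_tissue_pcs: int = 3
    min_volumes: int = 30
    #: include the interleaved rest blocks of the task run in its MVCS
    include_task_rest_blocks: bool = True


@dataclass(frozen=True)
class SimilarityRecord:
    """One similarity index keyed by subject, condition, ROI, and pairing."""

    subject: str
    condition: str
    visit: int
    stimulation: str
    task: str
    roi: str
    pairing: str
    si: float
    n_voxels: int
    n_volumes: int


@dataclass(frozen=True)
class PairingExclusion:
    subject: str
    condition: str
    roi: str
    pairing: str
    reason: str


@dataclass(frozen=True)
class RunUsage:
    """Volume accounting for one run role within one pairing.

    ``n_input`` counts the volumes on the analysis grid (after any
    down-sampling); the identity ``n_input = n_used + n_censored +
    n_trimmed`` holds exactly.
    """

    subject: str
    condition: str
    roi: str
    pairing: str
    role: str
    n_input: int
    n_censored: int
    n_trimmed: int
    n_used: int


@dataclass
class PreparedRun:
    ts: RoiTimeSeries
    n_input: int
    n_censored: int


def prepare_run(
    bundle: RunBundle,
    roi: str,
    gm_prob: np.ndarray,
    settings: PreprocessSettings,
    target_tr: float | None = None,
) -> PreparedRun:
    """Clean one run's ROI time series up to (not including) matching."""
    ts = detrend_highpass(bundle.roi_ts[roi], settings.highpass_hz)
    motion = bundle.motion
    wm, csf = bundle.wm_pool, bundle.csf_pool
    if target_tr is not None and target_tr > ts.tr:
        src_tr = ts.tr
        ts = resample_to_tr(ts, target_tr)
        motion = resample_motion(motion, src_tr, target_tr)
        wm = _resample_pool(wm, src_tr, target_tr)
        csf = _resample_pool(csf, src_tr, target_tr)
    fd = compute_fd(motion)
    keep = censor_mask(fd, settings.fd_threshold_mm)
    n_input = ts.n_volumes
    rows = np.flatnonzero(keep)
    if rows.size == 0:
        raise RunUnusableError("all volumes censored by the FD rule")
    ts = ts.take_frames(rows)
    ts = select_voxels_gm(ts, gm_prob, settings.gm_threshold)
    tissue = extract_tissue_components(
        wm[rows], csf[rows], settings.n_tissue_pcs
    )
    motion_regs = build_motion_regressors(motion).take_rows(rows)
    nuis = NuisanceMatrix.hstack([tissue, motion_regs])
    ts = regress_nuisance(ts, nuis)
    return PreparedRun(ts, n_input=n_input, n_censored=n_input - rows.size)


def _resample_pool(pool: np.ndarray, tr: float, target_tr: float) -> np.ndarray:
    from .preprocess import _resample_columns

    if target_tr == tr:
        return pool
    return _resample_columns(pool, tr, target_tr)


@dataclass
class PairingResult:
    records: list[SimilarityRecord] = field(default_factory=list)
    exclusions: list[PairingExclusion] = field(default_factory=list)
    usage: list[RunUsage] = field(default_factory=list)


def _pair_si(
    a: RoiTimeSeries, b: RoiTimeSeries, roi: str, settings: PreprocessSettings
) -> tuple[float, int, int, int, int]:
    """Match volumes and compute the SI; returns (si, n_vox, n_vol, trim_a, trim_b)."""
    na, nb = a.n_volumes, b.n_volumes
    am, bm = match_volumes(a, b, settings.min_volumes)
    si = similarity_index(
        compute_mvcs(am, roi=roi), compute_mvcs(bm, roi=roi)
    )
    return si, am.n_voxels, am.n_volumes, na - am.n_volumes, nb - bm.n_volumes


def assemble_pairings(
    pre: RunBundle | None,
    task: RunBundle | None,
    post: RunBundle | None,
    *,
    roi: str,
    gm_prob: np.ndarray,
    meta: dict,
    settings: PreprocessSettings | None = None,
    pairings: tuple[str, ...] = PAIRINGS,
) -> PairingResult:
    """Compute the available similarity records for one session and ROI.

    Missing runs yield missing records, not failures; any unusable pair
    is omitted with a logged reason.  ``meta`` must carry ``subject``,
    ``condition``, ``visit``, ``stimulation`` and ``task``.
    """
    settings = settings or PreprocessSettings()
    out = PairingResult()
    key = dict(
        subject=meta["subject"], condition=meta["condition"], roi=roi
    )

    def _exclude(pairing: str, reason: str) -> None:
        logger.info(
            "omitting %s for %s/%s/%s: %s",
            pairing, key["subject"], key["condition"], roi, reason,
        )
        out.exclusions.append(PairingExclusion(**key, pairing=pairing,
                                               reason=reason))

    def _record(pairing: str, si: float, n_vox: int, n_vol: int) -> None:
        out.records.append(
            SimilarityRecord(
                subject=meta["subject"], condition=meta["condition"],
                visit=int(meta["visit"]), stimulation=meta["stimulation"],
                task=meta["task"], roi=roi, pairing=pairing, si=si,
                n_voxels=n_vox, n_volumes=n_vol,
            )
        )

    task_tr = task.roi_ts[roi].tr if task is not None else None

    if "early_late" in pairings:
        if task is None:
            _exclude("early_late", "task run missing")
        else:
            try:
                prep = prepare_run(task, roi, gm_prob, settings)
                early, late = split_early_late(prep.ts)
                si, n_vox, n_vol, trim_e, trim_l = _pair_si(
                    early, late, roi, settings
                )
                _record("early_late", si, n_vox, n_vol)
                out.usage.append(RunUsage(
                    **key, pairing="early_late", role="task",
                    n_input=prep.n_input, n_censored=prep.n_censored,
                    n_trimmed=trim_e + trim_l, n_used=2 * n_vol,
                ))
            except MvcsError as exc:
                _exclude("early_late", str(exc))

    if "rs_pre_post" in pairings:
        if pre is None or post is None:
            _exclude("rs_pre_post", "pre or post rest run missing")
        else:
            try:
                prep_a = prepare_run(pre, roi, gm_prob, settings)
                prep_b = prepare_run(post, roi, gm_prob, settings)
                si, n_vox, n_vol, trim_a, trim_b = _pair_si(
                    prep_a.ts, prep_b.ts, roi, settings
                )
                _record("rs_pre_post", si, n_vox, n_vol)
                for prep, trim, role in (
                    (prep_a, trim_a, "pre_rs"), (prep_b, trim_b, "post_rs")
                ):
                    out.usage.append(RunUsage(
                        **key, pairing="rs_pre_post", role=role,
                        n_input=prep.n_input, n_censored=prep.n_censored,
                        n_trimmed=trim, n_used=n_vol,
                    ))
            except MvcsError as exc:
                _exclude("rs_pre_post", str(exc))

    if "task_rs_post" in pairings:
        if task is None or post is None:
            _exclude("task_rs_post", "task or post rest run missing")
        else:
            try:
                prep_t = prepare_run(task, roi, gm_prob, settings)
                ts_t = prep_t.ts
                if not settings.include_task_rest_blocks:
                    ts_t = _practice_only(ts_t)
                prep_r = prepare_run(
                    post, roi, gm_prob, settings, target_tr=task_tr
                )
                si, n_vox, n_vol, trim_t, trim_r = _pair_si(
                    ts_t, prep_r.ts, roi, settings
                )
                _record("task_rs_post", si, n_vox, n_vol)
                skipped = prep_t.ts.n_volumes - ts_t.n_volumes
                out.usage.append(RunUsage(
                    **key, pairing="task_rs_post", role="task",
                    n_input=prep_t.n_input, n_censored=prep_t.n_censored,
                    n_trimmed=trim_t + skipped, n_used=n_vol,
                ))
                out.usage.append(RunUsage(
                    **key, pairing="task_rs_post", role="post_rs",
                    n_input=prep_r.n_input, n_censored=prep_r.n_censored,
                    n_trimmed=trim_r, n_used=n_vol,
                ))
            except MvcsError as exc:
                _exclude("task_rs_post", str(exc))

    return out


def _practice_only(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Drop frames falling in rest blocks (config switch, off by default)."""
    spans = ts.block_annotations or ()
    times = ts.times
    keep = np.zeros(ts.n_volumes, dtype=bool)
    for s in spans:
        if s.label == "practice":
            keep |= (times >= s.start_s) & (times < s.end_s)
    return ts.take_frames(np.flatnonzero(keep))
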