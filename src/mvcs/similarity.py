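"""MVCS matrices and the pattern-similarity index (SI).

The multivoxel correlation structure of one run's ROI is the n-by-n
matrix of pairwise Pearson correlations between the n voxel time
courses, Fisher z-transformed entry-wise.  The similarity index between
two runs is the r-to-z transformed Pearson correlation between their two
MVCS matrices, computed over the strict upper triangle (the diagonal is
meaningless after the z transform and the matrix is symmetric, so the
triangle carries all the information).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import RoiTimeSeries
from .exceptions import (
    ConfigError,
    DegenerateCorrelationError,
    DegenerateSimilarityError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_z",
    "MvcsMatrix",
    "compute_mvcs",
    "similarity_index",
    "split_early_late",
]

#: Degenerate voxel-pair correlations (|r| >= 1) are clipped to this
#: magnitude before the z transform so that a single tied pair does not
#: force the voxels out of the analysis.
DEGENERATE_CLIP = 1.0 - 1e-7


def fisher_z(r: float) -> float:
    """Fisher r-to-z transform, ``arctanh(r)``; requires ``|r| < 1``."""
    r = float(r)
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise DegenerateCorrelationError(
            f"correlation r={r} is degenerate; Fisher z is undefined"
        )
    return float(np.arctanh(r))


@dataclass
class MvcsMatrix:
    """Fisher-z voxel-by-voxel correlation structure of one run's ROI.

    The diagonal is stored as 0 and excluded from all downstream use.
    """

    z: np.ndarray
    voxel_ids: np.ndarray
    roi: str = ""
    run: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape != (n, n):
            raise ConfigError("z must be a square matrix")
        if n < 3:
            raise ConfigError("an MVCS matrix needs at least 3 voxels")
        if self.voxel_ids.shape != (n,):
            raise ConfigError("voxel_ids length must match the matrix size")
        if not np.allclose(self.z, self.z.T, atol=1e-12, rtol=0.0):
            raise ConfigError("z must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ConfigError("z must be finite off the diagonal")

    @property
    def n(self) -> int:
        return self.z.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """The strict upper triangle as a flat vector (row-major)."""
        iu = np.triu_indices(self.n, k=1)
        return self.z[iu]


def compute_mvcs(
    run: RoiTimeSeries, roi: str = "", run_label: str = ""
) -> MvcsMatrix:
    """Pairwise Pearson correlations between voxel time courses, Fisher z.

    Zero-variance voxels are removed (logged) before the correlation;
    degenerate voxel pairs (|r| >= 1 between distinct voxels) are clipped
    to +/- (1 - 1e-7) with a warning so the SI stays finite.
    """
    if run.n_volumes < 3:
        raise ConfigError("MVCS needs at least 3 volumes")
    sd = run.data.std(axis=0)
    live = sd > 0
    if not live.all():
        dropped = run.voxel_ids[~live].tolist()
        logger.warning(
            "removing %d zero-variance voxel(s) before MVCS: %s",
            len(dropped), dropped,
        )
        run = run.take_voxels(np.flatnonzero(live))
    if run.n_voxels < 3:
        raise ConfigError("MVCS needs at least 3 voxels with variance")
    r = np.corrcoef(run.data, rowvar=False)
    np.fill_diagonal(r, 0.0)
    clipped = np.abs(r) >= DEGENERATE_CLIP
    if clipped.any():
        logger.warning(
            "clipping %d degenerate voxel-pair correlation(s) to |r|=%g",
            int(clipped.sum()) // 2, DEGENERATE_CLIP,
        )
        r = np.clip(r, -DEGENERATE_CLIP, DEGENERATE_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return MvcsMatrix(z, run.voxel_ids, roi=roi, run=run_label)


def similarity_index(a: MvcsMatrix, b: MvcsMatrix) -> float:
    """SI: r-to-z transformed correlation between two MVCS matrices.

    Both matrices must cover the same voxels in the same order.  The
    Pearson correlation is taken over the vectorized strict upper
    triangles; ``|r| = 1`` (e.g. a matrix with itself) is degenerate and
    raises rather than returning infinity.
    """
    if a.n != b.n or not np.array_equal(a.voxel_ids, b.voxel_ids):
        raise ConfigError("MVCS matrices must share voxel identity and order")
    ua, ub = a.upper_triangle(), b.upper_triangle()
    da = ua - ua.mean()
    db = ub - ub.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0:
        raise DegenerateSimilarityError("constant MVCS triangle; SI undefined")
    r = float((da @ db) / denom)
    if abs(r) >= 1.0:
        raise DegenerateSimilarityError(
            f"MVCS matrices are perfectly correlated (r={r}); SI undefined"
        )
    return float(np.arctanh(r))


def split_early_late(
    task_run: RoiTimeSeries,
) -> tuple[RoiTimeSeries, RoiTimeSeries]:
    """Split a task run into early and late halves of practice.

    The run must carry block annotations for an even number of practice
    blocks; the split point is the boundary between the rest period that
    follows the first half's last block and the next block's onset.
    Retained frames (post-censoring) are assigned by acquisition time, so
    the two halves always partition the run's volumes in order.
    """
    spans = task_run.block_annotations
    if not spans:
        raise ConfigError("task run has no block annotations")
    blocks = sorted({s.block for s in spans})
    n_blocks = len(blocks)
    if n_blocks < 2 or n_blocks % 2 != 0:
        raise ConfigError(
            f"early/late split needs an even block count, got {n_blocks}"
        )
    practice_blocks = {s.block for s in spans if s.label == "practice"}
    if practice_blocks != set(blocks):
        raise ConfigError("every block must have a practice span")
    half = blocks[n_blocks // 2 - 1]
    boundary_s = max(s.end_s for s in spans if s.block <= half)
    times = task_run.times
    early_rows = np.flatnonzero(times < boundary_s)
    late_rows = np.flatnonzero(times >= boundary_s)
    if early_rows.size == 0 or late_rows.size == 0:
        raise ConfigError("early/late split produced an empty half")
    early = task_run.take_frames(early_rows)
    late = task_run.take_frames(late_rows)
    early.block_annotations = tuple(s for s in spans if s.block <= half)
    late.block_annotations = tuple(s for s in spans if s.block > half)
    return early, late
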