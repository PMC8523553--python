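"""Core in-memory containers for ROI fMRI runs and their ancillary data.

The unit that every preprocessing stage maps to itself is
:class:`RoiTimeSeries`: a time-by-voxel matrix together with its TR, the
original volume indices of the retained frames (so censoring never loses
track of acquisition time), stable voxel identifiers (so matrices from
different runs of the same ROI stay comparable element-wise), and, for
task runs, practice/rest block annotations expressed in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ConfigError

__all__ = [
    "BlockSpan",
    "RoiTimeSeries",
    "MotionParams",
    "FdTrace",
    "NuisanceMatrix",
    "MOTION_COLUMNS",
]

#: Fixed column order of realignment-parameter tables:
#: three translations in mm, three rotations in radians.
MOTION_COLUMNS = (
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_rad",
    "rot_y_rad",
    "rot_z_rad",
)


@dataclass(frozen=True)
class BlockSpan:
    """One practice or rest interval of a task run, in run time (seconds)."""

    label: str  # "practice" | "rest"
    block: int  # 1-based practice-block number the span belongs to
    start_s: float
    end_s: float


@dataclass
class RoiTimeSeries:
    """Time-by-voxel matrix for one ROI in one run.

    Attributes
    ----------
    data:
        ``(n_volumes, n_voxels)`` float array.
    tr:
        Repetition time of the *current* sampling grid, seconds.
    frame_index:
        Original (grid) volume index of each retained row, strictly
        increasing.  ``frame_index * tr`` gives the acquisition time of
        each retained frame.
    voxel_ids:
        Stable per-voxel labels, unique within the ROI.
    block_annotations:
        Optional practice/rest spans (seconds); TR-independent so they
        survive resampling.
    """

    data: np.ndarray
    tr: float
    frame_index: np.ndarray = None  # type: ignore[assignment]
    voxel_ids: np.ndarray = None  # type: ignore[assignment]
    block_annotations: tuple[BlockSpan, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError("data must be a 2-D (volumes x voxels) array")
        if not self.tr > 0:
            raise ConfigError(f"tr must be positive, got {self.tr}")
        if self.frame_index is None:
            self.frame_index = np.arange(self.data.shape[0])
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.frame_index.shape != (self.data.shape[0],):
            raise ConfigError(
                "frame_index length must equal the number of volumes"
            )
        if self.frame_index.size > 1 and np.any(np.diff(self.frame_index) <= 0):
            raise ConfigError("frame_index must be strictly increasing")
        if self.voxel_ids is None:
            self.voxel_ids = np.array(
                [f"v{i:04d}" for i in range(self.data.shape[1])]
            )
        self.voxel_ids = np.asarray(self.voxel_ids)
        if self.voxel_ids.shape != (self.data.shape[1],):
            raise ConfigError("voxel_ids length must equal the voxel count")
        if len(set(self.voxel_ids.tolist())) != self.voxel_ids.size:
            raise ConfigError("voxel_ids must be unique")
        if self.block_annotations is not None:
            self.block_annotations = tuple(self.block_annotations)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time (s) of each retained frame."""
        return self.frame_index * self.tr

    def with_data(self, data: np.ndarray, **updates) -> "RoiTimeSeries":
        """Copy with replaced data (and optionally other fields)."""
        return replace(self, data=np.asarray(data, dtype=float), **updates)

    def take_frames(self, rows: np.ndarray) -> "RoiTimeSeries":
        """Subset of frames by positional row index (order preserved)."""
        rows = np.asarray(rows)
        return replace(
            self, data=self.data[rows], frame_index=self.frame_index[rows]
        )

    def take_voxels(self, cols: np.ndarray) -> "RoiTimeSeries":
        """Subset of voxels by positional column index (order preserved)."""
        cols = np.asarray(cols)
        return replace(
            self, data=self.data[:, cols], voxel_ids=self.voxel_ids[cols]
        )


@dataclass
class MotionParams:
    """Per-volume rigid-body realignment parameters.

    Six columns in the order of :data:`MOTION_COLUMNS`: translations in
    mm, rotations in radians.  One row per acquired volume.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ConfigError(
                "motion parameters must have 6 columns "
                f"(got shape {self.values.shape})"
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]


@dataclass
class FdTrace:
    """Per-volume framewise displacement (mm) and the censoring threshold."""

    fd: np.ndarray
    threshold_mm: float = 0.5

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1:
            raise ConfigError("fd must be a 1-D array")
        if self.fd.size and self.fd[0] != 0:
            raise ConfigError("FD of the first volume must be 0")
        if np.any(self.fd < 0):
            raise ConfigError("FD values must be non-negative")


@dataclass
class NuisanceMatrix:
    """Time-by-regressor nuisance matrix with column labels."""

    values: np.ndarray
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("nuisance matrix must be 2-D")
        self.labels = list(self.labels)
        if not self.labels:
            self.labels = [f"reg{i:02d}" for i in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ConfigError("labels length must equal the column count")

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]

    def take_rows(self, rows: np.ndarray) -> "NuisanceMatrix":
        return NuisanceMatrix(self.values[np.asarray(rows)], self.labels)

    @staticmethod
    def hstack(parts: Sequence["NuisanceMatrix"]) -> "NuisanceMatrix":
        parts = [p for p in parts if p.n_regressors > 0]
        if not parts:
            return NuisanceMatrix(np.empty((0, 0)), [])
        values = np.hstack([p.values for p in parts])
        labels = [lab for p in parts for lab in p.labels]
        return NuisanceMatrix(values, labels)
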