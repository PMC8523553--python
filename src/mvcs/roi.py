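"""ROI mask utilities: spherical ROIs and the anterior/posterior split.

Masks are pure voxel sets on an integer grid with a physical spacing;
the second grid axis is the anterior–posterior (coronal) axis, with
anterior in the direction of increasing index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError

__all__ = ["RoiMask", "build_sphere_roi", "split_mask_coronal"]


@dataclass
class RoiMask:
    """Voxel-set ROI: integer grid coordinates plus grid spacing (mm)."""

    coords: np.ndarray  # (n_voxels, 3) integer grid indices
    spacing: np.ndarray  # (3,) mm per grid step

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ConfigError("mask coordinates must be an (n, 3) array")
        if self.coords.shape[0] == 0:
            raise ConfigError("mask must contain at least one voxel")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ConfigError("spacing must be three positive values (mm)")
        if len({tuple(c) for c in self.coords.tolist()}) != len(self.coords):
            raise ConfigError("mask coordinates must be unique")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def centers_mm(self) -> np.ndarray:
        """Physical voxel-center coordinates (mm)."""
        return self.coords * self.spacing


def build_sphere_roi(
    center_mm: np.ndarray,
    radius_mm: float = 10.0,
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> RoiMask:
    """All voxels whose center lies within ``radius_mm`` of ``center_mm``.

    The inclusion test is Euclidean and inclusive (<=).  A 10 mm sphere
    on an isotropic 2 mm grid centered on a voxel center contains 515
    voxels.
    """
    if radius_mm <= 0:
        raise ConfigError(f"radius must be positive, got {radius_mm}")
    center_mm = np.asarray(center_mm, dtype=float)
    spacing_arr = np.asarray(spacing, dtype=float)
    lo = np.floor((center_mm - radius_mm) / spacing_arr).astype(int)
    hi = np.ceil((center_mm + radius_mm) / spacing_arr).astype(int)
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = np.sum((grid * spacing_arr - center_mm) ** 2, axis=1)
    inside = grid[d2 <= radius_mm**2 + 1e-9]
    if inside.shape[0] == 0:
        raise ConfigError(
            "sphere contains no voxel center; radius smaller than the grid "
            "allows at this off-grid center"
        )
    return RoiMask(inside, spacing_arr)


def split_mask_coronal(mask: RoiMask) -> tuple[RoiMask, RoiMask]:
    """Split a mask at the middle slice of its coronal extension.

    With occupied coronal slices spanning ``[y_min, y_max]`` the middle
    slice is ``m = floor((y_min + y_max) / 2)``; voxels with ``y > m``
    form the anterior half, voxels with ``y <= m`` the posterior half.
    The two halves partition the input.
    """
    y = mask.coords[:, 1]
    y_min, y_max = int(y.min()), int(y.max())
    if y_max == y_min:
        raise ConfigError("mask spans a single coronal slice; cannot split")
    m = (y_min + y_max) // 2
    anterior = mask.coords[y > m]
    posterior = mask.coords[y <= m]
    return RoiMask(anterior, mask.spacing), RoiMask(posterior, mask.spacing)
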