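"""In-memory CT volume container.

A :class:`VolumeGrid` holds an axial stack of CT slices in Hounsfield units
together with its voxel spacing and physical origin.  Conventions used
throughout the package:

* array axes are ``(z, y, x)`` — axial slices stacked along ``z``;
* voxel indexing is 0-based and physical coordinates are voxel-center based,
  in millimetres;
* world in-plane axes: ``x`` increases with column index, ``y`` with row
  index; the phantom axis is nominally at world ``(x, y) = (0, 0)``;
* HU values are clipped to the representable CT range [−1024, 3071].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0
AIR_HU = -1000.0


@dataclass
class VolumeGrid:
    """3D HU image with uniform voxel spacing.

    Parameters
    ----------
    values
        ``(nz, ny, nx)`` array of HU values.
    spacing
        ``(dz, dy, dx)`` voxel spacing in mm.
    origin
        World coordinates ``(z0, y0, x0)`` in mm of the center of voxel
        ``[0, 0, 0]``.
    meta
        Free-form metadata (simulation parameters, material palette,
        warnings, acquisition annotations).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise ValueError("empty volume")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def clip_hu(self) -> None:
        np.clip(self.values, HU_MIN, HU_MAX, out=self.values)

    # ---- coordinate helpers -------------------------------------------------

    def z_coords(self) -> np.ndarray:
        """World z coordinate of every slice center (mm)."""
        nz = self.shape[0]
        return self.origin[0] + self.spacing[0] * np.arange(nz)

    def y_coords(self) -> np.ndarray:
        ny = self.shape[1]
        return self.origin[1] + self.spacing[1] * np.arange(ny)

    def x_coords(self) -> np.ndarray:
        nx = self.shape[2]
        return self.origin[2] + self.spacing[2] * np.arange(nx)

    def world_to_index(self, point_zyx: tuple[float, float, float]) -> tuple[float, float, float]:
        """Continuous voxel index of a world point (mm)."""
        return tuple(
            (p - o) / s for p, o, s in zip(point_zyx, self.origin, self.spacing)
        )  # type: ignore[return-value]

    def slice_index_near(self, z_mm: float) -> int:
        """Index of the slice whose center is closest to ``z_mm``."""
        idx = int(round((z_mm - self.origin[0]) / self.spacing[0]))
        return min(max(idx, 0), self.shape[0] - 1)

    def slice_indices_within(self, z_mm: float, thickness_mm: float) -> np.ndarray:
        """Indices of slices whose centers fall in ``z_mm ± thickness/2``."""
        z = self.z_coords()
        sel = np.nonzero(np.abs(z - z_mm) <= thickness_mm / 2.0 + 1e-9)[0]
        if sel.size == 0:
            sel = np.array([self.slice_index_near(z_mm)])
        return sel

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(
            self.values.copy(),
            self.spacing,
            self.origin,
            dict(self.meta),
        )
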