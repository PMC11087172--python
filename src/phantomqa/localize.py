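"""Phantom localization: find landmarks, estimate the rigid pose, map ROIs.

The analyzer never assumes the phantom is perfectly centered.  The pose is
estimated from the image itself — the in-plane center from the centroid of the
non-air mask, the rotation from the ball-bearing axis, the longitudinal offset
from the extent of the phantom along z — and every nominal ROI is mapped
through that pose before any statistic is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable

import numpy as np
from scipy import ndimage

from .volume import VolumeGrid

#: HU above which a voxel is considered metal (ball bearings).  Chosen well
#: above every non-metal feature in the phantom — including the bone-
#: equivalent resolution bars near +910 HU — and well below the ~2500 HU the
#: bearings render at, so neither noise nor blur moves anything across it.
METAL_THRESHOLD_HU = 1600.0
#: HU above which a voxel is considered phantom material (non-air).
BODY_THRESHOLD_HU = -300.0


class LocalizationError(RuntimeError):
    """Raised when a landmark or the phantom itself cannot be located."""


@dataclass(frozen=True)
class RoiSpec:
    """A circular region of interest on an axial plane.

    ``center`` is the in-plane world position (x, y) in mm; ``z`` selects the
    axial position, averaged over ``z_thickness`` mm of slices.
    """

    label: str
    center: tuple[float, float]
    diameter: float
    z: float
    z_thickness: float = 9.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"ROI {self.label!r}: diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def area(self) -> float:
        return math.pi * self.radius**2


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid pose of the phantom plus a longitudinal offset.

    Applying the transform maps phantom-frame coordinates into image (world)
    coordinates: ``p_img = R(rotation) @ p_phantom + translation``,
    ``z_img = z_phantom + z_offset``.
    """

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    z_offset: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        r = self.rotation_deg
        if not -180.0 < r <= 180.0:
            r = (r + 180.0) % 360.0 - 180.0
            if r == -180.0:
                r = 180.0
            object.__setattr__(self, "rotation_deg", r)

    def apply(self, point_xy: tuple[float, float]) -> tuple[float, float]:
        a = math.radians(self.rotation_deg)
        c, s = math.cos(a), math.sin(a)
        x, y = point_xy
        return (
            c * x - s * y + self.translation[0],
            s * x + c * y + self.translation[1],
        )

    def invert(self) -> "RigidTransform2D":
        a = math.radians(self.rotation_deg)
        c, s = math.cos(a), math.sin(a)
        tx, ty = self.translation
        return RigidTransform2D(
            rotation_deg=-self.rotation_deg,
            translation=(-(c * tx + s * ty), -(-s * tx + c * ty)),
            z_offset=-self.z_offset,
        )

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls()


# ---------------------------------------------------------------------------
# landmark detection
# ---------------------------------------------------------------------------


def find_ball_bearings(
    volume: VolumeGrid, threshold: float = METAL_THRESHOLD_HU
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the two metal ball bearings as sub-voxel 3D points (x, y, z) mm.

    The volume must contain exactly two compact objects above ``threshold``;
    their intensity-weighted centroids are returned, sorted by x.

    Raises
    ------
    LocalizationError
        If fewer or more than two candidate objects are found (the count is
        named in the message; ambiguity is rejected rather than guessed).
    """
    mask = volume.values >= threshold
    labels, n = ndimage.label(mask)
    if n != 2:
        raise LocalizationError(f"expected 2 metal objects above {threshold} HU, found {n}")
    points = []
    zc, yc, xc = volume.z_coords(), volume.y_coords(), volume.x_coords()
    for lab in (1, 2):
        comp = labels == lab
        w = np.where(comp, volume.values - threshold, 0.0)
        total = w.sum()
        if total <= 0:  # pragma: no cover - mask guarantees positive weights
            raise LocalizationError("degenerate metal component")
        iz, iy, ix = np.nonzero(comp)
        z = (w[iz, iy, ix] * zc[iz]).sum() / total
        y = (w[iz, iy, ix] * yc[iy]).sum() / total
        x = (w[iz, iy, ix] * xc[ix]).sum() / total
        points.append(np.array([x, y, z]))
    points.sort(key=lambda p: (p[0], p[1]))
    return points[0], points[1]


def estimate_phantom_transform(
    volume: VolumeGrid,
    spec: "PhantomSpec",  # noqa: F821 - forward ref, see phantom module
    *,
    body_threshold: float = BODY_THRESHOLD_HU,
    metal_threshold: float = METAL_THRESHOLD_HU,
) -> RigidTransform2D:
    """Estimate the phantom pose from the image.

    The in-plane translation is the centroid of the non-air mask (the phantom
    is rotationally symmetric at its boundary, so the centroid is the axis).
    The rotation is recovered from the ball-bearing axis, folded into
    (−90°, 90°] — the bearing pair is symmetric under a half turn, which is
    sufficient for the small setup misalignments this tolerates.  If the
    bearings cannot be found, rotation falls back to 0 and the condition is
    recorded in ``meta``.
    """
    mask = volume.values > body_threshold
    if not mask.any():
        raise LocalizationError(f"no voxels above {body_threshold} HU: phantom not visible")
    # fill enclosed holes (e.g. the air insert) so the mask is the full
    # phantom support and its centroid is the axis
    for k in range(mask.shape[0]):
        mask[k] = ndimage.binary_fill_holes(mask[k])
    iz, iy, ix = np.nonzero(mask)
    cx = volume.x_coords()[ix].mean()
    cy = volume.y_coords()[iy].mean()
    cz = volume.z_coords()[iz].mean()
    z_offset = cz - spec.length / 2.0

    meta: dict[str, Any] = {}
    rotation = 0.0
    marker = spec.markers()
    if marker is not None:
        try:
            p1, p2 = find_ball_bearings(volume, metal_threshold)
        except LocalizationError as err:
            meta["bearing_detection"] = str(err)
        else:
            measured = math.degrees(math.atan2(p2[1] - p1[1], p2[0] - p1[0]))
            ax, ay = marker.axis_direction()
            nominal = math.degrees(math.atan2(ay, ax))
            rotation = measured - nominal
            # fold into (-90, 90]: the bearing pair has a 180-degree symmetry
            rotation = (rotation + 90.0) % 180.0 - 90.0
            if rotation == -90.0:
                rotation = 90.0
            sep = float(np.linalg.norm(p2 - p1))
            meta["bearing_separation_mm"] = sep
            meta["bearing_residual_mm"] = abs(sep - marker.nominal_separation)
    return RigidTransform2D(rotation_deg=rotation, translation=(float(cx), float(cy)),
                            z_offset=float(z_offset), meta=meta)


def map_rois(
    layout: Iterable[RoiSpec],
    transform: RigidTransform2D,
    volume: VolumeGrid | None = None,
) -> list[RoiSpec]:
    """Map nominal (phantom-frame) ROIs into image coordinates.

    Areas are preserved (the transform is rigid).  If ``volume`` is given,
    every mapped ROI must lie fully inside the image bounds; offending ROIs
    are named in the raised error.
    """
    mapped = [
        replace(roi, center=transform.apply(roi.center), z=roi.z + transform.z_offset)
        for roi in layout
    ]
    if volume is not None:
        bad = [roi.label for roi in mapped if not _roi_in_bounds(roi, volume)]
        if bad:
            raise LocalizationError(f"mapped ROI(s) outside image bounds: {', '.join(bad)}")
    return mapped


def _roi_in_bounds(roi: RoiSpec, volume: VolumeGrid) -> bool:
    dz, dy, dx = volume.spacing
    x, y = roi.center
    r = roi.radius
    xlo, xhi = volume.x_coords()[0] - dx / 2, volume.x_coords()[-1] + dx / 2
    ylo, yhi = volume.y_coords()[0] - dy / 2, volume.y_coords()[-1] + dy / 2
    zlo, zhi = volume.z_coords()[0] - dz / 2, volume.z_coords()[-1] + dz / 2
    return (
        xlo <= x - r and x + r <= xhi and ylo <= y - r and y + r <= yhi and zlo <= roi.z <= zhi
    )
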