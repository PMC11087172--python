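"""The five measured image-quality quantities.

Each metric follows the accreditation procedure: ROI mean/SD statistics,
contrast-to-noise ratio CNR = (mean_A − mean_B) / SD_B, uniformity as the
maximum |peripheral − center| ROI-mean difference, image scaling from the
ball-bearing separation, bar-pattern modulation for spatial resolution, and
per-material mean HU for accuracy.

Values are kept at full precision here; rounding to the 1-decimal presentation
used in scorecards happens only at the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .localize import METAL_THRESHOLD_HU, RigidTransform2D, RoiSpec, find_ball_bearings
from .phantom import BarPatternSpec, HU_MATERIALS
from .volume import VolumeGrid

#: Modulation (fraction of the nominal bar-gap contrast) at or above which a
#: bar pattern counts as resolved.  The accreditation procedure scores
#: visibility by eye; this fixed, documented threshold replaces that judgment.
RESOLUTION_MODULATION_THRESHOLD = 0.25


class MetricError(RuntimeError):
    """Raised when a metric's preconditions are not met."""


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("RoiStats requires n >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class CnrResult:
    stats_a: RoiStats
    stats_b: RoiStats
    cnr: float


@dataclass(frozen=True)
class UniformityResult:
    center_mean: float
    peripheral_means: tuple[float, float, float, float]
    diffs: tuple[float, float, float, float]
    max_abs_diff: float


@dataclass(frozen=True)
class ScalingResult:
    measured_mm: float
    nominal_mm: float
    percent_error: float


@dataclass(frozen=True)
class ResolutionResult:
    frequencies: tuple[float, ...]
    modulations: tuple[float, ...]
    resolvable_lp: float
    threshold: float


@dataclass(frozen=True)
class HuAccuracyResult:
    means: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(HU_MATERIALS) - set(self.means)
        if missing:
            raise ValueError(f"missing material(s): {sorted(missing)}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def roi_values(volume: VolumeGrid, roi: RoiSpec) -> np.ndarray:
    """HU of all voxels whose centers fall inside the ROI disc and z window."""
    sel = volume.slice_indices_within(roi.z, roi.z_thickness)
    ys = volume.y_coords()
    xs = volume.x_coords()
    mask = (xs[np.newaxis, :] - roi.center[0]) ** 2 + (
        ys[:, np.newaxis] - roi.center[1]
    ) ** 2 <= roi.radius**2
    if not mask.any():
        raise MetricError(f"ROI {roi.label!r} contains no voxel centers")
    return volume.values[sel][:, mask].ravel()


def roi_stats(volume: VolumeGrid, roi: RoiSpec) -> RoiStats:
    """Mean and sample (n−1) standard deviation over the ROI voxels."""
    v = roi_values(volume, roi)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return RoiStats(mean=float(v.mean()), sd=sd, n=int(v.size))


def compute_cnr(stats_a: RoiStats, stats_b: RoiStats) -> CnrResult:
    """Contrast-to-noise ratio (mean_A − mean_B) / SD_B, sign preserved."""
    if stats_b.sd <= 0:
        raise MetricError("CNR undefined: ROI B has zero standard deviation")
    return CnrResult(stats_a, stats_b, (stats_a.mean - stats_b.mean) / stats_b.sd)


def measure_uniformity(volume: VolumeGrid, rois: Sequence[RoiSpec]) -> UniformityResult:
    """Max |peripheral − center| mean difference over five equal-area ROIs.

    The center ROI is the one labelled ``center`` (else the first).
    """
    if len(rois) != 5:
        raise MetricError(f"uniformity needs exactly 5 ROIs, got {len(rois)}")
    areas = [r.area for r in rois]
    if max(areas) - min(areas) > 1e-6 * max(areas):
        raise MetricError("uniformity ROIs must have identical area")
    center = next((r for r in rois if r.label == "center"), rois[0])
    peripheral = [r for r in rois if r is not center]
    cm = roi_stats(volume, center).mean
    pm = tuple(roi_stats(volume, r).mean for r in peripheral)
    diffs = tuple(p - cm for p in pm)
    return UniformityResult(cm, pm, diffs, max(abs(d) for d in diffs))


def measure_scaling(
    volume: VolumeGrid, nominal_mm: float = 100.0, metal_threshold: float = METAL_THRESHOLD_HU
) -> ScalingResult:
    """Percent distance error from the sub-voxel ball-bearing separation."""
    p1, p2 = find_ball_bearings(volume, metal_threshold)
    measured = float(np.linalg.norm(p2 - p1))
    return ScalingResult(measured, nominal_mm, 100.0 * abs(measured - nominal_mm) / nominal_mm)


def measure_resolution(
    volume: VolumeGrid,
    patterns: Sequence[BarPatternSpec],
    *,
    contrast_hu: float,
    z: float,
    transform: RigidTransform2D | None = None,
    z_thickness: float = 9.0,
    threshold: float = RESOLUTION_MODULATION_THRESHOLD,
) -> ResolutionResult:
    """Modulation per bar pattern and the resolvable spatial frequency.

    For each pattern the image is sampled along narrow strips at the known
    bar and gap center lines (geometry from the pattern spec mapped through
    the phantom pose); modulation is (mean over bar strips − mean over gap
    strips) / ``contrast_hu``, clipped to [0, 1].  The resolvable frequency is
    the highest for which this pattern *and every coarser pattern* reach the
    threshold — a dropout at a low frequency caps the score.
    """
    if not patterns:
        raise MetricError("no bar patterns given")
    transform = transform or RigidTransform2D.identity()
    pats = sorted(patterns, key=lambda p: p.frequency_lp_cm)
    sel = volume.slice_indices_within(z + transform.z_offset, z_thickness)
    plane = volume.values[sel].mean(axis=0)

    mods = []
    for pat in pats:
        mods.append(
            _pattern_modulation(plane, volume, pat, transform, contrast_hu)
        )
    freqs = tuple(p.frequency_lp_cm for p in pats)
    resolvable = 0.0
    for f, m in zip(freqs, mods):
        if m >= threshold:
            resolvable = f
        else:
            break
    return ResolutionResult(freqs, tuple(mods), resolvable, threshold)


def _pattern_modulation(
    plane: np.ndarray,
    volume: VolumeGrid,
    pat: BarPatternSpec,
    transform: RigidTransform2D,
    contrast_hu: float,
) -> float:
    p = pat.period_mm
    h = pat.size_mm / 2.0
    # strip centers along the modulation axis, keeping clear of patch edges
    bar_u, gap_u = [], []
    k = 0
    while True:
        u_b = -h + p / 4.0 + k * p
        u_g = -h + 3.0 * p / 4.0 + k * p
        if u_b > h - p / 4.0:
            break
        if abs(u_b) <= h - p / 4.0:
            bar_u.append(u_b)
        if abs(u_g) <= h - p / 4.0:
            gap_u.append(u_g)
        k += 1
    if not bar_u or not gap_u:
        raise MetricError(
            f"patch too small for {pat.frequency_lp_cm:g} lp/cm strip sampling"
        )
    # sample each strip at 3 phases around its center, along 60% of the bar
    du = np.array([-p / 8.0, 0.0, p / 8.0])
    v = np.linspace(-0.3 * pat.size_mm, 0.3 * pat.size_mm, 9)

    def strip_mean(centers: list[float]) -> float:
        u = (np.asarray(centers)[:, None] + du[None, :]).ravel()
        uu, vv = np.meshgrid(u, v, indexing="ij")
        a = math.radians(pat.orientation_deg)
        xl = uu * math.cos(a) - vv * math.sin(a) + pat.center[0]
        yl = uu * math.sin(a) + vv * math.cos(a) + pat.center[1]
        # map phantom frame -> image world
        ang = math.radians(transform.rotation_deg)
        c, s = math.cos(ang), math.sin(ang)
        xw = c * xl - s * yl + transform.translation[0]
        yw = s * xl + c * yl + transform.translation[1]
        rows = (yw - volume.origin[1]) / volume.spacing[1]
        cols = (xw - volume.origin[2]) / volume.spacing[2]
        vals = ndimage.map_coordinates(
            plane, np.vstack([rows.ravel(), cols.ravel()]), order=1, mode="nearest"
        )
        return float(vals.mean())

    modulation = (strip_mean(bar_u) - strip_mean(gap_u)) / contrast_hu
    return float(np.clip(modulation, 0.0, 1.0))


def measure_hu_accuracy(volume: VolumeGrid, rois: Sequence[RoiSpec]) -> HuAccuracyResult:
    """Mean HU per material insert; ROIs are labelled by material name."""
    means = {roi.label: roi_stats(volume, roi).mean for roi in rois}
    missing = set(HU_MATERIALS) - set(means)
    if missing:
        raise MetricError(f"missing material ROI(s): {sorted(missing)}")
    return HuAccuracyResult({m: means[m] for m in HU_MATERIALS})
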