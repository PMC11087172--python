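"""Voxelized CT scans of the phantom with controllable degradations.

The renderer produces a noiseless, artifact-free voxelization: each voxel's HU
is the area-weighted nominal HU of the materials it covers, computed by
supersampled anti-aliasing on a sub-grid at least 4× finer than the voxel
grid so that even the 12 lp/cm bar pattern (0.42 mm bars) is representable.

Degradations are then applied in a fixed, documented order — geometric
scale/shift/rotation (resampling), in-plane Gaussian blur, a radial cupping
field, per-material HU bias, and finally i.i.d. white Gaussian noise — which
defines, for testing purposes, the artifact families the image-quality
metrics are meant to detect (blur ↔ resolution, cupping ↔ uniformity,
noise ↔ CNR, bias ↔ HU accuracy, magnification ↔ scaling).  No projection
physics is modelled: no scatter, beam hardening or reconstruction algorithm.

The same parameters and seed always produce bit-identical volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage

from .phantom import PhantomSpec
from .volume import AIR_HU, VolumeGrid

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Fraction of the phantom outer radius at which the cupping field saturates.
#: The field is 0 at the center and −amplitude from this radius out to the
#: edge, so ROIs placed near (but inside) the boundary see the full amplitude.
CUPPING_SATURATION_FRAC = 0.7


@dataclass
class SimulationParams:
    """Scan geometry plus degradation magnitudes.

    Units: mm for spacing/blur/shift, HU for noise/cupping/bias, degrees for
    rotation.  ``scale_factor`` is a unitless in-plane magnification (the
    artifact the ball-bearing scaling check detects).
    """

    in_plane_spacing: float = 0.4
    slice_thickness: float = 3.0
    noise_sd: float = 0.0
    blur_fwhm: float = 0.0
    cupping_amplitude: float = 0.0
    material_bias: Mapping[str, float] = field(default_factory=dict)
    scale_factor: float = 1.0
    shift: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    seed: int = 0
    supersample: int = 4
    fov_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel spacing must be > 0")
        if self.noise_sd < 0 or self.blur_fwhm < 0:
            raise ValueError("noise_sd and blur_fwhm must be >= 0")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _fine_coords(n: int, spacing: float, ss: int) -> np.ndarray:
    """Centers of the ss× supersampled sub-pixels of an n-pixel centered axis."""
    start = -(n * spacing) / 2.0 + spacing / (2.0 * ss)
    return start + np.arange(n * ss) * (spacing / ss)


def _downsample(fine: np.ndarray, ss: int) -> np.ndarray:
    n0, n1 = fine.shape[0] // ss, fine.shape[1] // ss
    return fine.reshape(n0, ss, n1, ss).mean(axis=(1, 3))


def _render_section(spec: PhantomSpec, module_index: Optional[int], xs: np.ndarray,
                    ys: np.ndarray) -> np.ndarray:
    """Supersampled HU cross-section for one module (or air if None)."""
    X = xs[np.newaxis, :]
    Y = ys[:, np.newaxis]
    img = np.full((ys.size, xs.size), AIR_HU, dtype=np.float32)
    if module_index is None:
        return img
    r2 = X**2 + Y**2
    if spec.body_ring_outer_diameter is not None:
        img[r2 <= spec.outer_radius**2] = spec.ring_material.nominal_hu
    mod = spec.module(module_index)
    img[r2 <= spec.head_radius**2] = mod.background.nominal_hu
    for ins in mod.inserts:
        mask = (X - ins.center[0]) ** 2 + (Y - ins.center[1]) ** 2 <= (ins.diameter / 2.0) ** 2
        img[mask] = ins.material.nominal_hu
    bar_hu = spec.material_table().get("bone", 910.0)
    for pat in mod.bar_patterns:
        a = math.radians(pat.orientation_deg)
        u = (X - pat.center[0]) * math.cos(a) + (Y - pat.center[1]) * math.sin(a)
        v = -(X - pat.center[0]) * math.sin(a) + (Y - pat.center[1]) * math.cos(a)
        h = pat.size_mm / 2.0
        inside = (np.abs(u) <= h) & (np.abs(v) <= h)
        bars = ((u + h) % pat.period_mm) < pat.period_mm / 2.0
        img[inside & bars] = bar_hu
    return img


def _paint_bb_disc(img: np.ndarray, xs: np.ndarray, ys: np.ndarray, cx: float, cy: float,
                   radius: float, hu: float) -> None:
    """Paint a disc (sphere section) onto a supersampled section in place."""
    jx = np.nonzero(np.abs(xs - cx) <= radius)[0]
    jy = np.nonzero(np.abs(ys - cy) <= radius)[0]
    if jx.size == 0 or jy.size == 0:
        return
    sub_x = xs[jx[0] : jx[-1] + 1]
    sub_y = ys[jy[0] : jy[-1] + 1]
    mask = (sub_x[np.newaxis, :] - cx) ** 2 + (sub_y[:, np.newaxis] - cy) ** 2 <= radius**2
    region = img[jy[0] : jy[-1] + 1, jx[0] : jx[-1] + 1]
    region[mask] = hu


def render_volume(
    spec: PhantomSpec,
    params: SimulationParams,
    z_range: Optional[tuple[float, float]] = None,
) -> VolumeGrid:
    """Noiseless, artifact-free voxelization of the phantom.

    The phantom axis is placed at world (x, y) = (0, 0) and the first module
    face at world z = 0.  ``z_range`` optionally restricts rendering to the
    slices whose centers fall inside it (useful for fast partial scans).

    If the in-plane spacing is too coarse to represent the finest bar pattern
    at the Nyquist limit, a warning is recorded in the volume metadata (the
    sub-grid rendering itself is always at least 4× finer).
    """
    dx = params.in_plane_spacing
    dz = params.slice_thickness
    ss = params.supersample
    fov = params.fov_mm
    if fov is None:
        fov = 2.0 * spec.outer_radius + 30.0
    n = int(round(fov / dx))

    nz = int(round(spec.length / dz))
    z_centers = (np.arange(nz) + 0.5) * dz
    if z_range is not None:
        keep = (z_centers >= z_range[0]) & (z_centers <= z_range[1])
        z_centers = z_centers[keep]
        if z_centers.size == 0:
            raise ValueError(f"z_range {z_range} selects no slices")

    xs = _fine_coords(n, dx, ss)
    ys = xs

    meta: dict = {"materials": spec.material_table(), "params": params}
    max_freq = max(
        (p.frequency_lp_cm for m in spec.modules for p in m.bar_patterns), default=None
    )
    if max_freq is not None and dx > 10.0 / (2.0 * max_freq):
        meta["warnings"] = [
            f"in-plane spacing {dx} mm exceeds the Nyquist limit "
            f"{10.0 / (2.0 * max_freq):.3f} mm for the {max_freq:g} lp/cm pattern"
        ]

    marker = spec.markers()
    bb_r = marker.diameter / 2.0 if marker is not None else 0.0
    metal_hu = spec.material_table().get("metal", 2500.0)

    section_cache: dict[Optional[int], np.ndarray] = {}

    def module_section(idx: Optional[int]) -> np.ndarray:
        if idx not in section_cache:
            section_cache[idx] = _render_section(spec, idx, xs, ys)
        return section_cache[idx]

    n_sub = 3  # z sub-samples per slice (slice-thickness averaging)
    sub_offsets = (np.arange(n_sub) - (n_sub - 1) / 2.0) * (dz / n_sub)

    slices = np.empty((z_centers.size, n, n), dtype=np.float32)
    for k, zc in enumerate(z_centers):
        acc: Optional[np.ndarray] = None
        for dz_sub in sub_offsets:
            z = zc + dz_sub
            mod = spec.module_at(z)
            sec = module_section(None if mod is None else mod.index)
            if marker is not None and abs(z - marker.point_a[2]) < bb_r:
                sec = sec.copy()
                rz = math.sqrt(bb_r**2 - (z - marker.point_a[2]) ** 2)
                for p in (marker.point_a, marker.point_b):
                    _paint_bb_disc(sec, xs, ys, p[0], p[1], rz, metal_hu)
            fine = sec if acc is None else acc + sec
            acc = fine
        slices[k] = _downsample(acc / n_sub, ss)

    oxy = -(n - 1) / 2.0 * dx  # center of voxel [0,0] on a centered axis
    origin = (float(z_centers[0]), oxy, oxy)
    vol = VolumeGrid(slices, (dz, dx, dx), origin, meta)
    vol.clip_hu()
    return vol


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------


def degrade(volume: VolumeGrid, params: SimulationParams) -> VolumeGrid:
    """Apply the degradation chain to a rendered volume.

    Order: geometric scale/shift/rotation → Gaussian blur → radial cupping →
    per-material bias → white Gaussian noise.  Deterministic given
    ``(volume, params)``; all-zero parameters return an identical copy.
    """
    out = volume.copy()
    dz, dy, dx = out.spacing

    # 1. geometry: magnify/rotate about the volume in-plane center, then shift
    if params.scale_factor != 1.0 or params.rotation_deg != 0.0 or params.shift != (0.0, 0.0):
        a = math.radians(params.rotation_deg)
        c, s = math.cos(a), math.sin(a)
        inv_s = 1.0 / params.scale_factor
        # world mapping: p_in = R(-a) @ (p_out - t) / scale  (x, y components)
        # in (row=y, col=x) index space with equal dy == dx:
        A = np.array([[c, -s], [s, c]]) * inv_s  # acts on (y, x)
        oy = out.origin[1]
        ox = out.origin[2]
        o_vec = np.array([oy, ox])
        t_vec = np.array([params.shift[1], params.shift[0]])
        b = (A @ (o_vec - t_vec) - o_vec) / dx
        new = np.empty_like(out.values)
        for k in range(out.shape[0]):
            ndimage.affine_transform(
                out.values[k], A, offset=b, output=new[k], order=1,
                mode="constant", cval=AIR_HU,
            )
        out.values = new

    # 2. in-plane Gaussian blur
    if params.blur_fwhm > 0:
        sigma_pix = params.blur_fwhm * FWHM_TO_SIGMA / dx
        out.values = ndimage.gaussian_filter(
            out.values, sigma=(0.0, sigma_pix, sigma_pix), mode="nearest"
        )

    # 3. radial cupping: 0 at the phantom center, -A from the saturation
    # radius outward; applied to phantom material only
    if params.cupping_amplitude != 0.0:
        mask = out.values > -300.0
        if mask.any():
            ys = out.y_coords() - params.shift[1]
            xs = out.x_coords() - params.shift[0]
            r2 = (ys[:, np.newaxis]) ** 2 + (xs[np.newaxis, :]) ** 2
            iz, iy, ix = np.nonzero(mask)
            r_edge = math.sqrt(float(r2[iy, ix].max()))
            r_sat = CUPPING_SATURATION_FRAC * r_edge
            fieldmap = -params.cupping_amplitude * np.minimum(1.0, r2 / r_sat**2)
            out.values += np.where(mask, fieldmap[np.newaxis, :, :], 0.0).astype(np.float32)

    # 4. per-material HU bias inside nearest-nominal material masks
    if params.material_bias:
        table = out.meta.get("materials")
        if not table:
            raise ValueError("volume metadata lacks a material table; cannot apply bias")
        names = list(table)
        best = np.full(out.shape, np.inf, dtype=np.float32)
        assigned = np.zeros(out.shape, dtype=np.int8)
        for i, m in enumerate(names):
            d = np.abs(out.values - np.float32(table[m]))
            closer = d < best
            best = np.where(closer, d, best)
            assigned[closer] = i
        close = best <= 50.0
        for mat, bias in params.material_bias.items():
            if mat not in table:
                raise ValueError(f"material {mat!r} not in the volume's material table")
            sel = close & (assigned == names.index(mat))
            out.values[sel] += np.float32(bias)

    # 5. white Gaussian noise
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        out.values += rng.normal(0.0, params.noise_sd, size=out.shape).astype(np.float32)

    out.clip_hu()
    return out


def simulate_scan(
    spec: PhantomSpec,
    params: SimulationParams,
    z_range: Optional[tuple[float, float]] = None,
) -> VolumeGrid:
    """Render then degrade; same spec/params/seed → bit-identical volume."""
    return degrade(render_volume(spec, params, z_range=z_range), params)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def clean_diagnostic_params(seed: int = 0, **overrides) -> SimulationParams:
    """Diagnostic-CT-like conditions: low noise, sharp, nearly flat field.

    Ground truth lies well inside every accreditation band, so a full
    scorecard of a scan simulated with this preset passes all nine criteria.
    """
    defaults = dict(noise_sd=2.5, blur_fwhm=0.6, cupping_amplitude=2.0, seed=seed)
    defaults.update(overrides)
    return SimulationParams(**defaults)


def degraded_cbct_params(seed: int = 0, **overrides) -> SimulationParams:
    """CBCT-like conditions: heavy noise, softer optics, strong cupping.

    Chosen to fail the uniformity criterion (cupping beyond the minor band)
    and the CNR criterion (noise swamping the 6 HU rod contrast) while the
    geometric and HU-accuracy criteria remain intact.
    """
    defaults = dict(noise_sd=25.0, blur_fwhm=0.8, cupping_amplitude=9.0, seed=seed)
    defaults.update(overrides)
    return SimulationParams(**defaults)
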