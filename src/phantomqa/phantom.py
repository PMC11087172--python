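"""Canonical description of the ACR CT accreditation phantom.

The ACR phantom is a 20 cm diameter × 16 cm long cylinder (with an optional
33 cm outer body ring) containing four axial modules:

0. **HU accuracy** — cylindrical inserts of polyethylene, bone, acrylic, air
   and water whose mean HU is compared against accreditation bands;
1. **Low contrast / CNR** — a rod a few HU above the water background, used
   for the contrast-to-noise ratio;
2. **Spatial resolution** — eight bar patterns from 4 to 12 line-pairs/cm;
3. **Uniformity** — a water-equivalent slab with five equal ROIs (center +
   four peripheral) plus two metal ball bearings spaced exactly 100 mm apart
   for image-scaling checks.

Both the simulator and the analyzer consume this one description, so insert
positions only need internal consistency.  Exact in-module coordinates are not
published with the phantom at the precision used here; the layout below
(72° angular insert spacing, peripheral uniformity ROIs 10 mm in from the
edge, ~200 mm² HU/CNR ROIs and ~400 mm² uniformity ROIs) follows ACR CT
quality-control documentation and is configurable.

Phantom frame: right-handed, x/y from the phantom axis (mm), z along the axis
measured from the first module face, so modules tile ``[0, length]``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .localize import RoiSpec
from .volume import HU_MAX, HU_MIN

#: Material labels the phantom description may use.
MATERIAL_NAMES = frozenset(
    {"water", "air", "acrylic", "bone", "polyethylene", "background", "metal", "low_contrast"}
)

#: Nominal HU used when rendering each material (single scalar per material;
#: energy dependence is out of scope).
DEFAULT_NOMINAL_HU = {
    "water": 0.0,
    "air": -1000.0,
    "acrylic": 120.0,
    "bone": 910.0,
    "polyethylene": -95.0,
    "low_contrast": 6.0,
    "metal": 2500.0,
}

HU_MATERIALS = ("acrylic", "air", "bone", "polyethylene", "water")


@dataclass(frozen=True)
class MaterialRef:
    name: str
    nominal_hu: float

    def __post_init__(self) -> None:
        if self.name not in MATERIAL_NAMES:
            raise ValueError(f"unknown material name {self.name!r}")
        if not HU_MIN <= self.nominal_hu <= HU_MAX:
            raise ValueError(f"nominal HU {self.nominal_hu} outside [{HU_MIN}, {HU_MAX}]")


@dataclass(frozen=True)
class InsertSpec:
    """A cylindrical insert within one module (in-plane position, mm)."""

    material: MaterialRef
    center: tuple[float, float]
    diameter: float
    module_index: int

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("insert diameter must be > 0")


@dataclass(frozen=True)
class BarPatternSpec:
    """A square bar-pattern patch: bars of pitch 10/frequency mm along x.

    ``orientation_deg`` rotates the modulation axis; 0 means HU varies along
    the phantom x axis.
    """

    frequency_lp_cm: float
    center: tuple[float, float]
    size_mm: float
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_lp_cm <= 0 or self.size_mm <= 0:
            raise ValueError("bar pattern frequency and size must be > 0")

    @property
    def period_mm(self) -> float:
        """One line pair (bar + gap) in mm."""
        return 10.0 / self.frequency_lp_cm


@dataclass(frozen=True)
class MarkerSpec:
    """Two ball bearings at a known separation for image-scaling checks."""

    point_a: tuple[float, float, float]
    point_b: tuple[float, float, float]
    diameter: float = 5.0
    nominal_separation: float = 100.0

    def __post_init__(self) -> None:
        sep = math.dist(self.point_a, self.point_b)
        if not math.isclose(sep, self.nominal_separation, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"marker separation {sep:.6f} mm != nominal {self.nominal_separation} mm"
            )

    def axis_direction(self) -> tuple[float, float]:
        dx = self.point_b[0] - self.point_a[0]
        dy = self.point_b[1] - self.point_a[1]
        n = math.hypot(dx, dy)
        return (dx / n, dy / n)


@dataclass(frozen=True)
class ModuleSpec:
    name: str
    index: int
    z_range: tuple[float, float]
    background: MaterialRef
    inserts: tuple[InsertSpec, ...] = ()
    bar_patterns: tuple[BarPatternSpec, ...] = ()
    marker: Optional[MarkerSpec] = None

    @property
    def z_center(self) -> float:
        return 0.5 * (self.z_range[0] + self.z_range[1])


@dataclass(frozen=True)
class PhantomSpec:
    head_diameter: float = 200.0
    length: float = 160.0
    body_ring_outer_diameter: Optional[float] = None
    modules: tuple[ModuleSpec, ...] = ()
    ring_material: MaterialRef = MaterialRef("water", 0.0)

    def __post_init__(self) -> None:
        if self.body_ring_outer_diameter is not None and (
            self.body_ring_outer_diameter <= self.head_diameter
        ):
            raise ValueError("body ring outer diameter must exceed head diameter")
        self._check_modules_tile()
        self._check_materials_unique()
        self._check_inserts_inside()

    def _check_modules_tile(self) -> None:
        z = 0.0
        for mod in self.modules:
            if not math.isclose(mod.z_range[0], z, abs_tol=1e-9):
                raise ValueError(f"module {mod.name!r} does not start at z={z}")
            if mod.z_range[1] <= mod.z_range[0]:
                raise ValueError(f"module {mod.name!r} has empty z extent")
            z = mod.z_range[1]
        if self.modules and not math.isclose(z, self.length, abs_tol=1e-9):
            raise ValueError(f"modules tile [0, {z}] but phantom length is {self.length}")

    def _check_materials_unique(self) -> None:
        seen: dict[str, float] = {}
        for mat in self.materials():
            if mat.name in seen and seen[mat.name] != mat.nominal_hu:
                raise ValueError(f"material {mat.name!r} appears with conflicting HU")
            seen[mat.name] = mat.nominal_hu

    def _check_inserts_inside(self) -> None:
        r = self.head_radius
        for mod in self.modules:
            for ins in mod.inserts:
                if math.hypot(*ins.center) + ins.diameter / 2.0 >= r:
                    raise ValueError(
                        f"insert {ins.material.name!r} not fully inside phantom radius"
                    )

    @property
    def head_radius(self) -> float:
        return self.head_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        if self.body_ring_outer_diameter is not None:
            return self.body_ring_outer_diameter / 2.0
        return self.head_radius

    def materials(self) -> list[MaterialRef]:
        mats: list[MaterialRef] = []
        for mod in self.modules:
            mats.append(mod.background)
            mats.extend(ins.material for ins in mod.inserts)
        if self.body_ring_outer_diameter is not None:
            mats.append(self.ring_material)
        return mats

    def material_table(self) -> dict[str, float]:
        """Material name → nominal HU, including metal and bar material."""
        table = {m.name: m.nominal_hu for m in self.materials()}
        for mod in self.modules:
            if mod.marker is not None:
                table.setdefault("metal", DEFAULT_NOMINAL_HU["metal"])
            if mod.bar_patterns:
                table.setdefault("bone", DEFAULT_NOMINAL_HU["bone"])
        table.setdefault("air", -1000.0)
        return table

    def module(self, index: int) -> ModuleSpec:
        for mod in self.modules:
            if mod.index == index:
                return mod
        raise IndexError(f"no module with index {index}")

    def module_at(self, z: float) -> Optional[ModuleSpec]:
        for mod in self.modules:
            if mod.z_range[0] <= z < mod.z_range[1] or (
                mod is self.modules[-1] and math.isclose(z, mod.z_range[1], abs_tol=1e-9)
            ):
                return mod
        return None

    def markers(self) -> Optional[MarkerSpec]:
        for mod in self.modules:
            if mod.marker is not None:
                return mod.marker
        return None

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return _spec_to_dict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return _spec_from_dict(d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# default layout
# ---------------------------------------------------------------------------

#: Bar-pattern frequencies present in the phantom (lp/cm), 4 through 12.
BAR_FREQUENCIES = (4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 12.0)

INSERT_DIAMETER = 25.0
INSERT_RADIUS_POSITION = 60.0
CNR_ROD_DIAMETER = 25.0
CNR_ROD_CENTER = (0.0, 25.0)
BAR_PATCH_SIZE = 12.0
BAR_PATCH_RADIUS_POSITION = 55.0
BB_RADIUS_POSITION = 50.0
BB_Z_OFFSET_FROM_MODULE_CENTER = 12.0

DEFAULT_HU_ROI_AREA = 200.0
DEFAULT_CNR_ROI_AREA = 200.0
DEFAULT_UNIFORMITY_ROI_AREA = 400.0
UNIFORMITY_ROI_EDGE_MARGIN = 10.0


def default_head_phantom() -> PhantomSpec:
    """The ACR head phantom: 200 mm diameter, 160 mm long, four modules."""
    water = MaterialRef("water", DEFAULT_NOMINAL_HU["water"])
    mats = {
        name: MaterialRef(name, DEFAULT_NOMINAL_HU[name])
        for name in ("acrylic", "bone", "air", "polyethylene", "water")
    }
    length = 160.0
    dz = length / 4.0

    inserts = tuple(
        InsertSpec(
            material=mats[name],
            center=(
                INSERT_RADIUS_POSITION * math.cos(math.radians(90.0 - 72.0 * k)),
                INSERT_RADIUS_POSITION * math.sin(math.radians(90.0 - 72.0 * k)),
            ),
            diameter=INSERT_DIAMETER,
            module_index=0,
        )
        for k, name in enumerate(("water", "bone", "acrylic", "air", "polyethylene"))
    )
    hu_module = ModuleSpec("hu_accuracy", 0, (0.0, dz), water, inserts=inserts)

    rod = InsertSpec(
        material=MaterialRef("low_contrast", DEFAULT_NOMINAL_HU["low_contrast"]),
        center=CNR_ROD_CENTER,
        diameter=CNR_ROD_DIAMETER,
        module_index=1,
    )
    cnr_module = ModuleSpec("low_contrast", 1, (dz, 2 * dz), water, inserts=(rod,))

    patterns = tuple(
        BarPatternSpec(
            frequency_lp_cm=f,
            center=(
                BAR_PATCH_RADIUS_POSITION * math.cos(math.radians(90.0 - 45.0 * k)),
                BAR_PATCH_RADIUS_POSITION * math.sin(math.radians(90.0 - 45.0 * k)),
            ),
            size_mm=BAR_PATCH_SIZE,
        )
        for k, f in enumerate(BAR_FREQUENCIES)
    )
    res_module = ModuleSpec("resolution", 2, (2 * dz, 3 * dz), water, bar_patterns=patterns)

    bb_z = 3.5 * dz + BB_Z_OFFSET_FROM_MODULE_CENTER
    marker = MarkerSpec(
        point_a=(-BB_RADIUS_POSITION, 0.0, bb_z),
        point_b=(BB_RADIUS_POSITION, 0.0, bb_z),
    )
    unif_module = ModuleSpec("uniformity", 3, (3 * dz, length), water, marker=marker)

    return PhantomSpec(modules=(hu_module, cnr_module, res_module, unif_module))


def with_body_ring(spec: PhantomSpec, outer_diameter: float = 330.0) -> PhantomSpec:
    """Return a copy of ``spec`` with the outer body ring attached."""
    if spec.body_ring_outer_diameter is not None:
        raise ValueError("phantom already has a body ring")
    return dataclasses.replace(spec, body_ring_outer_diameter=outer_diameter)


def nominal_roi_layout(
    spec: PhantomSpec,
    module_index: int,
    *,
    hu_roi_area: float = DEFAULT_HU_ROI_AREA,
    cnr_roi_area: float = DEFAULT_CNR_ROI_AREA,
    uniformity_roi_area: float = DEFAULT_UNIFORMITY_ROI_AREA,
    edge_margin: float = UNIFORMITY_ROI_EDGE_MARGIN,
    z_thickness: float = 9.0,
) -> list[RoiSpec]:
    """Nominal (phantom-frame) ROI placements for one module.

    * HU module: one ROI centered on each insert, labelled by material.
    * CNR module: ROI ``A`` on the low-contrast rod, ``B`` mirrored across the
      phantom center on background.
    * Resolution module: one square-circumscribing ROI per bar patch,
      labelled by frequency (informational).
    * Uniformity module: five equal-area ROIs — ``center`` plus peripheral
      ROIs at 12/3/6/9 o'clock whose edges stay ``edge_margin`` mm inside the
      phantom boundary.
    """
    mod = spec.module(module_index)  # raises IndexError for invalid index
    z = mod.z_center
    if mod.name == "hu_accuracy":
        d = 2.0 * math.sqrt(hu_roi_area / math.pi)
        return [
            RoiSpec(ins.material.name, ins.center, d, z, z_thickness) for ins in mod.inserts
        ]
    if mod.name == "low_contrast":
        d = 2.0 * math.sqrt(cnr_roi_area / math.pi)
        rod = mod.inserts[0]
        mirrored = (-rod.center[0], -rod.center[1])
        return [
            RoiSpec("A", rod.center, d, z, z_thickness),
            RoiSpec("B", mirrored, d, z, z_thickness),
        ]
    if mod.name == "resolution":
        return [
            RoiSpec(f"{p.frequency_lp_cm:g}lp", p.center, p.size_mm, z, z_thickness)
            for p in mod.bar_patterns
        ]
    if mod.name == "uniformity":
        r_roi = math.sqrt(uniformity_roi_area / math.pi)
        d = 2.0 * r_roi
        r_pos = spec.head_radius - edge_margin - r_roi
        rois = [RoiSpec("center", (0.0, 0.0), d, z, z_thickness)]
        for label, ang in (("12", 90.0), ("3", 0.0), ("6", -90.0), ("9", 180.0)):
            c = (r_pos * math.cos(math.radians(ang)), r_pos * math.sin(math.radians(ang)))
            rois.append(RoiSpec(label, c, d, z, z_thickness))
        return rois
    raise IndexError(f"module {mod.name!r} has no ROI layout")  # pragma: no cover


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------


def _mat(m: MaterialRef) -> dict:
    return {"name": m.name, "nominal_hu": m.nominal_hu}


def _spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "head_diameter": spec.head_diameter,
        "length": spec.length,
        "body_ring_outer_diameter": spec.body_ring_outer_diameter,
        "ring_material": _mat(spec.ring_material),
        "modules": [
            {
                "name": mod.name,
                "index": mod.index,
                "z_range": list(mod.z_range),
                "background": _mat(mod.background),
                "inserts": [
                    {
                        "material": _mat(ins.material),
                        "center": list(ins.center),
                        "diameter": ins.diameter,
                        "module_index": ins.module_index,
                    }
                    for ins in mod.inserts
                ],
                "bar_patterns": [
                    {
                        "frequency_lp_cm": p.frequency_lp_cm,
                        "center": list(p.center),
                        "size_mm": p.size_mm,
                        "orientation_deg": p.orientation_deg,
                    }
                    for p in mod.bar_patterns
                ],
                "marker": None
                if mod.marker is None
                else {
                    "point_a": list(mod.marker.point_a),
                    "point_b": list(mod.marker.point_b),
                    "diameter": mod.marker.diameter,
                    "nominal_separation": mod.marker.nominal_separation,
                },
            }
            for mod in spec.modules
        ],
    }


def _spec_from_dict(d: dict) -> PhantomSpec:
    def mat(m: dict) -> MaterialRef:
        return MaterialRef(m["name"], float(m["nominal_hu"]))

    modules = []
    for md in d["modules"]:
        marker = None
        if md.get("marker") is not None:
            mk = md["marker"]
            marker = MarkerSpec(
                tuple(mk["point_a"]), tuple(mk["point_b"]),
                mk.get("diameter", 5.0), mk.get("nominal_separation", 100.0),
            )
        modules.append(
            ModuleSpec(
                name=md["name"],
                index=int(md["index"]),
                z_range=tuple(md["z_range"]),
                background=mat(md["background"]),
                inserts=tuple(
                    InsertSpec(mat(i["material"]), tuple(i["center"]), float(i["diameter"]),
                               int(i["module_index"]))
                    for i in md.get("inserts", [])
                ),
                bar_patterns=tuple(
                    BarPatternSpec(float(p["frequency_lp_cm"]), tuple(p["center"]),
                                   float(p["size_mm"]), float(p.get("orientation_deg", 0.0)))
                    for p in md.get("bar_patterns", [])
                ),
                marker=marker,
            )
        )
    return PhantomSpec(
        head_diameter=float(d["head_diameter"]),
        length=float(d["length"]),
        body_ring_outer_diameter=d.get("body_ring_outer_diameter"),
        modules=tuple(modules),
        ring_material=mat(d.get("ring_material", {"name": "water", "nominal_hu": 0.0})),
    )
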