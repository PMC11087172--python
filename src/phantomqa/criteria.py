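"""ACR accreditation criteria: classification, tallies, deviation summaries.

Measured metrics are classified as *pass*, *minor deviation* or *major
deviation*:

* **HU accuracy** — pass iff the material mean lies inside the inclusive
  accreditation band (water −7..+7, acrylic 110..135, bone 850..970, air
  −1005..−970, polyethylene −107..−84 HU by default).  Optional minor bands
  may be configured per material; with none configured (the default), any
  value outside the passing band is a major deviation.
* **Uniformity** — pass if the maximum peripheral-to-center difference is
  strictly below 5 HU, minor for 5–7 HU inclusive, major above 7 HU.
* **CNR** — protocol-class minimum (1.0 for adult head/adult body/pediatric
  head, 0.4 for pediatric body by default), inclusive.
* **Spatial resolution** — at least 6 lp/cm for head-type protocols, 5 lp/cm
  for body-type protocols.
* **Image scaling** — distance error within 1.0 % (not stated explicitly by
  the accreditation text used here; every value labelled passing in practice
  is ≤ 0.9 %, and the bound is configurable).

Criteria are selected by the *protocol class* (adult/pediatric × head/body),
independent of which phantom was scanned.  Classification is a total
function on finite values: the bands partition the line.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

#: The nine scorecard criteria, in table column order.
CRITERIA = (
    "contrast_resolution",
    "spatial_resolution",
    "acrylic",
    "air",
    "bone",
    "polyethylene",
    "water",
    "image_scaling",
    "hu_uniformity",
)

HU_MATERIALS = ("acrylic", "air", "bone", "polyethylene", "water")

HEAD_CLASSES = ("adult_head", "pediatric_head")


class Level(str, enum.Enum):
    PASS = "pass"
    MINOR = "minor"
    MAJOR = "major"


@dataclass(frozen=True)
class Verdict:
    level: Level
    value: float
    criterion: str

    @property
    def passed(self) -> bool:
        return self.level is Level.PASS


@dataclass(frozen=True)
class ProtocolVerdict:
    """The nine per-criterion verdicts for one scanned protocol."""

    verdicts: Mapping[str, Verdict]

    def __post_init__(self) -> None:
        if set(self.verdicts) != set(CRITERIA):
            missing = set(CRITERIA) - set(self.verdicts)
            extra = set(self.verdicts) - set(CRITERIA)
            raise ValueError(f"need exactly the 9 criteria; missing={missing} extra={extra}")
        object.__setattr__(self, "verdicts", {k: self.verdicts[k] for k in CRITERIA})

    @property
    def overall_pass(self) -> bool:
        return all(v.passed for v in self.verdicts.values())

    @property
    def n_no_deviation(self) -> int:
        return sum(v.passed for v in self.verdicts.values())


@dataclass(frozen=True)
class DeviationSummary:
    """Mean ± sample SD of how far failing values sit outside the band."""

    n_failing: int
    mean: Optional[float]
    sd: Optional[float]


@dataclass(frozen=True)
class BaselineSet:
    """Per-material baseline HU with a clinical ±tolerance acceptance rule."""

    baselines: Mapping[str, float]
    tolerance: float = 50.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    def check(self, material: str, value: float) -> bool:
        return abs(value - self.baselines[material]) <= self.tolerance


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CriteriaConfig:
    hu_ranges: Mapping[str, tuple[float, float]]
    hu_minor_bands: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    uniformity_pass_below: float = 5.0
    uniformity_minor_max: float = 7.0
    cnr_min: Mapping[str, float] = field(
        default_factory=lambda: {
            "adult_head": 1.0,
            "adult_body": 1.0,
            "pediatric_head": 1.0,
            "pediatric_body": 0.4,
        }
    )
    resolution_min: Mapping[str, float] = field(
        default_factory=lambda: {"head": 6.0, "body": 5.0}
    )
    scaling_tolerance_pct: float = 1.0
    protocol_classes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mat, (lo, hi) in self.hu_ranges.items():
            if lo >= hi:
                raise ValueError(f"{mat}: range lo must be < hi")
            minor = self.hu_minor_bands.get(mat)
            if minor is not None and not (minor[0] <= lo and hi <= minor[1]):
                raise ValueError(f"{mat}: minor band must contain the passing band")
        if not 0 < self.uniformity_pass_below <= self.uniformity_minor_max:
            raise ValueError("uniformity bands must satisfy 0 < pass <= minor_max")

    def protocol_class(self, protocol: str) -> str:
        try:
            return self.protocol_classes[protocol]
        except KeyError:
            raise KeyError(f"protocol {protocol!r} has no configured class") from None

    @staticmethod
    def body_type(protocol_class: str) -> str:
        return "head" if protocol_class in HEAD_CLASSES else "body"

    # ---- serialization ----

    def to_dict(self) -> dict:
        return {
            "hu_ranges": {m: list(r) for m, r in self.hu_ranges.items()},
            "hu_minor_bands": {m: list(r) for m, r in self.hu_minor_bands.items()},
            "uniformity": {
                "pass_below": self.uniformity_pass_below,
                "minor_max": self.uniformity_minor_max,
            },
            "cnr_min": dict(self.cnr_min),
            "resolution_min": dict(self.resolution_min),
            "scaling_tolerance_pct": self.scaling_tolerance_pct,
            "protocol_classes": dict(self.protocol_classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CriteriaConfig":
        return cls(
            hu_ranges={m: tuple(r) for m, r in d["hu_ranges"].items()},
            hu_minor_bands={m: tuple(r) for m, r in d.get("hu_minor_bands", {}).items()},
            uniformity_pass_below=d.get("uniformity", {}).get("pass_below", 5.0),
            uniformity_minor_max=d.get("uniformity", {}).get("minor_max", 7.0),
            cnr_min=d.get("cnr_min", {}),
            resolution_min=d.get("resolution_min", {"head": 6.0, "body": 5.0}),
            scaling_tolerance_pct=d.get("scaling_tolerance_pct", 1.0),
            protocol_classes=d.get("protocol_classes", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "CriteriaConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config() -> CriteriaConfig:
    """The packaged accreditation criteria (see data/acr_criteria.yaml)."""
    from . import tables

    return tables.load_default_config()


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_uniformity(
    max_abs_diff: float, config: Optional[CriteriaConfig] = None
) -> Verdict:
    """Pass below 5 HU, minor for 5–7 HU inclusive, major above 7 HU."""
    if max_abs_diff < 0:
        raise ValueError("uniformity difference cannot be negative")
    lo = config.uniformity_pass_below if config else 5.0
    hi = config.uniformity_minor_max if config else 7.0
    if max_abs_diff < lo:
        level = Level.PASS
    elif max_abs_diff <= hi:
        level = Level.MINOR
    else:
        level = Level.MAJOR
    return Verdict(level, max_abs_diff, "hu_uniformity")


def classify_hu(material: str, mean_hu: float, config: CriteriaConfig) -> Verdict:
    """Inclusive passing band; minor band if configured, else outside = major."""
    if material not in config.hu_ranges:
        raise KeyError(f"unknown material {material!r}")
    lo, hi = config.hu_ranges[material]
    if lo <= mean_hu <= hi:
        level = Level.PASS
    else:
        minor = config.hu_minor_bands.get(material)
        if minor is not None and minor[0] <= mean_hu <= minor[1]:
            level = Level.MINOR
        else:
            level = Level.MAJOR
    return Verdict(level, mean_hu, material)


def classify_cnr(value: float, protocol_class: str, config: CriteriaConfig) -> Verdict:
    minimum = config.cnr_min[protocol_class]
    return Verdict(Level.PASS if value >= minimum else Level.MAJOR, value, "contrast_resolution")


def classify_resolution(value: float, protocol_class: str, config: CriteriaConfig) -> Verdict:
    minimum = config.resolution_min[CriteriaConfig.body_type(protocol_class)]
    return Verdict(Level.PASS if value >= minimum else Level.MAJOR, value, "spatial_resolution")


def classify_scaling(percent_error: float, config: CriteriaConfig) -> Verdict:
    if percent_error < 0:
        raise ValueError("scaling percent error cannot be negative")
    level = Level.PASS if percent_error <= config.scaling_tolerance_pct else Level.MAJOR
    return Verdict(level, percent_error, "image_scaling")


def evaluate_protocol(
    metrics: Mapping[str, float], protocol_class: str, config: CriteriaConfig
) -> ProtocolVerdict:
    """Classify a nine-metric scorecard row for one protocol.

    ``metrics`` maps each name in :data:`CRITERIA` to its measured value
    (a plain mapping or anything dict-like, e.g. a DataFrame row).
    """
    metrics = dict(metrics)
    missing = set(CRITERIA) - set(metrics)
    if missing:
        raise KeyError(f"missing metric(s): {sorted(missing)}")
    verdicts = {
        "contrast_resolution": classify_cnr(
            float(metrics["contrast_resolution"]), protocol_class, config
        ),
        "spatial_resolution": classify_resolution(
            float(metrics["spatial_resolution"]), protocol_class, config
        ),
    }
    for mat in HU_MATERIALS:
        verdicts[mat] = classify_hu(mat, float(metrics[mat]), config)
    verdicts["image_scaling"] = classify_scaling(float(metrics["image_scaling"]), config)
    verdicts["hu_uniformity"] = classify_uniformity(float(metrics["hu_uniformity"]), config)
    return ProtocolVerdict({k: verdicts[k] for k in CRITERIA})


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def deviation_beyond_range(
    value: float, rng: tuple[float, float], bound: str = "nearest"
) -> float:
    """Distance from ``value`` to the passing band (0 if inside).

    ``bound`` selects the reference: ``"nearest"`` (default) measures to the
    nearest violated bound; ``"lower"``/``"upper"`` measure from a fixed bound
    for values outside the band, a convention some QA reports use.
    """
    lo, hi = rng
    if lo >= hi:
        raise ValueError("range lo must be < hi")
    if lo <= value <= hi:
        return 0.0
    if bound == "nearest":
        return lo - value if value < lo else value - hi
    if bound == "lower":
        return abs(value - lo)
    if bound == "upper":
        return abs(value - hi)
    raise ValueError(f"unknown bound selector {bound!r}")


def summarize_failures(
    values: Iterable[float], rng: tuple[float, float], bound: str = "nearest"
) -> DeviationSummary:
    """Mean and sample SD of deviations over the out-of-band values only."""
    devs = [
        deviation_beyond_range(v, rng, bound)
        for v in values
        if not rng[0] <= v <= rng[1]
    ]
    if not devs:
        return DeviationSummary(0, None, None)
    mean = statistics.fmean(devs)
    sd = statistics.stdev(devs) if len(devs) >= 2 else None
    return DeviationSummary(len(devs), mean, sd)


def tally_verdicts(
    protocol_verdicts: Iterable[ProtocolVerdict], criterion: str
) -> tuple[int, int, int]:
    """(pass, minor, major) counts for one criterion across protocols."""
    counts = {Level.PASS: 0, Level.MINOR: 0, Level.MAJOR: 0}
    for pv in protocol_verdicts:
        counts[pv.verdicts[criterion].level] += 1
    return counts[Level.PASS], counts[Level.MINOR], counts[Level.MAJOR]


def build_baseline(
    values_per_material: Mapping[str, Sequence[float]], tolerance: float = 50.0
) -> BaselineSet:
    """Per-material arithmetic-mean baseline with a ±tolerance rule."""
    baselines = {}
    for mat, vals in values_per_material.items():
        vals = list(vals)
        if not vals:
            raise ValueError(f"no values for material {mat!r}")
        baselines[mat] = statistics.fmean(vals)
    return BaselineSet(baselines, tolerance)


def exposure_stability(
    table: Mapping[str, Mapping[str, Sequence[float]]]
) -> tuple[float, tuple[str, str]]:
    """Maximum CT-number range across repeated exposures.

    ``table[protocol][material]`` is the sequence of mean HU at each exposure
    setting.  Returns the largest max−min range over all (protocol, material)
    cells and where it occurred.  Each protocol needs at least two exposures.
    """
    best: Optional[tuple[float, tuple[str, str]]] = None
    for protocol, materials in table.items():
        for material, vals in materials.items():
            vals = list(vals)
            if len(vals) < 2:
                raise ValueError(
                    f"{protocol}/{material}: need >= 2 exposures, got {len(vals)}"
                )
            rng = max(vals) - min(vals)
            if best is None or rng > best[0]:
                best = (rng, (protocol, material))
    if best is None:
        raise ValueError("empty exposure table")
    return best
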