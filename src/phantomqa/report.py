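"""End-to-end pipeline: analyze a volume into a scorecard row, score metric
tables, and compare machines or sessions.

A *scorecard* is a DataFrame with one row per (machine, protocol, phantom):
the nine metric values in the fixed column order plus per-criterion verdict
levels, the no-deviation count and the overall pass flag.  Values are kept at
full precision; :func:`round_for_display` applies the 1-decimal presentation
used in published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import pandas as pd

from . import criteria as crit
from .criteria import CRITERIA, HU_MATERIALS, CriteriaConfig, ProtocolVerdict
from .localize import estimate_phantom_transform, map_rois
from .metrics import (
    RESOLUTION_MODULATION_THRESHOLD,
    compute_cnr,
    measure_hu_accuracy,
    measure_resolution,
    measure_scaling,
    measure_uniformity,
    roi_stats,
)
from .phantom import PhantomSpec, nominal_roi_layout
from .volume import VolumeGrid

SCORECARD_VERSION = 1


# ---------------------------------------------------------------------------
# volume -> metric row
# ---------------------------------------------------------------------------


def analyze_volume(
    volume: VolumeGrid,
    spec: PhantomSpec,
    *,
    resolution_threshold: float = RESOLUTION_MODULATION_THRESHOLD,
) -> dict[str, Any]:
    """Compute the nine-metric scorecard row for one scan.

    Localizes the phantom, maps the nominal ROI layout through the estimated
    pose and evaluates every metric.  The returned mapping carries the metric
    values under the standard column names plus a ``localization`` entry with
    the estimated transform (logged by the CLI for provenance).
    """
    transform = estimate_phantom_transform(volume, spec)

    hu_rois = map_rois(nominal_roi_layout(spec, 0), transform, volume)
    hu = measure_hu_accuracy(volume, hu_rois)

    cnr_rois = {r.label: r for r in map_rois(nominal_roi_layout(spec, 1), transform, volume)}
    cnr = compute_cnr(roi_stats(volume, cnr_rois["A"]), roi_stats(volume, cnr_rois["B"]))

    res_module = spec.module(2)
    mat = spec.material_table()
    contrast = mat.get("bone", 910.0) - res_module.background.nominal_hu
    resolution = measure_resolution(
        volume,
        res_module.bar_patterns,
        contrast_hu=contrast,
        z=res_module.z_center,
        transform=transform,
        threshold=resolution_threshold,
    )

    unif_rois = map_rois(nominal_roi_layout(spec, 3), transform, volume)
    uniformity = measure_uniformity(volume, unif_rois)

    scaling = measure_scaling(volume, nominal_mm=spec.markers().nominal_separation)

    row: dict[str, Any] = {
        "contrast_resolution": cnr.cnr,
        "spatial_resolution": resolution.resolvable_lp,
        **{m: hu.means[m] for m in HU_MATERIALS},
        "image_scaling": scaling.percent_error,
        "hu_uniformity": uniformity.max_abs_diff,
        "localization": transform,
        "resolution_modulations": dict(zip(resolution.frequencies, resolution.modulations)),
    }
    return row


# ---------------------------------------------------------------------------
# metric table -> scorecard
# ---------------------------------------------------------------------------


def evaluate_row(row: Mapping[str, Any], config: CriteriaConfig) -> ProtocolVerdict:
    protocol_class = config.protocol_class(str(row["protocol"]))
    return crit.evaluate_protocol(row, protocol_class, config)


def score_table(table: pd.DataFrame, config: Optional[CriteriaConfig] = None) -> pd.DataFrame:
    """Score a metric table (one protocol per row) against the criteria.

    The input needs a ``protocol`` column plus the nine metric columns; any
    other columns (machine, phantom, dose) pass through untouched.
    """
    config = config or crit.default_config()
    out = table.copy()
    verdicts = [evaluate_row(row, config) for row in table.to_dict("records")]
    for c in CRITERIA:
        out[f"{c}_verdict"] = [pv.verdicts[c].level.value for pv in verdicts]
    out["n_no_deviation"] = [pv.n_no_deviation for pv in verdicts]
    out["overall_pass"] = [pv.overall_pass for pv in verdicts]
    out.attrs["scorecard_version"] = SCORECARD_VERSION
    return out


def hu_failure_summaries(
    table: pd.DataFrame,
    config: Optional[CriteriaConfig] = None,
    materials: Sequence[str] = HU_MATERIALS,
    bound: str = "nearest",
) -> dict[str, crit.DeviationSummary]:
    """Deviation-beyond-band summaries per material over a metric table."""
    config = config or crit.default_config()
    return {
        m: crit.summarize_failures(table[m].astype(float), config.hu_ranges[m], bound)
        for m in materials
    }


def round_for_display(scorecard: pd.DataFrame) -> pd.DataFrame:
    """1-decimal presentation for HU, lp/cm and percent columns."""
    out = scorecard.copy()
    for c in CRITERIA:
        if c in out:
            out[c] = out[c].astype(float).round(1)
    return out


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonReport:
    """Cross-machine / cross-session comparison of scorecards.

    ``no_deviation_counts[name][protocol]`` counts criteria at the
    no-deviation level (out of 9).  ``material_differences`` holds per-
    protocol absolute HU differences of each material between the first
    scorecard and every other; ``baseline_checks`` flags those values against
    a ±tolerance baseline built from the first scorecard.
    """

    no_deviation_counts: Mapping[str, Mapping[str, int]]
    material_differences: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    baseline_checks: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    baselines: Mapping[str, crit.BaselineSet] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "no_deviation_counts": {m: dict(p) for m, p in self.no_deviation_counts.items()},
            "material_differences": {
                m: df.to_dict("records") for m, df in self.material_differences.items()
            },
            "baseline_checks": {
                m: df.to_dict("records") for m, df in self.baseline_checks.items()
            },
            "baselines": {
                ph: {"values": dict(bl.baselines), "tolerance": bl.tolerance}
                for ph, bl in self.baselines.items()
            },
        }


def compare_scorecards(
    scorecards: Mapping[str, pd.DataFrame],
    *,
    baseline_tolerance: float = 50.0,
) -> ComparisonReport:
    """Compare two or more scorecards with matching protocol sets.

    The first scorecard is the reference: material differences and the
    ±tolerance baselines are computed against it.  Baselines are built per
    phantom (a clinical HU baseline is meaningless across phantom sizes), so
    a ``phantom`` column, when present, groups the rows.
    """
    if len(scorecards) < 2:
        raise ValueError("need at least two scorecards to compare")
    names = list(scorecards)
    ref_name = names[0]
    ref = scorecards[ref_name].set_index("protocol")
    ref_protocols = set(ref.index)
    for name in names[1:]:
        protocols = set(scorecards[name]["protocol"])
        if protocols != ref_protocols:
            raise ValueError(
                f"protocol sets differ between {ref_name!r} and {name!r}: "
                f"{sorted(ref_protocols ^ protocols)}"
            )

    counts = {
        name: dict(zip(df["protocol"], df["n_no_deviation"].astype(int)))
        for name, df in scorecards.items()
    }

    phantoms = ref["phantom"] if "phantom" in ref.columns else pd.Series("all", index=ref.index)
    baselines = {
        ph: crit.build_baseline(
            {m: ref.loc[sel, m].astype(float).tolist() for m in HU_MATERIALS},
            baseline_tolerance,
        )
        for ph, sel in phantoms.groupby(phantoms).groups.items()
    }

    diffs: dict[str, pd.DataFrame] = {}
    checks: dict[str, pd.DataFrame] = {}
    for name in names[1:]:
        df = scorecards[name].set_index("protocol").loc[ref.index]
        diffs[name] = (
            (df[list(HU_MATERIALS)].astype(float) - ref[list(HU_MATERIALS)].astype(float))
            .abs()
            .reset_index()
        )
        checks[name] = pd.DataFrame(
            {
                "protocol": df.index,
                **{
                    m: [
                        baselines[ph].check(m, float(v))
                        for ph, v in zip(phantoms, df[m].astype(float))
                    ]
                    for m in HU_MATERIALS
                },
            }
        )
    return ComparisonReport(counts, diffs, checks, baselines)
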