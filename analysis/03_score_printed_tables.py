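#!/usr/bin/env python
"""Score the published per-protocol measurement tables.

Reproduces, from the packaged tables alone: the head/body uniformity verdict
tallies, the count of fully passing head-phantom protocols, the per-material
failing-HU deviation summaries, the exposure-stability maximum range, and the
per-material head-phantom baselines.  Writes results/table_scorecards.csv and
results/table_summary.json.
"""

import json
from pathlib import Path

from phantomqa import report, tables
from phantomqa.criteria import (
    build_baseline,
    default_config,
    exposure_stability,
    summarize_failures,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
HU_MATERIALS = ("acrylic", "air", "bone", "polyethylene", "water")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = default_config()
    t2 = tables.load_protocol_scorecards()
    scored = report.score_table(t2, config)
    scored.to_csv(RESULTS / "table_scorecards.csv", index=False)

    summary = {}
    for phantom in ("head", "body"):
        sub = scored[scored["phantom"] == phantom]
        levels = sub["hu_uniformity_verdict"].value_counts().to_dict()
        summary[f"{phantom}_uniformity_tally"] = {
            lvl: int(levels.get(lvl, 0)) for lvl in ("pass", "minor", "major")
        }
        summary[f"{phantom}_fully_passing"] = int(sub["overall_pass"].sum())
        print(f"{phantom}: uniformity {summary[f'{phantom}_uniformity_tally']}, "
              f"{summary[f'{phantom}_fully_passing']}/11 protocols fully passing")

    body = t2[t2["phantom"] == "body"]
    summary["failing_hu_summaries"] = {}
    for mat in ("acrylic", "bone", "water"):
        s = summarize_failures(body[mat], config.hu_ranges[mat])
        summary["failing_hu_summaries"][mat] = {
            "n": s.n_failing, "mean": round(s.mean, 1), "sd": round(s.sd, 1)
        }
        print(f"body {mat}: {s.n_failing} failing, {s.mean:.1f} +/- {s.sd:.1f} HU beyond band")

    t3 = tables.load_exposure_series()
    table = {p: {m: g[m].tolist() for m in HU_MATERIALS} for p, g in t3.groupby("protocol")}
    rng, where = exposure_stability(table)
    summary["exposure_stability"] = {"max_range_hu": round(rng, 1), "at": list(where)}
    print(f"exposure stability: max CT-number range {rng:.1f} HU at {where}")

    head = t2[t2["phantom"] == "head"]
    bl = build_baseline({m: head[m].tolist() for m in HU_MATERIALS})
    summary["head_baselines_hu"] = {m: round(v, 1) for m, v in bl.baselines.items()}
    print("head-phantom baselines:", summary["head_baselines_hu"])

    (RESULTS / "table_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"wrote {RESULTS / 'table_scorecards.csv'} and table_summary.json")


if __name__ == "__main__":
    main()
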