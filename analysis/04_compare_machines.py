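#!/usr/bin/env python
"""Machine comparison over the published four-scanner table.

Scores every machine/protocol row and reports the per-row count of criteria
met at the no-deviation level — the ring-gantry CBCT under test and the
diagnostic CT both reach 9/9 on the Head protocol, against 4/9 (C-arm CBCT)
and 3/9 (previous ring-gantry CBCT).  Writes results/machine_comparison.csv.
"""

from pathlib import Path

from phantomqa import report, tables

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    t4 = tables.load_machine_comparison()
    scored = report.score_table(t4)
    cols = ["protocol", "machine", "phantom", "n_no_deviation", "overall_pass"]
    out = scored[cols + [c for c in scored.columns if c.endswith("_verdict")]]
    out.to_csv(RESULTS / "machine_comparison.csv", index=False)

    for proto, grp in scored.groupby("protocol", sort=False):
        counts = ", ".join(
            f"{m}: {n}/9" for m, n in zip(grp["machine"], grp["n_no_deviation"])
        )
        print(f"{proto}: {counts}")
    print(f"wrote {RESULTS / 'machine_comparison.csv'}")


if __name__ == "__main__":
    main()
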