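# phantomqa

Automated image-quality analysis for the ACR CT accreditation phantom,
aimed at medical physicists benchmarking CT and linac-mounted CBCT systems
(e.g. a new ring-gantry CBCT against a diagnostic CT simulator).

The ACR phantom is a 20 cm × 16 cm cylinder (optional 33 cm body ring) with
four modules; from one scan of it the package computes the five accreditation
metrics and classifies each against the ACR pass / minor-deviation /
major-deviation bands:

| Metric | Definition | Default criterion |
|---|---|---|
| Contrast resolution | CNR = (ROI_A − ROI_B) / SD(ROI_B) | ≥ 1.0 (adult and pediatric head, adult body), ≥ 0.4 (pediatric body) |
| Spatial resolution | highest of 8 bar patterns (4–12 lp/cm) with modulation ≥ 0.25 | ≥ 6 lp/cm head-type, ≥ 5 lp/cm body-type |
| HU accuracy | mean HU of polyethylene, bone, acrylic, air, water inserts | water −7..7, acrylic 110..135, bone 850..970, air −1005..−970, poly −107..−84 HU |
| Image scaling | % error of the 100 mm ball-bearing separation | ≤ 1.0 % |
| HU uniformity | max \|peripheral − center\| of five equal ROIs | < 5 HU pass, 5–7 HU minor, > 7 HU major |

Three front doors:

* **`phantomqa` library** — phantom description (`phantom`), synthetic scan
  simulator with controllable degradations (`simulate`), DICOM/internal
  volume I/O (`series_io`), automatic phantom localization (`localize`),
  metrics (`metrics`), criteria engine (`criteria`), scorecards and
  machine/session comparison (`report`).
* **`phantomqa` CLI** — `simulate`, `analyze`, `score` (metric-table-only
  path), `compare`.
* **`analysis/` scripts** — numbered drivers that run the full study:
  simulate reference scans, analyze them, score the published benchmark
  tables (shipped in `phantomqa/data/`), compare machines; outputs land in
  `results/`.

## Worked example

Simulate a diagnostic-quality scan of the head phantom, analyze it and score
it as an adult-head protocol:

```sh
phantomqa simulate --preset clean --seed 1 -o scan.npz
phantomqa analyze scan.npz --protocol Head
```

which prints (one scorecard row, values rounded for display):

```
protocol  contrast_resolution  spatial_resolution  acrylic     air   bone  polyethylene  water  image_scaling  hu_uniformity ... n_no_deviation  overall_pass
    Head                  2.4                 8.0    118.5 -1000.0  908.4         -96.5   -1.4            0.0            2.0 ...              9          True
```

Reading: the 6 HU low-contrast rod stands 2.4 noise standard deviations above
background (CNR criterion ≥ 1.0); the 8 lp/cm bar pattern is the finest with
modulation ≥ 0.25 (criterion ≥ 6 for head protocols); all five insert means
sit inside their accreditation bands; the ball-bearing separation is correct
to < 0.05 % and the uniformity slab varies by 2.0 HU (< 5 HU) — all nine
criteria at the no-deviation level. The degraded preset
(`--preset degraded`: 25 HU noise, 9 HU cupping) instead fails contrast
resolution (CNR ≈ 0.3) and uniformity (≈ 9.6 HU, major deviation), the
signature of an uncorrected cone-beam acquisition.

Scoring a measured metric table needs no images:

```sh
phantomqa score metrics.csv -o scorecard.csv
```

with `metrics.csv` holding one row per protocol in the column order above.

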