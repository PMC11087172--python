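# Methods

## The phantom model

The package carries one canonical description of the ACR CT accreditation
phantom (`phantomqa.phantom`): a water-equivalent cylinder of 200 mm diameter
and 160 mm length, tiled by four 40 mm modules along the axis, with an
optional body ring extending the outer diameter to 330 mm. The phantom frame
is right-handed, in millimetres, x/y from the phantom axis and z measured
from the first module face.

Published drawings of the phantom do not give insert coordinates at the
precision a simulator needs, so the in-module layout is this package's own
documented convention, chosen to match ACR quality-control practice and kept
configurable:

* **HU module (z 0–40 mm)** — five 25 mm inserts (water, bone, acrylic, air,
  polyethylene) at radius 60 mm, spaced 72° starting at 12 o'clock. Nominal
  rendering HU: water 0, air −1000, acrylic +120, bone +910,
  polyethylene −95 — each the midpoint region of its accreditation band.
* **Low-contrast/CNR module (40–80 mm)** — a 25 mm rod 6 HU above the water
  background at (0, +25) mm; ROI A sits on the rod, ROI B mirrored through
  the center. 6 HU is the nominal contrast of the phantom's low-contrast
  rods and, with clinically realistic noise, yields CNR values in the range
  accreditation scorecards actually show (0.1–3).
* **Resolution module (80–120 mm)** — eight 12 mm square bar patterns at
  radius 55 mm, 45° apart, at 4, 5, 6, 7, 8, 9, 10 and 12 lp/cm (a bar =
  half the 10/f mm period), bars rendered at bone HU (+910) against water.
* **Uniformity module (120–160 mm)** — uniform water slab; five equal 400 mm²
  ROIs (center + 12/3/6/9 o'clock, peripheral ROI edges 10 mm inside the
  phantom boundary, i.e. centers at radius ≈ 78.7 mm); two 5 mm metal ball
  bearings (+2500 HU) at (±50, 0) mm — exactly 100 mm apart — placed 12 mm
  off the module's measurement plane so they never contaminate the
  uniformity ROIs.

HU-accuracy and CNR ROIs default to ~200 mm², uniformity ROIs to ~400 mm²,
per ACR CT quality-control documentation; all areas are arguments of
`nominal_roi_layout`. Metric planes average the three slices around each
module center (9 mm window at the default 3 mm slice thickness), which
reduces noise relative to a single-slice reading without crossing module
boundaries.

## The scan simulator

`render_volume` voxelizes the phantom: each voxel's HU is the area-weighted
mean of the materials it covers, computed on a sub-grid `supersample`× finer
per axis (default 4×) with three z sub-samples per slice for slice-thickness
averaging. Defaults: 0.4 mm in-plane spacing (inside the 0.417 mm Nyquist
limit of the 12 lp/cm pattern — a coarser request is honoured but recorded as
a warning in the volume metadata), 3 mm slices, field of view 30 mm beyond
the phantom.

`degrade` applies artifacts in a fixed order — geometry (magnification,
rotation, shift, by bilinear resampling), in-plane Gaussian blur of stated
FWHM, radial cupping, per-material HU bias, then i.i.d. Gaussian noise — and
is bit-reproducible given the parameters and seed. Each knob is the minimal
model of the artifact family one accreditation metric detects:

* **Blur** stands in for the system MTF; measured bar-pattern modulation
  decays with frequency essentially like the Gaussian MTF
  exp(−2π²σ²f²).
* **Cupping** is −A·min(1, (r/r_sat)²) with r_sat = 0.7× the phantom outer
  radius, applied to phantom voxels: zero on the axis, the full −A from
  r_sat to the edge. The saturation means the peripheral uniformity ROIs
  (just inside the boundary) read the nominal amplitude, so an injected
  cupping of A HU produces a uniformity result of ≈ A HU — the simulator
  knob is calibrated in the same units the metric reports.
* **Material bias** shifts voxels assigned (by nearest nominal HU within
  ±50) to a named material; blurred boundary voxels can be misassigned, but
  all measurement ROIs are interior.
* **Noise** is white Gaussian in HU, added last (so its ROI standard
  deviation equals the parameter); no quantum, streak or structured noise.

Not modelled: projection physics (scatter, beam hardening), reconstruction
algorithms, detector effects. Consequently a passing synthetic scorecard
shows the *analysis chain* is correct — ROI placement, statistics,
classification — not that any physical scanner passes; conversely the
parameter-recovery tests show each artifact magnitude is measured back
within its sampling tolerance.

Two presets define the reference conditions: **clean diagnostic**
(noise 2.5 HU, blur 0.6 mm FWHM, cupping 2 HU — ground truth inside every
band, full scorecard passes) and **degraded CBCT-like** (noise 25 HU, blur
0.8 mm, cupping 9 HU — fails contrast resolution and uniformity, the two
metrics that dominate real uncorrected cone-beam images, while geometry and
mean HU stay intact).

## Localization and measurement

The analyzer never assumes perfect setup. The phantom axis is the centroid
of the non-air mask (> −300 HU, interior holes such as the air insert
filled); the rotation comes from the ball-bearing axis (detected as the two
connected components above 1600 HU — comfortably above the +910 HU bone
bars and below the +2500 HU bearings — with sub-voxel intensity-weighted
centroids, folded to (−90°, 90°] because the bearing pair is symmetric
under a half turn); the z offset from the mask extent. Ambiguity (≠ 2 metal
components) is rejected with the count named, never guessed. Nominal ROIs
are mapped rigidly through this pose; metrics are invariant to known
misalignments within noise (property-tested).

Bar-pattern modulation is measured by sampling narrow strips along the known
bar and gap center lines (central 60 % of the patch, strips ±p/8 around each
line, bilinear interpolation), normalized by the nominal bar-gap contrast
and clipped to [0, 1]. A pattern is "resolved" at modulation ≥ 0.25 — a
fixed, documented surrogate for the by-eye visibility scoring of the
accreditation procedure; no exact equivalence with human readings is
claimed, and acceptance-style tests only use synthetic scans whose answer is
far from the threshold. The resolvable frequency requires every coarser
pattern to pass too, so a low-frequency dropout caps the score.

Statistics use the sample (n−1) standard deviation throughout; values are
rounded to one decimal only at the reporting layer.

## Criteria engine

Classification bands live in configuration (`data/acr_criteria.yaml`), never
in logic. Conventions, each consistent with every published scorecard row
the package ships:

* HU passing bands are inclusive; with no minor band configured (default),
  any value outside is a major deviation, matching the pass/fail language
  accreditation reports use for HU accuracy.
* Uniformity: pass strictly below 5 HU; minor on the closed interval
  [5, 7]; major above (4.98 passes, 5.10 is minor).
* CNR and resolution minima are inclusive and selected by the *protocol
  class* (adult/pediatric × head/body), independent of which phantom was
  scanned. The pediatric-body CNR minimum is 0.4; the others 1.0.
* Scaling tolerance defaults to 1.0 % — no explicit published bound is
  reproduced here; every value labelled passing in the shipped tables is
  ≤ 0.9 %. Flagged as a package default.

Deviation summaries report the mean ± sample SD of the distance from each
failing value to the nearest violated bound. One shipped summary (air) was
published measured from the opposite (lower) bound instead; the
`bound="lower"` option reproduces it and the discrepancy is noted at the
call sites.

Clinical baselines (mean per material over a session, ±50 HU acceptance)
are built per phantom — a HU baseline is meaningless across phantom sizes —
and applied by the comparison report alongside per-protocol no-deviation
counts and per-material session differences.

## Problem sizes and numerical choices

Full simulated scans are 575×575×53 voxels at 0.4 mm / 3 mm; resolution
studies render only the resolution module at 0.3 mm; parameter-recovery
studies run at 1.0 mm where no bar pattern is involved, with ≥ 20 seeds per
recovery. Geometric resampling and strip sampling are bilinear (order 1) to
avoid ringing at material boundaries; HU is clipped to [−1024, 3071] after
degradation; ties in classification cannot occur because the bands partition
the line.

## Known limitations

* The simulator is an image-domain twin, not a physics simulation; it cannot
  expose errors that only projection-space effects produce.
* Rotation estimation relies on the bearings and carries a 180° ambiguity;
  pitch/roll are not estimated (the phantom is assumed level, as in the
  physical setup).
* The 0.25 modulation threshold is a convention; automated and human
  resolution scores can legitimately differ by one pattern step.
* DICOM support covers only the geometry and rescale tags the analyzer
  needs; the DICOM writer rounds HU to integers (the internal `.npz` format
  is the lossless path).
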