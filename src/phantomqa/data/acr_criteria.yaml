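# Default ACR CT accreditation criteria used by the scoring engine.
#
# Provenance: HU passing bands are the ACR CT accreditation values published
# in the program's quality-control documentation (water -7..+7, acrylic
# 110..135, bone 850..970, air -1005..-970, polyethylene -107..-84 HU).
# CNR minima are per protocol class; the pediatric-body minimum is 0.4 and
# the others 1.0.  Spatial-resolution minima follow the older published
# recommendation of >= 6 lp/cm for head-type and >= 5 lp/cm for body-type
# protocols.  The image-scaling tolerance of 1.0 % is this package's
# documented default (see docs/methods.md); no explicit published bound is
# reproduced here.  All values are configuration, never hard-coded in logic.
hu_ranges:
  water: [-7.0, 7.0]
  acrylic: [110.0, 135.0]
  bone: [850.0, 970.0]
  air: [-1005.0, -970.0]
  polyethylene: [-107.0, -84.0]
hu_minor_bands: {}
uniformity:
  pass_below: 5.0
  minor_max: 7.0
cnr_min:
  adult_head: 1.0
  adult_body: 1.0
  pediatric_head: 1.0
  pediatric_body: 0.4
resolution_min:
  head: 6.0
  body: 5.0
scaling_tolerance_pct: 1.0
protocol_classes:
  Head: adult_head
  H&N: adult_head
  Thorax: adult_body
  Thorax slow: adult_body
  Breast: adult_body
  Abdomen: adult_body
  Abdomen large: adult_body
  Pelvis: adult_body
  Pelvis large: adult_body
  Pediatric head: pediatric_head
  Pediatric abdomen: pediatric_body
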