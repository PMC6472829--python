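# Anchors (promoter coordinate of the first PWM column), canonical windows
# (promoter interval where hits count for composition calls) and default
# score thresholds (bits) for the packaged element matrices.
Inr_dros:
  anchor: -2
  canonical_window: [-2, 4]
  threshold: 3.0
Inr_mamm:
  anchor: -2
  canonical_window: [-2, 5]
  threshold: 4.0
TATA:
  anchor: null
  canonical_window: [-40, -20]
  threshold: 5.0
BridgeI:
  anchor: 18
  canonical_window: [18, 22]
  threshold: 1.0
BridgeII:
  anchor: 30
  canonical_window: [30, 33]
  threshold: 3.0
DPE:
  anchor: 28
  canonical_window: [28, 33]
  threshold: 1.0
MTE:
  anchor: 18
  canonical_window: [18, 29]
  threshold: 4.0
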