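# Default ROB scoring criteria.
#
# Each component maps a raw measurement to a 1-5 sub-score via contiguous
# bands; the composite total (3-15) maps to a severity class. Touching band
# edges are resolved lower-inclusive unless a strict inequality is explicit
# (open-field top band strictly > 1000; body-weight-loss end bands strictly
# < 5 % and > 20 %). The 300-s Rotarod endpoint is the only latency scoring 5.
#
# min_open / max_open mark an exclusive edge; omitted edges are inclusive.
rotarod:
  - {score: 1, min: 0, max: 50}
  - {score: 2, min: 50, max: 100, min_open: true}
  - {score: 3, min: 100, max: 200, min_open: true}
  - {score: 4, min: 200, max: 300, min_open: true, max_open: true}
  - {score: 5, min: 300, max: 300}
openfield:
  - {score: 1, min: 0, max: 300, max_open: true}
  - {score: 2, min: 300, max: 500, max_open: true}
  - {score: 3, min: 500, max: 800, max_open: true}
  - {score: 4, min: 800, max: 1000}
  - {score: 5, min: 1000, max: .inf, min_open: true}
bwl:
  - {score: 5, min: -.inf, max: 5, max_open: true}
  - {score: 4, min: 5, max: 10, max_open: true}
  - {score: 3, min: 10, max: 15, max_open: true}
  - {score: 2, min: 15, max: 20}
  - {score: 1, min: 20, max: .inf, min_open: true}
severity:
  - {label: severe, min: 3, max: 6}
  - {label: moderate, min: 7, max: 10}
  - {label: mild, min: 11, max: 15}
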