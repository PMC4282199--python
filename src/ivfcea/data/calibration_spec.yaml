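# Calibration spec: recover the pathway parameters the published
# aggregates leave implicit by fitting the two-cycle cohort model to the
# six per-strategy targets (expected cost per couple, cumulative live
# births). Free parameters are exactly those absent from the published
# probability and unit-cost tables. Tied paths encode sharing: the frozen
# transfer is single-embryo in every strategy, so the double-transfer
# strategy's frozen twin rate is tied to the single-transfer twin rate.
# Per-strategy live-delivery and complication rates are free: the targets
# cannot be reproduced with a single shared conversion rate (see
# docs/methods.md, "Identifiability").
convention_search: true
cycles: 2
free_parameters:
- name: frozen_cycle_cost
  paths: [costs.frozen_cycle]
  lower: 0.0
  upper: 10000.0
- name: p_frozen_available
  paths: [strategies.*.p_frozen_available]
  lower: 0.0
  upper: 1.0
- name: p_ongoing_frozen
  paths: [strategies.*.p_ongoing_frozen]
  lower: 0.0
  upper: 1.0
- name: p_twin_set
  paths:
  - strategies.eSET.p_twin_given_ongoing
  - strategies.DxSET.p_twin_given_ongoing
  - strategies.DET.p_twin_frozen
  lower: 0.0
  upper: 1.0
- name: p_twin_det
  paths: [strategies.DET.p_twin_given_ongoing]
  lower: 0.0
  upper: 1.0
- name: p_live_set
  paths:
  - strategies.eSET.p_live_given_ongoing
  - strategies.DxSET.p_live_given_ongoing
  lower: 0.0
  upper: 1.0
- name: p_live_det
  paths: [strategies.DET.p_live_given_ongoing]
  lower: 0.0
  upper: 1.0
- name: p_complication_set
  paths:
  - strategies.eSET.p_complication
  - strategies.DxSET.p_complication
  lower: 0.0
  upper: 1.0
- name: p_complication_det
  paths: [strategies.DET.p_complication]
  lower: 0.0
  upper: 1.0
targets:
- {strategy: eSET, quantity: expected_cost, value: 14896.0, weight: 1.0}
- {strategy: eSET, quantity: live_births, value: 0.314, weight: 1.0}
- {strategy: DxSET, quantity: expected_cost, value: 16687.0, weight: 1.0}
- {strategy: DxSET, quantity: live_births, value: 0.43, weight: 1.0}
- {strategy: DET, quantity: expected_cost, value: 18952.0, weight: 1.0}
- {strategy: DET, quantity: live_births, value: 0.473, weight: 1.0}
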