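# Kinematic landmark targets for surrogate calibration: the upper-cervical
# flexion peak window of the active-muscle run, cross-scenario percent
# reductions at the end of the 150 ms event, and the qualitative curvature
# sequence gates.
peak_deg_window: [8.0, 9.0]
peak_ms_window: [95.0, 105.0]
at_time_ms: 150.0
reductions:
  - ["C1-C2", "active", "passive", 43.2]
  - ["C5-C6", "active", "passive", 7.0]
  - ["C0-C1", "active", "none", 55.0]
reduction_scale_pp: 5.0
require_inverted_s_before_ms: 110.0
require_mirrored_c_at_end: true
require_inverted_u_active: true
require_end_peak_scenarios: ["none", "passive"]
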