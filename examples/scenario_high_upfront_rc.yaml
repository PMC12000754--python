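# Scenario: a setting where NAC is traditionally used sparingly and most
# patients get upfront RC (high end of the plausible upfront-RC range,
# NAC share adjusted to its complement).
name: high_upfront_rc
overrides:
  p_rc_only_current: 0.811
  p_nac_rc_current: 0.189
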