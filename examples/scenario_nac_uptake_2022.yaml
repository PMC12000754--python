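# Scenario: NAC uptake at the most recent Swedish level (74% in 2022),
# with the upfront-RC share adjusted to its complement.
name: nac_uptake_2022
overrides:
  p_nac_rc_current: 0.74
  p_rc_only_current: 0.26
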