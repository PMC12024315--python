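# Healthy-reference bands for flow-profile flagging.
# Medians come from the healthy control cohort summary; the 3rd/97th
# percentile bounds are NOT published values — they are placeholders
# calibrated on the synthetic healthy generator and should be replaced
# with cohort-specific percentiles where available.
reference_ranges:
  dp_mmhg:    {median: 6.0,  p3: 2.0,  p97: 10.0, direction: high}
  vmax_mps:   {median: 1.2,  p3: 0.8,  p97: 1.6,  direction: high}
  angle_deg:  {median: 8.0,  p3: 2.0,  p97: 16.0, direction: high}
  nfd:        {median: 0.03, p3: 0.005, p97: 0.08, direction: high}
  wpd:        {median: 0.75, p3: 0.60, p97: 0.90, direction: low}
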