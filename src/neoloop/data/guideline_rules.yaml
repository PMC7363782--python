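# Reconstructed ward titration table: first matching row wins.
# SG bands in mmol/L (half-open [sg_lo, sg_hi)), trends in mmol/L per hour.
# magnitude: start dose (U/kg/h) for start_insulin, fractional step otherwise.
start_dose: 0.02
step_fraction: 0.5
rules:
  - {sg_lo: 0.0, sg_hi: 3.5, action: start_dextrose_review}
  - {sg_lo: 3.5, sg_hi: 4.0, action: stop_insulin}
  - {sg_lo: 4.0, sg_hi: 8.0, trend_hi: -1.0, action: decrease, magnitude: 0.5}
  - {sg_lo: 4.0, sg_hi: 8.0, trend_lo: -1.0, action: none}
  - {sg_lo: 8.0, sg_hi: 10.0, trend_lo: 0.5, action: increase, magnitude: 0.5}
  - {sg_lo: 8.0, sg_hi: 10.0, trend_hi: 0.5, action: none}
  - {sg_lo: 10.0, sg_hi: null, trend_hi: -1.0, action: none}
  - {sg_lo: 10.0, sg_hi: null, trend_lo: -1.0, action: start_insulin, magnitude: 0.02}
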