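# Final population PD model for children with heart failure: direct
# full-inhibition Imax model on the ANG II/ANG I ratio with measured
# enalaprilat concentrations as input; IIV on IC50 only.
population: paediatric
model:
  absorption: first_order
  disposition: 1cmt
  pd_link: direct
  inhibition: full
  hill: fixed1
fixed:
  e0: 0.19        # -
  ic50: 1.19      # ug/L
iiv_cv_percent:
  ic50: 59.92
correlations: []
errors:
  pd: {kind: proportional, b: 0.37}
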