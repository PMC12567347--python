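# Final population PK/PD model for healthy adults (single 20 mg oral
# dose of enalapril maleate; enalaprilat concentration + ANG II/ANG I
# ratio).  IIV given on the CV% scale of the lognormal random effects.
population: adult
model:
  absorption: transit
  disposition: 2cmt
  pd_link: effect_compartment
  inhibition: full
  hill: estimated
fixed:
  k_tr: 5.31      # 1/h
  mtt: 1.46       # h
  k_a: 1.19       # 1/h
  cl_f: 36.39     # L/h
  v1_f: 223.71    # L
  q_f: 6.38       # L/h
  v2_f: 108.26    # L
  k_e0: 0.48      # 1/h
  gamma: 2.02     # -
  e0: 0.043       # -
  ic50: 30.01     # ug/L
iiv_cv_percent:
  k_tr: 72.89
  mtt: 33.7
  cl_f: 30.17
  v1_f: 46.61
  e0: 141.9
  ic50: 79.35
correlations:
  - [v1_f, cl_f, 0.84]
errors:
  pk: {kind: combined, a: 0.42, b: 0.072}   # a in ug/L
  pd: {kind: proportional, b: 0.41}
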