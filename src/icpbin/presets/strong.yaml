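# "strong" SCM family: two well-separated direct parents of the outcome
# (X1, X2), each with an intervened upstream driver (X3 -> X1, X4 -> X2),
# plus one intervened pure-noise predictor (X5).  Environment 1 mean-shifts
# every non-parent by one noise SD; environment 0 is observational.
names: [X1, X2, X3, X4, X5]
edges:
  - [X3, X1, 0.8]
  - [X4, X2, 0.8]
  - [X1, Y, 1.5]
  - [X2, Y, -1.2]
outcome_intercept: 0.0
noise_scales: [1.0, 1.0, 1.0, 1.0, 1.0]
# X4's shift is negative so the two upstream shifts reinforce (rather than
# cancel) in the outcome's marginal, giving the family its strong power.
interventions:
  1:
    - [X3, shift, 1.0]
    - [X4, shift, -1.0]
    - [X5, shift, 1.0]
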