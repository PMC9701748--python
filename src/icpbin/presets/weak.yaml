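# "weak" SCM family: same graph as the strong family with attenuated
# outcome coefficients and half-SD shifts, for power/degradation studies.
names: [X1, X2, X3, X4, X5]
edges:
  - [X3, X1, 0.8]
  - [X4, X2, 0.8]
  - [X1, Y, 0.6]
  - [X2, Y, -0.5]
outcome_intercept: 0.0
noise_scales: [1.0, 1.0, 1.0, 1.0, 1.0]
interventions:
  1:
    - [X3, shift, 0.5]
    - [X4, shift, -0.5]
    - [X5, shift, 0.5]
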