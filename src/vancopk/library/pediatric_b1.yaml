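# Illustrative pediatric vancomycin model (cohort B style).
# One compartment with body weight as the only covariate, mirroring the
# weight-only clearance models reported as best performers in older children.
name: pediatric_b1
n_compartments: 1
cohort: B
description: >
  Illustrative 1-compartment pediatric model with allometric weight scaling
  only.
theta:
  CL: 4.0
  V1: 42.0
covariate_terms:
  - {parameter: CL, covariate: weight, kind: allometric, ref: 70.0, exp: 0.75}
  - {parameter: V1, covariate: weight, kind: allometric, ref: 70.0, exp: 1.0}
random_effects: [CL, V1]
omega:
  - [0.09, 0.0]
  - [0.0, 0.06]
residual_model: {kind: combined, sigma_add: 1.2, sigma_prop: 0.15}
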