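# Illustrative pediatric vancomycin model (cohort B style).
# Two compartments; clearance scaled by weight and proportional to estimated
# creatinine clearance (age-dispatched renal function rule).
name: pediatric_b2
n_compartments: 2
cohort: B
description: >
  Illustrative 2-compartment pediatric model with allometric weight scaling
  and creatinine clearance proportionality on clearance.
theta:
  CL: 3.3
  V1: 30.0
  Q: 6.0
  V2: 25.0
covariate_terms:
  - {parameter: CL, covariate: weight, kind: allometric, ref: 70.0, exp: 0.75}
  - {parameter: CL, covariate: creatinine_clearance, kind: proportional_to_crcl, ref: 120.0}
  - {parameter: V1, covariate: weight, kind: allometric, ref: 70.0, exp: 1.0}
  - {parameter: V2, covariate: weight, kind: allometric, ref: 70.0, exp: 1.0}
  - {parameter: Q, covariate: weight, kind: allometric, ref: 70.0, exp: 0.75}
random_effects: [CL, V1]
omega:
  - [0.11, 0.0]
  - [0.0, 0.09]
residual_model: {kind: combined, sigma_add: 1.2, sigma_prop: 0.16}
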