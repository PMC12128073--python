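# Illustrative neonatal vancomycin model variant (cohort A style).
# Slower-maturing clearance than neonatal_a1/a2; included so the cohort-A
# ensemble shows realistic between-model spread.
name: neonatal_a3
n_compartments: 1
cohort: A
description: >
  Illustrative 1-compartment neonatal model; weight, postmenstrual age and
  serum creatinine on clearance, slower maturation.
theta:
  CL: 4.2
  V1: 34.0
covariate_terms:
  - {parameter: CL, covariate: weight, kind: allometric, ref: 70.0, exp: 0.75}
  - {parameter: CL, covariate: postmenstrual_age, kind: hill_maturation, gamma: 3.8, tm50: 50.0}
  - {parameter: CL, covariate: serum_creatinine, kind: power, ref: 45.0, exp: -0.25}
  - {parameter: V1, covariate: weight, kind: allometric, ref: 70.0, exp: 1.0}
random_effects: [CL, V1]
omega:
  - [0.10, 0.0]
  - [0.0, 0.07]
residual_model: {kind: combined, sigma_add: 0.8, sigma_prop: 0.13}
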