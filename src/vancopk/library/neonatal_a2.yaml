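# Illustrative neonatal vancomycin model variant (cohort A style).
# Same covariate composition as neonatal_a1 with different typical values
# and maturation parameters; stands in for an independently published model.
name: neonatal_a2
n_compartments: 1
cohort: A
description: >
  Illustrative 1-compartment neonatal model; weight, postmenstrual age and
  serum creatinine on clearance, alternative parameterization.
theta:
  CL: 5.4
  V1: 45.0
covariate_terms:
  - {parameter: CL, covariate: weight, kind: allometric, ref: 70.0, exp: 0.75}
  - {parameter: CL, covariate: postmenstrual_age, kind: hill_maturation, gamma: 3.0, tm50: 45.0}
  - {parameter: CL, covariate: serum_creatinine, kind: power, ref: 35.0, exp: -0.35}
  - {parameter: V1, covariate: weight, kind: allometric, ref: 70.0, exp: 1.0}
random_effects: [CL, V1]
omega:
  - [0.12, 0.0]
  - [0.0, 0.08]
residual_model: {kind: combined, sigma_add: 1.0, sigma_prop: 0.15}
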