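# Illustrative neonatal vancomycin model (cohort A style).
# One compartment; clearance scaled allometrically by weight, matured by
# postmenstrual age (Hill), and modulated by serum creatinine. Parameters
# are the package authors' illustrative values, not a published model.
name: neonatal_a1
n_compartments: 1
cohort: A
description: >
  Illustrative 1-compartment neonatal model with weight, postmenstrual age
  and serum creatinine on clearance.
theta:
  CL: 4.8    # L/h per 70 kg, mature
  V1: 39.0   # L per 70 kg
covariate_terms:
  - {parameter: CL, covariate: weight, kind: allometric, ref: 70.0, exp: 0.75}
  - {parameter: CL, covariate: postmenstrual_age, kind: hill_maturation, gamma: 3.4, tm50: 47.7}
  - {parameter: CL, covariate: serum_creatinine, kind: power, ref: 40.0, exp: -0.30}
  - {parameter: V1, covariate: weight, kind: allometric, ref: 70.0, exp: 1.0}
random_effects: [CL, V1]
omega:
  - [0.09, 0.0]
  - [0.0, 0.06]
residual_model: {kind: combined, sigma_add: 0.8, sigma_prop: 0.12}
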