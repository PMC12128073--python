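# Methods

## Scope and design

`vancopk` evaluates how well the steady-state 24-hour vancomycin exposure
(AUC₂₄ₕ) of a pediatric patient can be estimated from sparse therapeutic
drug monitoring (TDM) data under different sampling designs. The design is
an *external evaluation*: candidate population-PK models are taken as
fixed (their fixed effects, covariate relationships, inter-individual
variability and residual error are inputs, never re-estimated) and applied
to patients via MAP Bayesian estimation. Because dense reference sampling
is unavailable in routine TDM, the per-patient reference exposure is a
*consensus truth*: the median, across all candidate models, of the AUC₂₄ₕ
estimated from the richest available design (one peak + one trough).

## Pharmacokinetic engine

Disposition is linear and time-invariant, with one or two compartments and
zero-order (infusion) input. The single-dose central concentration is the
standard exponential-sum infusion solution; for two compartments the
macro-rates λ₁, λ₂ are the roots of
λ² − (k₁₀+k₁₂+k₂₁)λ + k₁₀k₂₁ = 0. Multiple doses superpose (linearity),
and the steady state of a τ-periodic regimen is obtained in closed form by
geometric accumulation of each exponential term with factor
1/(1−e^(−λτ)). An adaptive ODE integration (SciPy `solve_ivp`, rtol
1e-10) is retained purely as a test oracle; agreement is verified to
relative error ≲1e-7 (with the denominator floored at 1e-6 mg/L so
fully-eliminated profiles do not inflate a meaningless relative error).

Covariate models are declarative multiplicative terms on the structural
parameters: power/allometric `(x/ref)^exp`, sigmoid maturation
`PMA^γ/(PMA^γ+TM50^γ)`, linear `1+slope·(x−ref)`, and proportionality to
creatinine clearance. Individual parameters are lognormal,
`P_i = P_typ·e^η`, the universal convention for this model class.
Michaelis–Menten elimination, absorption models and time-varying
covariates are out of scope.

Renal function dispatches on postnatal age: below 365 days an infant
height/SCr formula; at and above 365 days the bedside Schwartz equation
`CrCL = 0.413·height(cm)/SCr(mg/dL)` (SCr stored in µmol/L, converted at
88.4 µmol/L per mg/dL). The handoff at the age boundary is deliberately
discontinuous. The infant bracket is pluggable
(`crcl_boer(cov, formula=...)`); the bundled default uses the classic
infant constants k = 0.45 (term) / 0.33 (preterm) on height/SCr and is
documented as a stand-in default rather than an attributed literature
equation. No physiologic cap is applied to creatinine clearance.

## MAP Bayesian estimation

For observations yⱼ at steady-state times tⱼ, the individual random
effects η minimize the extended-least-squares objective

    OFV(η) = Σⱼ [(yⱼ − fⱼ(η))²/gⱼ(η)² + ln gⱼ(η)²] + ηᵀΩ⁻¹η,

where fⱼ is the model prediction and gⱼ the residual SD (additive,
proportional, or combined `g² = σ_add² + (σ_prop·f)²`). The ln g² term
makes proportional-error fits proper. With no observations the objective
reduces to the prior and the mode is η = 0 exactly — the a priori
scenario. The estimation target is the posterior mode, not the mean.

The optimizer is Nelder–Mead with `xatol = fatol = 1e-8` and a
deterministic multi-start: η = 0 plus four starts jittered by the prior
SDs from a fixed seed (default 2026). Ties break on lowest objective,
then smallest ‖η‖. These tolerances are a configuration of this package,
not a literature requirement. The optimizer is verified against a
10 001-point exhaustive grid on one-dimensional problems (agreement
≤1e-3, i.e. within the grid's own half-spacing) and against exact
recovery of a known η from two noise-free observations. Non-converged
fits are flagged and excluded downstream with a logged warning rather
than imputed.

## Exposure and performance metrics

For linear PK at steady state, AUC₂₄ₕ = daily dose / CL, independent of
the distribution volumes; a 0.01-h trapezoid integration over one
interval (×24/τ) is kept as a cross-check (agreement ≤0.5%). Target
attainment uses the 400–600 mg·h/L window with both boundaries inclusive
(the window is conventionally quoted without boundary semantics; the
choice is centralized in `vancopk.exposure`).

Performance per model × scenario against the consensus truth:

- rBias = 100·mean((pred−true)/true) — signed accuracy, acceptable
  within ±15%;
- rRMSE = 100·sqrt(mean(((pred−true)/true)²)) — precision, preferably
  <20%;
- 95% CI on rBias by patient-level nonparametric bootstrap (2 000
  resamples, percentile method, fixed seed);
- dosage-advice concordance: the fraction of patients whose scenario AUC
  and true AUC fall in the same window segment (both below → both advise
  an increase, both within → neither adjusts, both above → both advise a
  decrease). Two related statistics are reported because the phrase
  "patients not requiring dosage adjustment" admits two readings:
  `percent_no_adjustment` (both AUCs within the window) and
  `percent_concordant_advice` (advice agrees in any segment).

Rows are canonically sorted before metric computation so results are
invariant to patient input order, and all bootstrap and optimizer seeds
are fixed, making end-to-end runs byte-identical at a given seed.

## Synthetic cohorts

Only medians and ranges are available for the populations being
emulated, so distribution families are package choices, documented here
and overridable in `CohortConfig`:

- **Cohort A** (neonates, postnatal age <50 d): PNA ~ Uniform(3, 40) d;
  GA ~ Triangular(25.4, 37, 41.0) wk; PMA = GA + PNA/7; weight lognormal
  (σ=0.20) around a linear-in-PMA median, truncated to 0.7–4.2 kg; SCr
  lognormal (median 29, σ=0.35) truncated to 15–81 µmol/L; dose
  lognormal (median 12.0 mg/kg) truncated to 5.8–26.9 mg/kg; τ = 12 h
  (PMA <37 wk) or 10 h.
- **Cohort B** (infants/children, ≥50 d): PNA log-uniform over 50–6273 d;
  weight and height lognormal around age-driven growth medians, truncated
  to 2.3–74.6 kg; SCr lognormal (median 19, σ=0.40) truncated to
  6–103 µmol/L; dose lognormal (median 14.9 mg/kg) truncated to
  5.8–33.5 mg/kg; τ = 8 h (<12 y) or 12 h.

Weight is age-driven; SCr is drawn independently (the real correlation
structure is unreported). Observations are simulated at steady state by
construction (closed form), not by simulating the preceding dose
history: one peak drawn 0.1–1.5 h after the end of the 1-h infusion
(lognormal offset, median 0.5 h) and one trough uniformly in the last
10% of the interval; residual noise follows the generating model's error
model (optionally scaled by `noise_scale`), truncated below at
0.05 mg/L. An optional mode adds Gaussian minutes-scale error to the
*recorded* sample times to emulate time-registration uncertainty.
Hidden ground truth (the sampled η and the generator AUC,
daily dose/(CL_typ·e^(η_CL))) travels on the patient record but is never
read by estimation code.

The dosing intervals and sampling windows were set, together with the
bundled models' residual errors, so that the generated cohorts satisfy
the generator's own contracts — trough < peak in ≥99% of patients, and
≥95% of simulated troughs/peaks inside the observed pediatric
concentration ranges (0.8–48.5 and 13.2–76.7 mg/L) — while landing the
simulated trough/peak medians near the published pediatric TDM values
(≈13 and ≈30 mg/L in neonates, ≈9–11 and ≈28–30 mg/L in children) and
median exposures in the upper-400s to mid-500s mg·h/L. Shorter 6-h
intervals in small children place troughs too close to peaks for the
ordering contract under realistic variability, which is why the τ policy
uses 8–12 h.

What the generator does *not* emulate: within-day creatinine dynamics,
ECMO/renal-replacement physiology, continuous infusions, correlated
covariate errors, assay censoring below the quantification limit, and
model misspecification beyond the differences among the bundled models.
Passing tests therefore demonstrate internal consistency of the pipeline
and the qualitative scenario ordering under controlled conditions — not
clinical performance of any particular published model.

## Bundled model library

Five illustrative specs ship with the package: three neonatal
1-compartment models with weight (allometric 0.75), PMA maturation and
SCr power terms on clearance (`neonatal_a1..a3`, deliberately spread in
maturation speed so the ensemble shows realistic between-model
disagreement), one weight-only pediatric 1-compartment model
(`pediatric_b1`) and one 2-compartment pediatric model with weight and
creatinine-clearance terms (`pediatric_b2`). Parameters are the package
authors' choices calibrated to the cohort targets above; they are not
published models and carry no citation.

## Problem sizes and numerical choices

Default study sizes: evaluation cohorts of n = 100 per cohort with the
full four-scenario grid; low-noise parameter recovery at n = 200
(residual sigmas and generator noise both scaled ×0.05), which recovers
the generator AUC with |rBias| ≤ 2% and rRMSE < 5%; oracle checks at
100 (PK), 50 (AUC) and 20 (MAP grid) randomized cases. Degenerate
inputs are rejected eagerly: non-positive doses, concentrations or
covariates, τ ≤ infusion duration, overlapping infusions, singular Ω,
and even-count medians use the mean of the two middle values.
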