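"""Synthetic pediatric TDM cohorts.

Generates virtual patients with the demographic structure of two
pediatric vancomycin cohorts — neonates (cohort A, postnatal age < 50 d,
including preterm infants) and infants/children (cohort B, >= 50 d) —
together with intermittent-infusion regimens at steady state and one
noisy peak + one noisy trough concentration per patient.

Only covariate medians and ranges are available for the populations
being emulated, not full distributions; the families used here
(uniform postnatal age, triangular gestational age, age-driven
log-normal weight and height, log-normal serum creatinine, all
truncated to the published ranges) are documented defaults and fully
overridable through :class:`CohortConfig`.

Hidden ground truth (the sampled random effects and the generator AUC)
travels on the patient record but is never read by estimation code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict

from .bayes import Observation, ObservationSet
from .modelspec import ModelSpec, individual_params, typical_params
from .pk import CovariateRecord, Regimen, steady_state_conc


class CohortConfig(BaseModel):
    """Generator settings; defaults emulate the two study cohorts."""

    model_config = ConfigDict(extra="forbid")

    cohort: Literal["A", "B"] = "A"
    n_patients: int = 100
    generating_model: str = ""          # bundled-model name, informational

    # Cohort A covariates
    pna_range_a: tuple[float, float] = (3.0, 40.0)        # days
    ga_range: tuple[float, float] = (25.4, 41.0)          # weeks
    ga_mode: float = 37.0                                 # weeks
    weight_range_a: tuple[float, float] = (0.7, 4.2)      # kg
    weight_sigma_a: float = 0.20                          # lognormal SD
    scr_median_a: float = 29.0                            # µmol/L
    scr_sigma_a: float = 0.35
    scr_range_a: tuple[float, float] = (15.0, 81.0)
    dose_per_kg_median_a: float = 12.0                    # mg/kg
    dose_per_kg_range_a: tuple[float, float] = (5.8, 26.9)

    # Cohort B covariates
    pna_range_b: tuple[float, float] = (50.0, 6273.0)     # days, log-uniform
    weight_range_b: tuple[float, float] = (2.3, 74.6)
    weight_sigma_b: float = 0.18
    scr_median_b: float = 19.0
    scr_sigma_b: float = 0.40
    scr_range_b: tuple[float, float] = (6.0, 103.0)
    dose_per_kg_median_b: float = 14.9
    dose_per_kg_range_b: tuple[float, float] = (5.8, 33.5)

    dose_per_kg_sigma: float = 0.25
    female_fraction_a: float = 0.571
    female_fraction_b: float = 0.638

    infusion_duration: float = 1.0                        # h
    # Peak drawn this long after infusion end (lognormal, truncated)
    peak_offset_median: float = 0.5                       # h
    peak_offset_sigma: float = 0.6
    peak_offset_range: tuple[float, float] = (0.1, 1.5)
    # Trough drawn uniformly in the tail of the interval
    trough_window_fraction: float = 0.9
    # Residual noise multiplier on the generating model's sigmas
    noise_scale: float = 1.0
    # Optional time-registration error mode: recorded sample times get
    # N(0, sd) minutes of error relative to the true draw times.
    time_registration_sd_min: float = 0.0


@dataclass(frozen=True)
class PatientRecord:
    """One virtual patient: covariates, regimen, TDM samples, hidden truth."""

    id: str
    covariates: CovariateRecord
    regimen: Regimen
    observations: ObservationSet = field(default_factory=ObservationSet)
    true_eta: np.ndarray | None = None
    true_auc24: float | None = None        # generator ground truth, mg·h/L


def _lognormal_trunc(rng: np.random.Generator, median: float, sigma: float,
                     lo: float, hi: float) -> float:
    """Lognormal with given median, rejection-truncated to [lo, hi]."""
    for _ in range(1000):
        x = median * math.exp(sigma * rng.standard_normal())
        if lo <= x <= hi:
            return x
    return float(np.clip(median, lo, hi))


def _weight_median_a(pma: float) -> float:
    # Roughly linear intrauterine/early-postnatal growth, kg.
    return max(0.12 * (pma - 27.9) + 1.2, 0.7)


def _weight_median_b(age_years: float) -> float:
    months = age_years * 12.0
    if age_years < 1.0:
        return 3.4 + 0.5 * months
    if age_years < 10.0:
        return 2.0 * (age_years + 4.0)
    return 28.0 + 2.5 * (age_years - 10.0)


def _height_median_b(age_years: float) -> float:
    months = age_years * 12.0
    if age_years < 1.0:
        return 50.0 + 2.0 * months
    if age_years < 12.0:
        return 75.0 + 6.0 * (age_years - 1.0)
    return min(141.0 + 5.0 * (age_years - 12.0), 175.0)


def sample_patient(config: CohortConfig, rng: np.random.Generator,
                   patient_id: str = "P1") -> PatientRecord:
    """Draw covariates and a regimen (no observations yet)."""
    c = config
    if c.cohort == "A":
        pna = rng.uniform(*c.pna_range_a)
        ga = rng.triangular(c.ga_range[0], c.ga_mode, c.ga_range[1])
        pma = ga + pna / 7.0
        wt = _lognormal_trunc(rng, _weight_median_a(pma), c.weight_sigma_a,
                              *c.weight_range_a)
        ht = _lognormal_trunc(rng, 50.0 * (pma / 40.0) ** 0.8, 0.03,
                              30.0, 60.0)
        scr = _lognormal_trunc(rng, c.scr_median_a, c.scr_sigma_a,
                               *c.scr_range_a)
        sex = "female" if rng.random() < c.female_fraction_a else "male"
        cov = CovariateRecord(weight=wt, postnatal_age=pna,
                              gestational_age=ga, height=ht, sex=sex,
                              serum_creatinine=scr)
        tau = 12.0 if pma < 37.0 else 10.0
        dose_per_kg = _lognormal_trunc(rng, c.dose_per_kg_median_a,
                                       c.dose_per_kg_sigma,
                                       *c.dose_per_kg_range_a)
    else:
        lo, hi = c.pna_range_b
        pna = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        age_years = pna / 365.25
        wt = _lognormal_trunc(rng, _weight_median_b(age_years),
                              c.weight_sigma_b, *c.weight_range_b)
        ht = _lognormal_trunc(rng, _height_median_b(age_years), 0.04,
                              45.0, 190.0)
        scr = _lognormal_trunc(rng, c.scr_median_b, c.scr_sigma_b,
                               *c.scr_range_b)
        sex = "female" if rng.random() < c.female_fraction_b else "male"
        cov = CovariateRecord(weight=wt, postnatal_age=pna, height=ht,
                              sex=sex, serum_creatinine=scr)
        tau = 8.0 if age_years < 12.0 else 12.0
        dose_per_kg = _lognormal_trunc(rng, c.dose_per_kg_median_b,
                                       c.dose_per_kg_sigma,
                                       *c.dose_per_kg_range_b)
    dose = round(dose_per_kg * wt, 1)
    regimen = Regimen(maintenance_dose=dose, tau=tau,
                      infusion_duration=c.infusion_duration)
    return PatientRecord(id=patient_id, covariates=cov, regimen=regimen)


def simulate_observations(model: ModelSpec, patient: PatientRecord,
                          config: CohortConfig,
                          rng: np.random.Generator) -> PatientRecord:
    """Attach one noisy steady-state peak and trough plus hidden truth."""
    c = config
    tau = patient.regimen.tau
    t_inf = patient.regimen.infusion_duration

    trough_t = rng.uniform(c.trough_window_fraction * tau, tau - 0.05)
    off_hi = min(c.peak_offset_range[1], trough_t - t_inf - 0.5)
    offset = _lognormal_trunc(rng, c.peak_offset_median, c.peak_offset_sigma,
                              c.peak_offset_range[0], max(off_hi, 0.15))
    peak_t = t_inf + offset

    k = len(model.random_effects)
    omega = model.omega_matrix
    # eigh-based factor handles PSD (including zero) matrices exactly
    w, v = np.linalg.eigh(omega)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    eta = factor @ rng.standard_normal(k)
    params = individual_params(model, patient.covariates, eta)

    times = np.array([peak_t, trough_t])
    f = np.asarray(steady_state_conc(
        params, patient.regimen.maintenance_dose, tau, t_inf, times))
    g = c.noise_scale * np.asarray(model.residual_model.sd(f), dtype=float)
    y = np.maximum(f + g * rng.standard_normal(2), 0.05)

    rec_times = times.copy()
    if c.time_registration_sd_min > 0:
        rec_times = times + (c.time_registration_sd_min / 60.0) \
            * rng.standard_normal(2)
        rec_times = np.clip(rec_times, 0.0, tau - 1e-6)
    obs = ObservationSet((
        Observation(float(rec_times[0]), float(y[0]), "peak"),
        Observation(float(rec_times[1]), float(y[1]), "trough"),
    ))

    cl_idx = model.random_effects.index("CL") \
        if "CL" in model.random_effects else None
    cl_typ = typical_params(model, patient.covariates).CL
    cl_ind = cl_typ * math.exp(eta[cl_idx]) if cl_idx is not None else cl_typ
    true_auc = patient.regimen.daily_dose / cl_ind
    return replace(patient, observations=obs, true_eta=eta,
                   true_auc24=true_auc)


def generate_cohort(model: ModelSpec, config: CohortConfig,
                    seed: int | np.random.Generator = 0
                    ) -> list[PatientRecord]:
    """Full cohort: covariates, regimens and simulated observations."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    prefix = config.cohort
    out = []
    for i in range(config.n_patients):
        pat = sample_patient(config, rng, patient_id=f"{prefix}{i + 1:04d}")
        out.append(simulate_observations(model, pat, config, rng))
    return out
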