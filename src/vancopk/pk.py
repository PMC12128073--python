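"""Compartmental PK primitives for intermittent IV infusion.

Closed-form concentration solutions for one- and two-compartment linear
models under zero-order infusion input, single-dose superposition and
steady-state accumulation, plus pediatric renal-function estimates used
as model covariates.

Units throughout: concentrations mg/L, amounts mg, times h, volumes L,
clearances L/h, serum creatinine µmol/L (converted internally to mg/dL
where an equation requires it), creatinine clearance mL/min/1.73 m².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: µmol/L of creatinine per mg/dL (molar mass conversion).
SCR_UMOL_PER_MGDL = 88.4

#: Postnatal age (days) at which renal-function estimation switches from the
#: infant formula to the bedside Schwartz equation.
INFANT_CRCL_AGE_CUTOFF_DAYS = 365.0


@dataclass(frozen=True)
class CovariateRecord:
    """Patient covariates relevant to pediatric vancomycin PK.

    ``postmenstrual_age`` may be given directly or derived from
    gestational + postnatal age; when all three are present they must be
    mutually consistent (PMA = GA + PNA/7, tolerance 0.1 wk).
    """

    weight: float                      # kg
    postnatal_age: float               # days
    serum_creatinine: float            # µmol/L
    gestational_age: float | None = None   # weeks
    postmenstrual_age: float | None = None  # weeks
    height: float | None = None        # cm
    sex: str | None = None             # "female" | "male"
    creatinine_clearance: float | None = None  # mL/min/1.73 m², derived

    def __post_init__(self) -> None:
        for name in ("weight", "postnatal_age", "serum_creatinine",
                     "gestational_age", "postmenstrual_age", "height",
                     "creatinine_clearance"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"covariate {name!r} must be positive, got {v}")
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.postmenstrual_age is None and self.gestational_age is not None:
            object.__setattr__(
                self, "postmenstrual_age",
                self.gestational_age + self.postnatal_age / 7.0)
        elif (self.postmenstrual_age is not None
              and self.gestational_age is not None):
            expected = self.gestational_age + self.postnatal_age / 7.0
            if abs(self.postmenstrual_age - expected) > 0.1:
                raise ValueError(
                    "postmenstrual_age inconsistent with gestational + "
                    f"postnatal age: {self.postmenstrual_age} vs {expected:.2f} wk")

    @property
    def cohort(self) -> str:
        """'A' for postnatal age < 50 d, 'B' otherwise."""
        return "A" if self.postnatal_age < 50 else "B"


@dataclass(frozen=True)
class DoseEvent:
    amount: float            # mg
    start_time: float        # h
    infusion_duration: float  # h

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if not self.infusion_duration > 0:
            raise ValueError(
                f"infusion duration must be > 0, got {self.infusion_duration}")

    @property
    def end_time(self) -> float:
        return self.start_time + self.infusion_duration

    @property
    def rate(self) -> float:
        """Zero-order infusion rate, mg/h."""
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class Regimen:
    """A maintenance regimen: repeated dose every ``tau`` hours.

    ``dose_events`` holds the explicit event list for transient
    (non-steady-state) prediction; steady-state computations use
    ``maintenance_dose``, ``tau`` and ``infusion_duration`` directly.
    """

    maintenance_dose: float          # mg
    tau: float                       # h, inter-dose interval
    infusion_duration: float         # h
    dose_events: tuple[DoseEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.maintenance_dose > 0:
            raise ValueError("maintenance_dose must be > 0")
        if not self.tau > self.infusion_duration:
            raise ValueError(
                f"inter-dose interval tau={self.tau} must exceed infusion "
                f"duration {self.infusion_duration}")
        events = sorted(self.dose_events, key=lambda d: d.start_time)
        for a, b in zip(events, events[1:]):
            if b.start_time < a.end_time:
                raise ValueError(
                    f"overlapping infusions at t={a.start_time} and "
                    f"t={b.start_time} h")
        object.__setattr__(self, "dose_events", tuple(events))

    @property
    def daily_dose(self) -> float:
        """mg administered per 24 h."""
        return self.maintenance_dose * 24.0 / self.tau

    @classmethod
    def repeated(cls, dose: float, tau: float, infusion_duration: float,
                 n_doses: int) -> "Regimen":
        """Explicit event list of ``n_doses`` doses starting at t=0."""
        events = tuple(
            DoseEvent(dose, i * tau, infusion_duration) for i in range(n_doses))
        return cls(dose, tau, infusion_duration, events)


@dataclass(frozen=True)
class StructuralParams:
    """Individual (or typical) structural parameters.

    Q and V2 are None for one-compartment models.
    """

    CL: float                # L/h
    V1: float                # L
    Q: float | None = None   # L/h
    V2: float | None = None  # L

    def __post_init__(self) -> None:
        for name in ("CL", "V1"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if (self.Q is None) != (self.V2 is None):
            raise ValueError("Q and V2 must be given together or not at all")
        if self.Q is not None:
            for name in ("Q", "V2"):
                v = getattr(self, name)
                if not (np.isfinite(v) and v > 0):
                    raise ValueError(f"{name} must be positive, got {v}")

    @property
    def n_compartments(self) -> int:
        return 1 if self.Q is None else 2

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V1, 1/h."""
        return self.CL / self.V1


def _disposition(params: StructuralParams) -> tuple[np.ndarray, np.ndarray]:
    """Exponential rates lambda_i and unit-rate infusion coefficients.

    Returns (lams, coefs) such that the concentration after a single
    infusion at rate R0 starting at t=0 is

        C(t) = R0 * sum_i coefs[i] * (1 - exp(-lams[i]*te)) * exp(-lams[i]*td)

    with te = min(t, t_inf) elapsed infusion time and td = max(0, t - t_inf).
    At steady infusion, C_ss = R0 * sum(coefs) = R0 / CL.
    """
    if params.n_compartments == 1:
        lam = params.CL / params.V1
        return np.array([lam]), np.array([1.0 / params.CL])
    k10 = params.CL / params.V1
    k12 = params.Q / params.V1
    k21 = params.Q / params.V2
    s = k10 + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    # Coefficients of the central-compartment infusion response.
    c1 = (k21 - lam1) / (lam1 * (lam2 - lam1)) / params.V1
    c2 = (k21 - lam2) / (lam2 * (lam1 - lam2)) / params.V1
    return np.array([lam1, lam2]), np.array([c1, c2])


def conc(params: StructuralParams, regimen: Regimen,
         t: float | Sequence[float]) -> np.ndarray | float:
    """Concentration (mg/L) at time(s) ``t`` from the explicit dose-event list.

    Superposition of per-dose zero-order-infusion solutions. Times before
    the first dose return 0.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    lams, coefs = _disposition(params)
    out = np.zeros_like(t_arr)
    for ev in regimen.dose_events:
        dt = t_arr - ev.start_time
        active = dt > 0
        if not np.any(active):
            continue
        te = np.minimum(dt[active], ev.infusion_duration)
        td = np.maximum(dt[active] - ev.infusion_duration, 0.0)
        contrib = ev.rate * np.sum(
            coefs[None, :] * (1.0 - np.exp(-lams[None, :] * te[:, None]))
            * np.exp(-lams[None, :] * td[:, None]), axis=1)
        out[active] += contrib
    out = np.maximum(out, 0.0)
    return out if np.ndim(t) else float(out[0])


def steady_state_conc(params: StructuralParams, dose: float, tau: float,
                      t_inf: float,
                      t: float | Sequence[float]) -> np.ndarray | float:
    """Steady-state concentration at time ``t`` within the dosing interval.

    ``t`` is measured from the start of an infusion; 0 <= t < tau.
    Closed form: each exponential term of the single-dose response
    accumulates geometrically with factor 1/(1 - exp(-lambda*tau)).
    """
    if not tau > t_inf:
        raise ValueError(f"tau={tau} must exceed infusion duration {t_inf}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any((t_arr < 0) | (t_arr >= tau)):
        raise ValueError("t must satisfy 0 <= t < tau")
    lams, coefs = _disposition(params)
    R0 = dose / t_inf
    te = np.minimum(t_arr, t_inf)
    td = np.maximum(t_arr - t_inf, 0.0)
    lam = lams[None, :]
    acc = 1.0 / (1.0 - np.exp(-lam * tau))
    # Current dose (partial if still infusing) + geometric tail of prior doses.
    current = (1.0 - np.exp(-lam * te[:, None])) * np.exp(-lam * td[:, None])
    prior = ((1.0 - np.exp(-lam * t_inf))
             * np.exp(-lam * (t_arr[:, None] - t_inf + tau)) * acc)
    out = R0 * np.sum(coefs[None, :] * (current + prior), axis=1)
    return out if np.ndim(t) else float(out[0])


def crcl_schwartz(height: float, serum_creatinine: float) -> float:
    """Bedside Schwartz estimate of creatinine clearance.

    CrCL (mL/min/1.73 m²) = 0.413 * height(cm) / SCr(mg/dL),
    with SCr supplied in µmol/L and converted internally.
    """
    if not height > 0:
        raise ValueError(f"height must be > 0, got {height}")
    if not serum_creatinine > 0:
        raise ValueError(f"serum_creatinine must be > 0, got {serum_creatinine}")
    scr_mgdl = serum_creatinine / SCR_UMOL_PER_MGDL
    return 0.413 * height / scr_mgdl


def _infant_crcl_default(cov: CovariateRecord) -> float:
    """Default infant (<1 y) creatinine-clearance estimate.

    Height/SCr formula with the classic infant constants (k = 0.45 for
    term, 0.33 for preterm infants, SCr in mg/dL). This is a documented
    stand-in default for the infant age bracket; the dispatch hook
    ``crcl_boer`` accepts any replacement formula.
    """
    if cov.height is None:
        raise ValueError("infant creatinine clearance requires height")
    preterm = cov.gestational_age is not None and cov.gestational_age < 37.0
    k = 0.33 if preterm else 0.45
    scr_mgdl = cov.serum_creatinine / SCR_UMOL_PER_MGDL
    return k * cov.height / scr_mgdl


def crcl_boer(cov: CovariateRecord, formula=None) -> float:
    """Creatinine clearance for infants (postnatal age < 365 d).

    Pluggable: pass ``formula(cov) -> float`` to substitute the estimate;
    the bundled default is :func:`_infant_crcl_default`.
    """
    fn = formula if formula is not None else _infant_crcl_default
    value = fn(cov)
    if not value > 0:
        raise ValueError(f"creatinine clearance must be positive, got {value}")
    return value


def creatinine_clearance(cov: CovariateRecord, infant_formula=None) -> float:
    """Age-dispatched creatinine clearance (mL/min/1.73 m²).

    Infant formula below 365 d postnatal age, bedside Schwartz at and
    above 365 d (the boundary day goes to Schwartz). The handoff is
    deliberately discontinuous; no smoothing is applied.
    """
    if cov.creatinine_clearance is not None:
        return cov.creatinine_clearance
    if cov.postnatal_age < INFANT_CRCL_AGE_CUTOFF_DAYS:
        return crcl_boer(cov, formula=infant_formula)
    if cov.height is None:
        raise ValueError("Schwartz creatinine clearance requires height")
    return crcl_schwartz(cov.height, cov.serum_creatinine)
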