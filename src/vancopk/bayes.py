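"""MAP Bayesian estimation of individual PK parameters.

Given a population model (taken as fixed — the external-evaluation
setting, where published models are applied, never re-estimated) and up
to two steady-state TDM concentrations, the individual random effects
eta are estimated as the posterior mode:

    OFV(eta) = sum_j [ (y_j - f_j(eta))^2 / g_j^2 + ln g_j^2 ]
               + eta' Omega^{-1} eta

with f_j the model-predicted concentration at observation j and g_j the
residual SD there (extended-least-squares form, so proportional and
combined error models are penalized for their prediction-dependent
variance). With no observations the objective reduces to the prior and
the mode is eta = 0 — the a priori scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .modelspec import ModelSpec, individual_params, typical_params
from .pk import CovariateRecord, Regimen, StructuralParams, steady_state_conc

SCENARIOS = ("peak+trough", "peak", "trough", "a priori")


@dataclass(frozen=True)
class Observation:
    time: float           # h after start of infusion, within [0, tau)
    concentration: float  # mg/L
    label: str            # "peak" | "trough"

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError(
                f"observed concentration must be > 0, got {self.concentration}")
        if self.label not in ("peak", "trough"):
            raise ValueError(f"label must be 'peak' or 'trough', got {self.label!r}")


@dataclass(frozen=True)
class ObservationSet:
    """Zero, one or two labelled steady-state samples."""

    observations: tuple[Observation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))

    def __len__(self) -> int:
        return len(self.observations)

    def subset(self, labels: Sequence[str]) -> "ObservationSet":
        return ObservationSet(tuple(o for o in self.observations
                                    if o.label in labels))

    def for_scenario(self, scenario: str) -> "ObservationSet":
        """Observations entering a TDM scenario."""
        if scenario == "a priori":
            return ObservationSet(())
        if scenario == "peak+trough":
            return self
        if scenario in ("peak", "trough"):
            return self.subset([scenario])
        raise ValueError(f"unknown scenario {scenario!r}; expected {SCENARIOS}")

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([o.concentration for o in self.observations])


@dataclass(frozen=True)
class IndividualFit:
    """Result of one MAP estimation (one patient x model x scenario)."""

    eta_hat: np.ndarray
    individual_params: StructuralParams
    ofv: float
    scenario: str
    converged: bool
    n_obs: int = 0


def _predict(model: ModelSpec, cov: CovariateRecord, regimen: Regimen,
             times: np.ndarray, eta: np.ndarray) -> np.ndarray:
    params = individual_params(model, cov, eta)
    return np.asarray(steady_state_conc(
        params, regimen.maintenance_dose, regimen.tau,
        regimen.infusion_duration, times))


def map_objective(model: ModelSpec, cov: CovariateRecord, regimen: Regimen,
                  obs: ObservationSet, eta: np.ndarray) -> float:
    """Extended-least-squares MAP objective; see module docstring."""
    eta = np.asarray(eta, dtype=float)
    k = len(model.random_effects)
    if eta.shape != (k,):
        raise ValueError(f"eta must have shape ({k},), got {eta.shape}")
    omega = model.omega_matrix
    try:
        omega_inv = np.linalg.inv(omega)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"model {model.name!r}: omega is singular; supply a positive "
            "definite IIV matrix or configure a pseudo-inverse explicitly"
        ) from err
    ofv = float(eta @ omega_inv @ eta)
    if len(obs) > 0:
        f = _predict(model, cov, regimen, obs.times, eta)
        g = np.asarray(model.residual_model.sd(f), dtype=float)
        if np.any(g <= 0):
            raise ValueError("residual SD must be positive at all predictions")
        resid = obs.concentrations - f
        ofv += float(np.sum(resid ** 2 / g ** 2 + np.log(g ** 2)))
    return ofv


@dataclass
class MAPBayes:
    """MAP Bayesian estimation problem for one patient under one model.

    statsmodels-style: construct from data, call :meth:`fit` to obtain an
    :class:`IndividualFit`. The optimizer runs a deterministic multi-start
    local search (eta = 0 plus ``n_jitter`` jittered starts drawn from the
    prior with a fixed seed); ties break on lowest objective, then
    smallest ``||eta||``.
    """

    model: ModelSpec
    covariates: CovariateRecord
    regimen: Regimen
    observations: ObservationSet = field(default_factory=ObservationSet)
    n_jitter: int = 4
    seed: int = 2026
    xtol: float = 1e-8

    def objective(self, eta: np.ndarray) -> float:
        return map_objective(self.model, self.covariates, self.regimen,
                             self.observations, eta)

    def _fast_objective(self, obs: ObservationSet):
        """Same value as :func:`map_objective`, with per-patient constants
        (typical params, prior precision) hoisted out of the optimizer loop."""
        model, regimen = self.model, self.regimen
        typ = typical_params(model, self.covariates)
        base = np.array([typ.CL, typ.V1,
                         typ.Q if typ.Q is not None else np.nan,
                         typ.V2 if typ.V2 is not None else np.nan])
        idx = {"CL": 0, "V1": 1, "Q": 2, "V2": 3}
        re_idx = np.array([idx[p] for p in model.random_effects])
        omega_inv = np.linalg.inv(model.omega_matrix)
        times = obs.times
        y = obs.concentrations
        resid_sd = model.residual_model.sd
        two_cmt = model.n_compartments == 2

        def fun(eta: np.ndarray) -> float:
            vals = base.copy()
            vals[re_idx] *= np.exp(eta)
            if two_cmt:
                params = StructuralParams(CL=vals[0], V1=vals[1], Q=vals[2],
                                          V2=vals[3])
            else:
                params = StructuralParams(CL=vals[0], V1=vals[1])
            f = np.asarray(steady_state_conc(
                params, regimen.maintenance_dose, regimen.tau,
                regimen.infusion_duration, times))
            g = np.asarray(resid_sd(f), dtype=float)
            r = y - f
            return float(np.sum(r * r / (g * g) + np.log(g * g))
                         + eta @ omega_inv @ eta)

        return fun

    def fit(self, scenario: str | None = None) -> IndividualFit:
        obs = (self.observations if scenario is None
               else self.observations.for_scenario(scenario))
        label = scenario or ("a priori" if len(obs) == 0 else "peak+trough")
        k = len(self.model.random_effects)
        if len(obs) == 0:
            eta0 = np.zeros(k)
            return IndividualFit(
                eta_hat=eta0,
                individual_params=typical_params(self.model, self.covariates),
                ofv=0.0, scenario=label, converged=True, n_obs=0)

        fun = self._fast_objective(obs)
        rng = np.random.default_rng(self.seed)
        omega = self.model.omega_matrix
        sd = np.sqrt(np.clip(np.diag(omega), 1e-12, None))
        starts = [np.zeros(k)]
        starts += [rng.standard_normal(k) * sd for _ in range(self.n_jitter)]

        best = None
        for x0 in starts:
            res = minimize(fun, x0, method="Nelder-Mead",
                           options={"xatol": self.xtol, "fatol": self.xtol,
                                    "maxiter": 2000})
            cand = (res.fun, float(np.linalg.norm(res.x)), res.x, res.success)
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
        ofv, _, eta_hat, success = best
        # Re-evaluate so the reported OFV is exactly map_objective(eta_hat).
        ofv = map_objective(self.model, self.covariates, self.regimen, obs,
                            eta_hat)
        converged = bool(success and np.isfinite(ofv))
        return IndividualFit(
            eta_hat=np.asarray(eta_hat),
            individual_params=individual_params(self.model, self.covariates,
                                                eta_hat),
            ofv=ofv, scenario=label, converged=converged, n_obs=len(obs))


def estimate_map(model: ModelSpec, cov: CovariateRecord, regimen: Regimen,
                 obs: ObservationSet, **kwargs) -> IndividualFit:
    """Functional entry point; equivalent to ``MAPBayes(...).fit()``."""
    return MAPBayes(model, cov, regimen, obs, **kwargs).fit()
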