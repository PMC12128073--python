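"""Declarative population-PK model specifications.

A ``ModelSpec`` describes one published-style popPK model: compartment
structure, fixed-effect typical values, multiplicative covariate terms per
structural parameter, a lognormal inter-individual variability (IIV)
covariance matrix, and a residual-error model. Specs round-trip through
YAML files so a model library can be maintained as plain text.

Covariate grammar
-----------------
Each term multiplies one structural parameter:

``power``               (x/ref)**exp
``allometric``          (x/ref)**exp with a fixed, literature-style exponent
``hill_maturation``     x**gamma / (x**gamma + tm50**gamma)
``linear``              1 + slope*(x - ref)
``proportional_to_crcl``  CrCL/ref, with CrCL derived by the age-dispatched
                          renal-function rule if not supplied directly
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .pk import CovariateRecord, StructuralParams, creatinine_clearance

STRUCTURAL_PARAMS_1CMT = ("CL", "V1")
STRUCTURAL_PARAMS_2CMT = ("CL", "V1", "Q", "V2")

TermKind = Literal["power", "allometric", "hill_maturation", "linear",
                   "proportional_to_crcl"]

_COVARIATE_FIELDS = ("weight", "postnatal_age", "gestational_age",
                     "postmenstrual_age", "height", "serum_creatinine",
                     "creatinine_clearance")


class CovariateTerm(BaseModel):
    """One multiplicative covariate effect on a structural parameter."""

    model_config = ConfigDict(extra="forbid")

    parameter: str                    # structural parameter the term scales
    covariate: str                    # CovariateRecord field name
    kind: TermKind
    ref: float | None = None          # reference covariate value
    exp: float | None = None          # power / allometric exponent
    gamma: float | None = None        # Hill coefficient
    tm50: float | None = None         # maturation half-time, same unit as cov
    slope: float | None = None        # linear slope per covariate unit

    @field_validator("covariate")
    @classmethod
    def _known_covariate(cls, v: str) -> str:
        if v not in _COVARIATE_FIELDS:
            raise ValueError(f"unknown covariate {v!r}")
        return v

    @model_validator(mode="after")
    def _required_parameters(self) -> "CovariateTerm":
        need = {"power": ("ref", "exp"), "allometric": ("ref", "exp"),
                "hill_maturation": ("gamma", "tm50"),
                "linear": ("ref", "slope"),
                "proportional_to_crcl": ("ref",)}[self.kind]
        missing = [n for n in need if getattr(self, n) is None]
        if missing:
            raise ValueError(f"{self.kind} term requires {missing}")
        if self.kind == "proportional_to_crcl" and \
                self.covariate != "creatinine_clearance":
            raise ValueError(
                "proportional_to_crcl terms must reference creatinine_clearance")
        return self

    def multiplier(self, cov: CovariateRecord) -> float:
        x = _covariate_value(cov, self.covariate)
        if self.kind in ("power", "allometric"):
            m = (x / self.ref) ** self.exp
        elif self.kind == "hill_maturation":
            xg = x ** self.gamma
            m = xg / (xg + self.tm50 ** self.gamma)
        elif self.kind == "linear":
            m = 1.0 + self.slope * (x - self.ref)
        else:  # proportional_to_crcl
            m = x / self.ref
        if not (math.isfinite(m) and m > 0):
            raise ValueError(
                f"covariate term {self.kind} on {self.parameter} yielded "
                f"non-positive multiplier {m} for {self.covariate}={x}")
        return m


def _covariate_value(cov: CovariateRecord, name: str) -> float:
    if name == "creatinine_clearance":
        return creatinine_clearance(cov)
    v = getattr(cov, name)
    if v is None:
        raise ValueError(f"covariate {name!r} missing from patient record")
    return v


class ResidualErrorModel(BaseModel):
    """Residual unexplained variability of assayed concentrations.

    SD of one observation with prediction f:
    additive sigma_add; proportional sigma_prop*f;
    combined sqrt(sigma_add^2 + (sigma_prop*f)^2).
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["additive", "proportional", "combined"]
    sigma_add: float = 0.0    # mg/L
    sigma_prop: float = 0.0   # fraction

    @model_validator(mode="after")
    def _positive_variance(self) -> "ResidualErrorModel":
        if self.kind in ("additive", "combined") and not self.sigma_add > 0:
            raise ValueError("sigma_add must be > 0 for this error model")
        if self.kind in ("proportional", "combined") and not self.sigma_prop > 0:
            raise ValueError("sigma_prop must be > 0 for this error model")
        return self

    def sd(self, f: np.ndarray | float) -> np.ndarray | float:
        if self.kind == "additive":
            return np.full_like(np.asarray(f, dtype=float), self.sigma_add) \
                if np.ndim(f) else self.sigma_add
        if self.kind == "proportional":
            return self.sigma_prop * np.asarray(f, dtype=float) \
                if np.ndim(f) else self.sigma_prop * f
        return np.sqrt(self.sigma_add ** 2
                       + (self.sigma_prop * np.asarray(f, dtype=float)) ** 2)


class ModelSpec(BaseModel):
    """Complete description of one population-PK model."""

    model_config = ConfigDict(extra="forbid")

    name: str
    n_compartments: Literal[1, 2]
    theta: dict[str, float]                 # typical values per parameter
    covariate_terms: list[CovariateTerm] = []
    random_effects: list[str] = ["CL", "V1"]  # parameters carrying IIV (eta)
    omega: list[list[float]] = []           # IIV covariance, log scale
    residual_model: ResidualErrorModel
    cohort: Literal["A", "B", "AB"] = "AB"
    description: str = ""

    @model_validator(mode="after")
    def _validate(self) -> "ModelSpec":
        required = (STRUCTURAL_PARAMS_1CMT if self.n_compartments == 1
                    else STRUCTURAL_PARAMS_2CMT)
        missing = [p for p in required if p not in self.theta]
        if missing:
            raise ValueError(f"theta missing structural parameters {missing}")
        for p, v in self.theta.items():
            if p not in required:
                raise ValueError(f"theta has unknown parameter {p!r}")
            if not v > 0:
                raise ValueError(f"theta[{p!r}] must be > 0, got {v}")
        for term in self.covariate_terms:
            if term.parameter not in required:
                raise ValueError(
                    f"covariate term targets unknown parameter "
                    f"{term.parameter!r}")
        for p in self.random_effects:
            if p not in required:
                raise ValueError(f"random effect on unknown parameter {p!r}")
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (len(self.random_effects), len(self.random_effects)):
            raise ValueError(
                f"omega must be {len(self.random_effects)}x"
                f"{len(self.random_effects)}, got shape {om.shape}")
        if not np.allclose(om, om.T):
            raise ValueError("omega must be symmetric")
        eig = np.linalg.eigvalsh(om)
        if np.min(eig) < -1e-10:
            raise ValueError("omega must be positive semidefinite")
        return self

    @property
    def omega_matrix(self) -> np.ndarray:
        return np.asarray(self.omega, dtype=float)

    def required_covariates(self) -> set[str]:
        out = set()
        for term in self.covariate_terms:
            out.add(term.covariate)
        return out


def typical_params(model: ModelSpec, cov: CovariateRecord) -> StructuralParams:
    """Population-typical structural parameters for a patient.

    Each parameter is theta_p times the product of its covariate-term
    multipliers. Raises naming the covariate and model if one is missing.
    """
    values = dict(model.theta)
    for term in model.covariate_terms:
        try:
            values[term.parameter] *= term.multiplier(cov)
        except ValueError as err:
            raise ValueError(f"model {model.name!r}: {err}") from err
    if model.n_compartments == 1:
        return StructuralParams(CL=values["CL"], V1=values["V1"])
    return StructuralParams(CL=values["CL"], V1=values["V1"],
                            Q=values["Q"], V2=values["V2"])


def individual_params(model: ModelSpec, cov: CovariateRecord,
                      eta: np.ndarray) -> StructuralParams:
    """Individual parameters P_i = P_typical * exp(eta) on IIV'd parameters."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(model.random_effects),):
        raise ValueError(
            f"eta must have length {len(model.random_effects)}, "
            f"got shape {eta.shape}")
    typ = typical_params(model, cov)
    values = {"CL": typ.CL, "V1": typ.V1, "Q": typ.Q, "V2": typ.V2}
    for p, e in zip(model.random_effects, eta):
        values[p] = values[p] * math.exp(e)
    return StructuralParams(**values)


def load_model(path) -> ModelSpec:
    """Read a model spec from a YAML file, validating the schema."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: model spec must be a YAML mapping")
    return ModelSpec.model_validate(data)


def save_model(model: ModelSpec, path) -> None:
    """Write a model spec as YAML; load_model(save_model(m)) == m."""
    with open(path, "w") as fh:
        yaml.safe_dump(model.model_dump(mode="json"), fh, sort_keys=False)
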