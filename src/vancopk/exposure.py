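"""Steady-state 24-hour exposure (AUC) and target-attainment classification.

For linear PK at steady state the 24-hour area under the curve is
daily dose / clearance, independent of distribution volumes; the
trapezoid route over one dosing interval exists as a cross-check.
The consensus vancomycin exposure target (MIC 1 mg/L) is an AUC of
400-600 mg·h/L; both window boundaries are treated as within-target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pk import Regimen, StructuralParams, steady_state_conc

#: Target window boundaries, mg·h/L, both inclusive.
AUC_TARGET_LOW = 400.0
AUC_TARGET_HIGH = 600.0


@dataclass(frozen=True)
class AucResult:
    auc24: float          # mg·h/L
    method: str           # "analytic" | "trapezoid"
    patient_id: str | None = None
    model_name: str | None = None
    scenario: str | None = None

    def __post_init__(self) -> None:
        if not self.auc24 > 0:
            raise ValueError(f"auc24 must be > 0, got {self.auc24}")


def auc24_ss(params: StructuralParams, regimen: Regimen, *,
             patient_id: str | None = None, model_name: str | None = None,
             scenario: str | None = None) -> AucResult:
    """Steady-state AUC over 24 h: daily dose / CL."""
    if not params.CL > 0:
        raise ValueError(f"CL must be > 0, got {params.CL}")
    return AucResult(auc24=regimen.daily_dose / params.CL, method="analytic",
                     patient_id=patient_id, model_name=model_name,
                     scenario=scenario)


def auc24_ss_trapezoid(params: StructuralParams, regimen: Regimen,
                       dt: float = 0.01) -> AucResult:
    """AUC over 24 h by fine-grid trapezoid over one steady-state interval.

    Cross-check route for the analytic formula; integrates the
    steady-state profile over one tau and scales by 24/tau.
    """
    tau = regimen.tau
    n = max(int(round(tau / dt)), 10)
    # Endpoint at tau is the next interval's t=0 concentration (periodic).
    t = np.linspace(0.0, tau, n + 1)
    c = np.empty_like(t)
    c[:-1] = steady_state_conc(params, regimen.maintenance_dose, tau,
                               regimen.infusion_duration, t[:-1])
    c[-1] = steady_state_conc(params, regimen.maintenance_dose, tau,
                              regimen.infusion_duration, 0.0)
    auc_tau = float(np.trapezoid(c, t))
    return AucResult(auc24=auc_tau * 24.0 / tau, method="trapezoid")


def classify_target_attainment(auc24: float) -> str:
    """'below' (< 400), 'within' (400-600 inclusive) or 'above' (> 600)."""
    if not auc24 > 0:
        raise ValueError(f"auc24 must be > 0, got {auc24}")
    if auc24 < AUC_TARGET_LOW:
        return "below"
    if auc24 > AUC_TARGET_HIGH:
        return "above"
    return "within"
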