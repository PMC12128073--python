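"""Predictive-performance metrics for external model evaluation.

rBias is the signed mean relative deviation of predicted from reference
exposure (accuracy; clinically acceptable within +/-15%), rRMSE the root
mean squared relative deviation (precision; preferably below 20%). Both
are reported in percent. The confidence interval on rBias is a
patient-level nonparametric bootstrap (percentile method).
"""

from __future__ import annotations

import numpy as np

from .exposure import classify_target_attainment

#: Clinical acceptability thresholds, percent.
RBIAS_ACCEPTABLE = 15.0
RRMSE_ACCEPTABLE = 20.0


def _check(predicted, true) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 1:
        raise ValueError(
            f"predicted and true must be equal-length 1-D with n >= 1, "
            f"got shapes {p.shape} and {t.shape}")
    if np.any(t <= 0):
        raise ValueError("true values must be strictly positive")
    return p, t


def rbias(predicted, true) -> float:
    """Signed mean relative error, percent."""
    p, t = _check(predicted, true)
    return float(np.mean((p - t) / t) * 100.0)


def rrmse(predicted, true) -> float:
    """Root mean squared relative error, percent."""
    p, t = _check(predicted, true)
    return float(np.sqrt(np.mean(((p - t) / t) ** 2)) * 100.0)


def rbias_bootstrap_ci(predicted, true, n_boot: int = 2000,
                       seed: int = 0, level: float = 0.95
                       ) -> tuple[float, float]:
    """Percentile bootstrap CI for rBias, resampling patients with replacement."""
    p, t = _check(predicted, true)
    rng = np.random.default_rng(seed)
    n = p.size
    rel = (p - t) / t
    idx = rng.integers(0, n, size=(n_boot, n))
    stats = np.mean(rel[idx], axis=1) * 100.0
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def consensus_true_auc(per_model_auc) -> float:
    """Per-patient reference exposure: sample median of contributing models.

    Even counts use the mean of the two middle values.
    """
    vals = np.asarray(per_model_auc, dtype=float)
    if vals.size == 0:
        raise ValueError("consensus truth requires at least one model AUC")
    return float(np.median(vals))


def dosage_advice_concordance(model_auc: float, true_auc: float) -> str:
    """'concordant' if both AUCs imply the same dosage advice.

    Both below the 400-600 mg·h/L window -> both advise an increase;
    both within -> neither adjusts; both above -> both advise a decrease.
    """
    same = (classify_target_attainment(model_auc)
            == classify_target_attainment(true_auc))
    return "concordant" if same else "discordant"
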