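"""Validation of a fitted surface: predefined accuracy, ROC and AUC.

Accuracy follows the strict predefined rule |R_i - P_i| < 0.5 (a
predicted probability of exactly 0.5 is counted inaccurate for both
classes).  The ROC is computed on the predicted probabilities; the AUC
equals the tie-corrected Mann-Whitney concordance of predictions between
classes, and its 95% confidence interval uses DeLong's closed-form
variance by default, with a patient-level bootstrap as the alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_curve

from nlmaz.fitting import _columns
from nlmaz.surface import SurfaceParameters, effect_many

__all__ = ["ValidationReport", "SingleClassError", "accuracy", "roc", "validate"]


class SingleClassError(ValueError):
    """AUC is undefined when only one response class is present."""


@dataclass
class ValidationReport:
    n_obs: int
    accuracy: float  # percent
    auc: float
    auc_ci: tuple[float, float]
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    predictions: pd.DataFrame  # per-observation table incl. predicted_p


def _predict(obs: pd.DataFrame, params: SurfaceParameters):
    cm, ca, cp, r = _columns(obs)
    return r, np.asarray(effect_many(cm, ca, cp, params))


def accuracy(obs: pd.DataFrame, params: SurfaceParameters) -> float:
    """Percent of observations with |response - predicted probability| < 0.5."""
    if len(obs) == 0:
        raise ValueError("empty observation set")
    r, p = _predict(obs, params)
    return float(100.0 * np.mean(np.abs(r - p) < 0.5))


def _delong_ci(r: np.ndarray, p: np.ndarray, level: float = 0.95):
    """DeLong (1988) variance of the AUC via midrank placements."""
    pos = p[r == 1]
    neg = p[r == 0]
    m, n = len(pos), len(neg)

    def midranks(x):
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x))
        sx = x[order]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and sx[j] == sx[i]:
                j += 1
            ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
            i = j
        return ranks

    all_ranks = midranks(np.concatenate([pos, neg]))
    pos_ranks = midranks(pos)
    neg_ranks = midranks(neg)
    auc = (np.sum(all_ranks[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # placement of each positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placement of each negative
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = math.sqrt(max(var, 0.0))
    zq = norm.ppf(0.5 + level / 2.0)
    return float(auc), (float(max(0.0, auc - zq * se)), float(min(1.0, auc + zq * se)))


def _bootstrap_ci(
    obs: pd.DataFrame, r, p, seed: int, n_boot: int = 2000, level: float = 0.95
):
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    if "patient_id" in obs.columns:
        pid = obs["patient_id"].to_numpy()
        ids = np.unique(pid)
        idx_by_id = {i: np.flatnonzero(pid == i) for i in ids}
    aucs = []
    for _ in range(n_boot):
        if "patient_id" in obs.columns:
            take = np.concatenate(
                [idx_by_id[i] for i in rng.choice(ids, size=len(ids), replace=True)]
            )
        else:
            take = rng.integers(0, len(r), size=len(r))
        rb, pb = r[take], p[take]
        if rb.min() == rb.max():
            continue
        aucs.append(_delong_ci(rb, pb)[0])
    lo, hi = np.quantile(aucs, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def roc(
    obs: pd.DataFrame,
    params: SurfaceParameters,
    ci_method: str = "delong",
    seed: int = 0,
) -> ValidationReport:
    """ROC points, AUC and 95% CI for a parameter set on an observation table."""
    if len(obs) == 0:
        raise ValueError("empty observation set")
    r, p = _predict(obs, params)
    if r.min() == r.max():
        raise SingleClassError("both response classes are required for a ROC curve")
    fpr, tpr, thr = roc_curve(r, p)
    auc, ci = _delong_ci(r, p)
    if ci_method == "bootstrap":
        ci = _bootstrap_ci(obs, r, p, seed)
    elif ci_method != "delong":
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    preds = obs.copy()
    preds["predicted_p"] = p
    preds["lor"] = r.astype(int)
    return ValidationReport(
        n_obs=len(obs),
        accuracy=accuracy(obs, params),
        auc=auc,
        auc_ci=ci,
        roc_points=points,
        predictions=preds,
    )


def validate(obs: pd.DataFrame, params: SurfaceParameters, **kwargs) -> ValidationReport:
    """Alias for :func:`roc` (full validation report)."""
    return roc(obs, params, **kwargs)
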