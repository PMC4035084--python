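"""ROC/AUC evaluation of nested obesity-classification models.

The AUC is the Mann-Whitney probability that a random case outscores a
random control (ties counted half), equal to the trapezoidal area under the
empirical ROC curve.  Variances, confidence intervals and paired
curve-difference tests use the placement-based (DeLong-type) estimator, so
nested models fitted on the same subjects can be compared while accounting
for the correlation between their curves.  Reports follow the
covariates -> +SNP score -> +CNV nesting, with Delta AUC and %Delta AUC
relative to the previous model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

logger = logging.getLogger("snpcnv")


@dataclass
class RocSummary:
    """AUC with uncertainty for one model x outcome."""

    outcome: str
    model: str
    auc: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    n_cases: int
    n_controls: int


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("both outcome classes must be present")
    return cases, controls


def _placements(cases: np.ndarray, controls: np.ndarray
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mann-Whitney AUC and per-observation placement values.

    V10[i] = P-hat(case_i > control), V01[j] = P-hat(case > control_j),
    with ties counted one half; computed via midranks in O(N log N).
    """
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    ranks = stats.rankdata(combined)  # midranks handle ties
    case_ranks = ranks[:m]
    control_ranks = ranks[m:]
    case_ranks_within = stats.rankdata(cases)
    control_ranks_within = stats.rankdata(controls)
    v10 = (case_ranks - case_ranks_within) / n
    v01 = 1.0 - (control_ranks - control_ranks_within) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc(scores, labels) -> float:
    """Mann-Whitney AUC (ties counted half)."""
    cases, controls = _split(scores, labels)
    a, _, _ = _placements(cases, controls)
    return a


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValidationError("need >= 2 cases and >= 2 controls for a variance")
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def auc_ci_and_test(scores, labels, outcome: str = "", model: str = "",
                    level: float = 0.95) -> RocSummary:
    """AUC with a Wald CI from the placement variance and a two-sided
    asymptotic test against AUC = 0.5."""
    cases, controls = _split(scores, labels)
    a, v10, v01 = _placements(cases, controls)
    var = _auc_variance(v10, v01)
    se = np.sqrt(var)
    zq = stats.norm.ppf(0.5 + level / 2)
    if se == 0:
        p = 1.0 if a == 0.5 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(a - 0.5) / se))
    return RocSummary(
        outcome=outcome, model=model, auc=a,
        ci_low=a - zq * se, ci_high=a + zq * se, p_vs_half=p,
        n_cases=len(cases), n_controls=len(controls),
    )


def paired_auc_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired test of AUC_b - AUC_a for two score vectors on the same subjects.

    The variance of the difference uses the placement covariance between the
    two curves; returns (Delta AUC, two-sided p).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValidationError("paired comparison requires identical subject sets")
    ca, na = _split(scores_a, labels)
    cb, nb = _split(scores_b, labels)
    auc_a, v10a, v01a = _placements(ca, na)
    auc_b, v10b, v01b = _placements(cb, nb)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_b - auc_a
    if var <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return float(delta), float(2 * stats.norm.sf(abs(z)))


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve (FPR, TPR) points."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def delta_auc_report(models: list[tuple[str, np.ndarray]], labels,
                     outcome: str = "") -> pd.DataFrame:
    """Nested-model discrimination report for one outcome.

    ``models`` is an ordered list of (label, predicted probabilities); each
    row reports the model's AUC, 95% CI, asymptotic p vs 0.5, and — from the
    second model on — Delta AUC vs the previous model, %Delta AUC
    (100 * Delta / previous AUC) and the paired curve-difference p.
    """
    rows = []
    prev_label = prev_scores = None
    for label, scores in models:
        s = auc_ci_and_test(scores, labels, outcome=outcome, model=label)
        row = {
            "outcome": outcome, "model": label, "auc": s.auc,
            "ci_low": s.ci_low, "ci_high": s.ci_high, "p_vs_half": s.p_vs_half,
            "n_cases": s.n_cases, "n_controls": s.n_controls,
            "delta_auc": np.nan, "pct_delta_auc": np.nan, "p_delta_auc": np.nan,
        }
        if prev_scores is not None:
            delta, p = paired_auc_test(prev_scores, scores, labels)
            row["delta_auc"] = delta
            row["pct_delta_auc"] = 100.0 * delta / rows[-1]["auc"]
            row["p_delta_auc"] = p
        rows.append(row)
        prev_label, prev_scores = label, scores
    return pd.DataFrame(rows)


def pct_delta_auc(previous_auc: float, new_auc: float) -> tuple[float, float]:
    """(Delta AUC, %Delta AUC) with the previous model's AUC as denominator."""
    delta = new_auc - previous_auc
    return delta, 100.0 * delta / previous_auc
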