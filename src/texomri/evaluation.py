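"""ROC analysis of out-of-fold scores: DeLong variance, CIs, paired z-tests.

AUC is the tie-corrected Mann-Whitney statistic U / (n1 * n2) (ties count
one half), identical to the trapezoidal area under the empirical ROC curve.
Its standard error comes from DeLong's structural components: with
V10[i] the placement of positive score i among the negatives and V01[j] the
placement of negative j among the positives,

    var(AUC) = S10 / n1 + S01 / n0

where S10, S01 are the sample variances of the placements.  The covariance
between two correlated AUCs (same patients, different score vectors) uses
the cross-covariances of the same components, giving the paired z-test

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov).

The 95% CI follows the "binomial exact" construction: the AUC is treated as
a proportion of concordant pairs with an effective number of Bernoulli
trials n_eff = AUC (1 - AUC) / var_DeLong, and Clopper-Pearson limits are
taken at that n_eff.  This is a documented approximation of the referenced
clinical-statistics software and is isolated in one function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import CVScores

__all__ = [
    "ROCResult",
    "OperatingPoint",
    "AUCComparison",
    "delong_placements",
    "roc_auc",
    "operating_point",
    "compare_auc",
    "run_report",
]


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    se_delong: float
    ci95: Tuple[float, float]
    n_pos: int
    n_neg: int
    y_true: np.ndarray
    scores: np.ndarray


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    covariance: float
    z: float
    p_value: float
    paired: bool


def _split_scores(y_true: np.ndarray, scores: np.ndarray):
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def delong_placements(pos: np.ndarray, neg: np.ndarray):
    """AUC and DeLong structural components (V10 over positives, V01 over negatives)."""
    n1, n0 = len(pos), len(neg)
    # midrank formulation: placement of each positive among negatives
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = wins.mean(axis=1)
    v01 = wins.mean(axis=0)
    auc = float(wins.mean())
    return auc, v10, v01


def _delong_var(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return float(s10 / len(v10) + s01 / len(v01))


def _binomial_exact_ci(auc: float, var: float, n_pos: int, n_neg: int) -> Tuple[float, float]:
    """Clopper-Pearson limits on an effective-trial-count scale (see module docs)."""
    if var <= 0 or auc <= 0 or auc >= 1:
        n_eff = float(n_pos * n_neg)
    else:
        n_eff = auc * (1.0 - auc) / var
    x = auc * n_eff
    lo = stats.beta.ppf(0.025, x, n_eff - x + 1) if x > 0 else 0.0
    hi = stats.beta.ppf(0.975, x + 1, n_eff - x) if x < n_eff else 1.0
    return float(lo), float(hi)


def roc_auc(scores: CVScores | None = None, *, y_true=None, score_values=None) -> ROCResult:
    """Empirical ROC curve with DeLong SE and binomial-exact 95% CI.

    Accepts either a :class:`~texomri.modeling.CVScores` or raw arrays via
    the keyword form.
    """
    if scores is not None:
        y_true, score_values = scores.y_true, scores.scores
    y = np.asarray(y_true).astype(int)
    s = np.asarray(score_values, dtype=float)
    pos, neg = _split_scores(y, s)
    auc, v10, v01 = delong_placements(pos, neg)
    var = _delong_var(v10, v01)

    thr = np.unique(s)[::-1]
    thr = np.concatenate([[np.inf], thr])
    tpr = np.array([(pos >= t).mean() for t in thr])
    fpr = np.array([(neg >= t).mean() for t in thr])
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        se_delong=float(np.sqrt(var)),
        ci95=_binomial_exact_ci(auc, var, len(pos), len(neg)),
        n_pos=len(pos),
        n_neg=len(neg),
        y_true=y,
        scores=s,
    )


def operating_point(roc: ROCResult, rule: str = "youden") -> OperatingPoint:
    """Operating point maximizing the Youden index J = sens + spec - 1.

    Ties are broken toward higher specificity.  Predicted positive means
    score >= threshold.
    """
    if rule != "youden":
        raise ValueError(f"unknown operating-point rule {rule!r}")
    j = roc.tpr - roc.fpr
    best_j = j.max()
    candidates = np.nonzero(j >= best_j - 1e-12)[0]
    best = candidates[np.argmin(roc.fpr[candidates])]
    thr = roc.thresholds[best]
    pred = roc.scores >= thr
    tp = int(np.sum(pred & (roc.y_true == 1)))
    fp = int(np.sum(pred & (roc.y_true == 0)))
    fn = int(np.sum(~pred & (roc.y_true == 1)))
    tn = int(np.sum(~pred & (roc.y_true == 0)))
    return OperatingPoint(
        threshold=float(thr),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(roc.y_true),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def compare_auc(a: CVScores, b: CVScores, paired: bool = True) -> AUCComparison:
    """DeLong z-test between two AUCs.

    Paired comparison requires identical patient sets; the covariance then
    comes from the shared structural components.  Unpaired comparisons set
    the covariance to zero.
    """
    pos_a, neg_a = _split_scores(a.y_true, a.scores)
    pos_b, neg_b = _split_scores(b.y_true, b.scores)
    auc_a, v10_a, v01_a = delong_placements(pos_a, neg_a)
    auc_b, v10_b, v01_b = delong_placements(pos_b, neg_b)
    var_a = _delong_var(v10_a, v01_a)
    var_b = _delong_var(v10_b, v01_b)
    if paired:
        if a.patient_ids != b.patient_ids or not np.array_equal(a.y_true, b.y_true):
            raise ValueError("paired comparison requires identical patient sets")
        s10 = np.cov(v10_a, v10_b, ddof=1)[0, 1]
        s01 = np.cov(v01_a, v01_b, ddof=1)[0, 1]
        cov = float(s10 / len(v10_a) + s01 / len(v01_a))
    else:
        cov = 0.0
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = float((auc_a - auc_b) / np.sqrt(var_diff))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return AUCComparison(
        auc_a=auc_a, auc_b=auc_b, covariance=cov, z=z, p_value=p, paired=paired
    )


def run_report(all_scores: List[CVScores]) -> Dict[str, pd.DataFrame]:
    """Performance table and per-phase pairwise AUC z-test matrices.

    Returns ``{"performance": ..., "ztest_<phase>": ...}`` where the
    performance table has one row per phase x classifier (AUC, DeLong SE,
    95% CI, Youden-point sensitivity/specificity/accuracy) and each z-test
    matrix holds two-sided p-values with "/" on the diagonal.
    """
    if not all_scores:
        raise ValueError("no CV scores supplied")
    rows = []
    for cv in all_scores:
        roc = roc_auc(cv)
        op = operating_point(roc)
        rows.append(
            {
                "phase": cv.phase,
                "classifier": cv.classifier.kind.upper(),
                "AUC": round(roc.auc, 3),
                "SE": round(roc.se_delong, 3),
                "CI95_low": round(roc.ci95[0], 3),
                "CI95_high": round(roc.ci95[1], 3),
                "sensitivity_pct": round(100 * op.sensitivity, 2),
                "specificity_pct": round(100 * op.specificity, 2),
                "accuracy_pct": round(100 * op.accuracy, 2),
            }
        )
    report = {"performance": pd.DataFrame(rows)}
    phases = sorted({cv.phase for cv in all_scores})
    for phase in phases:
        group = [cv for cv in all_scores if cv.phase == phase]
        if len(group) < 2:
            continue
        names = [cv.classifier.kind.upper() for cv in group]
        mat = pd.DataFrame("/", index=names, columns=names, dtype=object)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                p = compare_auc(group[i], group[j], paired=True).p_value
                mat.iloc[i, j] = mat.iloc[j, i] = round(p, 4)
        report[f"ztest_{phase}"] = mat
    return report
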