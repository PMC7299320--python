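"""Univariate feature screening and cohort-characteristics contingency tests.

Each texture feature is compared between FISH-positive and FISH-negative
groups with a normality-gated two-sample test: a Lilliefors-corrected
Kolmogorov-Smirnov test is applied to each group, and only if both groups
look normal (P >= alpha) is the pooled-variance Student t-test used;
otherwise the Mann-Whitney U test.  Features with P < alpha survive the
screen.  No multiple-testing correction is applied by default (the screen is
a raw P < 0.05 filter); Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats._lilliefors import lilliefors_table_norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreeningConfig",
    "FeatureScreenRecord",
    "ks_normal",
    "rank_sum_test",
    "compare_feature",
    "screen_table",
    "screen_matrix_fast",
    "contingency_test",
    "standardize_unit_interval",
]


@dataclass
class ScreeningConfig:
    alpha_normality: float = 0.05
    alpha_screen: float = 0.05
    pooled_normality: bool = False   # gate on the pooled sample instead of per group
    lilliefors_correction: bool = True
    benjamini_hochberg: bool = False

    def __post_init__(self) -> None:
        for a in (self.alpha_normality, self.alpha_screen):
            if not 0 < a <= 1:  # alpha_screen = 1 keeps every feature
                raise ValueError("alpha must lie in (0, 1]")


@dataclass
class FeatureScreenRecord:
    feature_name: str
    normal_pos: bool
    normal_neg: bool
    test_used: str           # "t" | "mann_whitney"
    statistic: float
    p_value: float
    kept: bool
    summary_pos: str
    summary_neg: str


def ks_normal(sample: Sequence[float], lilliefors_correction: bool = True) -> float:
    """Kolmogorov-Smirnov normality P-value with estimated mean and sd.

    Uses the Lilliefors correction by default (the naive KS P-value against
    N(mean, sd) is badly anti-conservative when the parameters come from the
    sample itself).  A zero-variance sample returns P = 0, maximally
    non-normal.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("normality test needs at least 4 observations")
    if x.std(ddof=0) == 0.0:
        return 0.0
    if lilliefors_correction:
        _, p = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        _, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(p)


def _t_test(pos: np.ndarray, neg: np.ndarray) -> Tuple[float, float]:
    res = stats.ttest_ind(pos, neg, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def rank_sum_test(pos: Sequence[float], neg: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when n1*n2 <= 400 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pooled = np.concatenate([pos, neg])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pos.size * neg.size <= 400 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.4g}±{x.std(ddof=1):.4g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.4g} ({q1:.4g}–{q3:.4g})"


def compare_feature(
    pos: Sequence[float],
    neg: Sequence[float],
    cfg: ScreeningConfig | None = None,
    feature_name: str = "",
) -> FeatureScreenRecord:
    """Normality-gated two-group comparison of one feature."""
    cfg = cfg or ScreeningConfig()
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 4 or neg.size < 4:
        raise ValueError("each group needs at least 4 observations")
    if cfg.pooled_normality:
        p_norm = ks_normal(np.concatenate([pos, neg]), cfg.lilliefors_correction)
        normal_pos = normal_neg = p_norm >= cfg.alpha_normality
    else:
        normal_pos = ks_normal(pos, cfg.lilliefors_correction) >= cfg.alpha_normality
        normal_neg = ks_normal(neg, cfg.lilliefors_correction) >= cfg.alpha_normality
    use_t = normal_pos and normal_neg
    if use_t:
        statistic, p = _t_test(pos, neg)
    else:
        statistic, p = rank_sum_test(pos, neg)
    return FeatureScreenRecord(
        feature_name=feature_name,
        normal_pos=bool(normal_pos),
        normal_neg=bool(normal_neg),
        test_used="t" if use_t else "mann_whitney",
        statistic=statistic,
        p_value=p,
        kept=bool(p < cfg.alpha_screen),
        summary_pos=_summary(pos, use_t),
        summary_neg=_summary(neg, use_t),
    )


def screen_table(
    table: pd.DataFrame,
    cfg: ScreeningConfig | None = None,
    label_col: str = "label",
) -> List[FeatureScreenRecord]:
    """Screen every feature column of a patients-by-features table.

    `table` holds one row per patient: feature columns plus a binary label
    column (1 = FISH-positive).  Returns one record per feature; the kept set
    is {P < alpha_screen} (after Benjamini-Hochberg if enabled).
    """
    cfg = cfg or ScreeningConfig()
    y = table[label_col].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("screening needs exactly two classes in the table")
    pos_rows = table[y == classes.max()]
    neg_rows = table[y == classes.min()]
    records = [
        compare_feature(
            pos_rows[colname].to_numpy(),
            neg_rows[colname].to_numpy(),
            cfg,
            feature_name=colname,
        )
        for colname in table.columns
        if colname != label_col
    ]
    if cfg.benjamini_hochberg:
        reject, _, _, _ = multipletests(
            [r.p_value for r in records], alpha=cfg.alpha_screen, method="fdr_bh"
        )
        for r, keep in zip(records, reject):
            r.kept = bool(keep)
    return records


def _lilliefors_p_matrix(X: np.ndarray) -> np.ndarray:
    """Columnwise Lilliefors normality P-values of an (n, p) matrix.

    Same statistic and lookup table as :func:`ks_normal`; zero-variance
    columns get P = 0.
    """
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    pvals = np.zeros(p)
    if ok.any():
        Z = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
        Zs = np.sort(Z, axis=0)
        cdf = stats.norm.cdf(Zs)
        grid = np.arange(1, n + 1)[:, None] / n
        d_plus = (grid - cdf).max(axis=0)
        d_minus = (cdf - (grid - 1.0 / n)).max(axis=0)
        d = np.maximum(d_plus, d_minus)
        pvals[ok] = [float(lilliefors_table_norm.prob(dk, n)) for dk in d]
    return pvals


def _mwu_p_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Columnwise two-sided Mann-Whitney P (normal approximation, tie and
    continuity corrected), matching scipy's asymptotic method."""
    n1, n0 = len(pos), len(neg)
    n = n1 + n0
    stacked = np.vstack([pos, neg])
    ranks = stats.rankdata(stacked, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n0 / 2.0
    tie_term = np.zeros(stacked.shape[1])
    for j in range(stacked.shape[1]):
        _, counts = np.unique(stacked[:, j], return_counts=True)
        tie_term[j] = np.sum(counts ** 3 - counts)
    sigma = np.sqrt(n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / sigma
    p = 2.0 * stats.norm.sf(z)
    p[~np.isfinite(z)] = 1.0  # all-tied column: no evidence either way
    return np.clip(p, 0.0, 1.0)


def screen_matrix_fast(
    pos: np.ndarray, neg: np.ndarray, cfg: ScreeningConfig | None = None
) -> np.ndarray:
    """Vectorized per-feature screening P-values for an entire matrix.

    Functionally equivalent to running :func:`compare_feature` on each
    column with the asymptotic Mann-Whitney branch; used where screening is
    repeated inside every cross-validation fold.  Returns the P-value array.
    """
    cfg = cfg or ScreeningConfig()
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    normal_pos = _lilliefors_p_matrix(pos) >= cfg.alpha_normality
    normal_neg = _lilliefors_p_matrix(neg) >= cfg.alpha_normality
    use_t = normal_pos & normal_neg
    p = _mwu_p_matrix(pos, neg)
    if use_t.any():
        t_p = stats.ttest_ind(pos[:, use_t], neg[:, use_t], equal_var=True).pvalue
        p[use_t] = np.nan_to_num(t_p, nan=1.0)
    return p


def contingency_test(counts: Sequence[Sequence[int]]) -> Dict[str, object]:
    """Chi-square (no continuity correction) or Fisher's exact test on a 2x2 table.

    The chi-square branch applies when every expected count is >= 5;
    otherwise Fisher's exact two-sided test (point-probability method).
    """
    t = np.asarray(counts, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    expected = stats.contingency.expected_freq(t)
    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        return {"method": "chi_square", "statistic": float(chi2), "p_value": float(p)}
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return {"method": "fisher_exact", "statistic": float("nan"), "p_value": float(p)}


def standardize_unit_interval(
    table: pd.DataFrame, label_col: str = "label"
) -> Tuple[pd.DataFrame, List[str]]:
    """Min-max scale every feature column to [0, 1].

    Constant features map to 0.5 and are returned in the flagged list.
    """
    out = table.copy()
    flagged: List[str] = []
    for colname in table.columns:
        if colname == label_col:
            continue
        col = table[colname].to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        if hi == lo:
            out[colname] = 0.5
            flagged.append(colname)
        else:
            out[colname] = (col - lo) / (hi - lo)
    return out, flagged
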