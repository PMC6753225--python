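"""Cohort-level analysis: age-group norming, stratified Mann-Whitney
comparison of function probabilities by amyloid status, and
APOE4-by-age majority-class prediction tables.

Age is stratified into three clinically chosen bands — under 70, 70 up
to 80, and 81 up to 90 years — used both for z-score norming of raw
test scores and for stratifying the amyloid comparisons.  Significance
of the seven function-level comparisons is Bonferroni-corrected for
the number of cognitive functions: p < 0.05/7 = 0.007.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .battery import FUNCTIONS

__all__ = [
    "AGE_GROUP_LABELS",
    "N_FUNCTIONS",
    "bonferroni_threshold",
    "assign_age_group",
    "zscore_by_age_group",
    "mann_whitney_u",
    "compare_by_amyloid",
    "apoe_age_accuracy",
]

AGE_GROUP_LABELS = {1: "<70", 2: "70-80", 3: "81-90"}
N_FUNCTIONS = len(FUNCTIONS)  # 7


def bonferroni_threshold(n_comparisons: int = N_FUNCTIONS, alpha: float = 0.05) -> float:
    """Per-comparison significance threshold: alpha divided by the
    number of cognitive functions (0.05/7 = 0.007 to three decimals)."""
    return alpha / n_comparisons


def assign_age_group(age) -> int:
    """1 for <70 years, 2 for 70-80, 3 for 81-90 (fractional ages floored)."""
    if not np.isfinite(age):
        raise ValueError("age must be a finite number")
    a = math.floor(age)
    if a < 55 or a > 90:
        raise ValueError(f"age {age} outside the accepted 55-90 study range")
    if a < 70:
        return 1
    if a <= 80:
        return 2
    return 3


def zscore_by_age_group(scores, age_groups, orientation: str = "higher-is-better"):
    """Within-age-group z-scores after orientation alignment.

    Lower-is-better (timed) scores are negated before standardizing, so
    larger z is always better.  Missing values propagate; a group with
    fewer than two non-missing scores or zero spread is an error.
    """
    x = pd.Series(np.asarray(scores, dtype=float))
    g = pd.Series(np.asarray(age_groups)).reset_index(drop=True)
    if orientation == "lower-is-better":
        x = -x
    out = pd.Series(np.nan, index=x.index)
    for grp, idx in x.groupby(g).groups.items():
        vals = x.loc[idx]
        obs = vals.dropna()
        if len(obs) < 2:
            raise ValueError(f"age group {grp}: need >= 2 non-missing scores")
        sd = obs.std(ddof=1)
        if sd == 0:
            raise ValueError(f"age group {grp}: zero within-group standard deviation")
        out.loc[idx] = (vals - obs.mean()) / sd
    return out.to_numpy()


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U statistic of ``x``, p-value).

    Uses the exact null distribution when the pooled sample is small
    (n1 + n2 <= 40) and tie-free, so that small strata are compared
    exactly; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= 40) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_by_amyloid(
    function_probs: pd.DataFrame,
    subjects: pd.DataFrame,
    stratify_cognitive_status: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stratified Mann-Whitney comparison of function-high probabilities
    between amyloid-positive and amyloid-negative subjects.

    ``function_probs`` has columns ``P_ATT`` ... ``P_PS`` (as produced
    by :func:`cogposet.classify.classify_cohort`); ``subjects`` must
    align on index and carry ``age_group``, ``amyloid`` and, when
    stratifying further, ``cognitive_status``.  One row per stratum and
    function with U, the two-sided p, the arm sizes, a Bonferroni flag
    at alpha/7 and a nominal flag at alpha (the exploratory mode).
    Strata with fewer than two subjects in either amyloid arm are
    flagged not-computable but kept.
    """
    df = subjects.join(function_probs, how="inner")
    strat_cols = ["age_group"] + (
        ["cognitive_status"] if stratify_cognitive_status else []
    )
    thr = bonferroni_threshold(N_FUNCTIONS, alpha)
    rows = []
    for keys, grp in df.groupby(strat_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        label = ", ".join(
            AGE_GROUP_LABELS.get(k, str(k)) if c == "age_group" else str(k)
            for c, k in zip(strat_cols, keys)
        )
        pos = grp[grp["amyloid"] == "positive"]
        neg = grp[grp["amyloid"] == "negative"]
        for fn in FUNCTIONS:
            xp = pos[f"P_{fn}"].dropna()
            xn = neg[f"P_{fn}"].dropna()
            computable = len(xp) >= 2 and len(xn) >= 2
            if computable:
                U, p = mann_whitney_u(xp, xn)
            else:
                U, p = np.nan, np.nan
            rows.append(
                {
                    "stratum": label,
                    "function": fn,
                    "U": U,
                    "p_value": p,
                    "n_positive": len(xp),
                    "n_negative": len(xn),
                    "computable": computable,
                    "significant_bonferroni": bool(computable and p < thr),
                    "significant_nominal": bool(computable and p < alpha),
                }
            )
    return pd.DataFrame(rows)


def apoe_age_accuracy(subjects: pd.DataFrame) -> pd.DataFrame:
    """Majority-class amyloid prediction per (APOE4 count x age group) cell.

    For each cell: the amyloid-negative and -positive counts, the
    majority class, and the accuracy of always predicting it,
    max(n+, n-)/(n+ + n-) as a percentage rounded to one decimal.
    Subjects with unknown APOE4 count are excluded; empty cells report
    accuracy NA.
    """
    df = subjects.dropna(subset=["apoe4_count", "amyloid"])
    rows = []
    for apoe in (0, 1, 2):
        for grp in (1, 2, 3):
            cell = df[(df["apoe4_count"] == apoe) & (df["age_group"] == grp)]
            n_neg = int((cell["amyloid"] == "negative").sum())
            n_pos = int((cell["amyloid"] == "positive").sum())
            total = n_neg + n_pos
            if total == 0:
                majority, acc = None, np.nan
            else:
                majority = "negative" if n_neg >= n_pos else "positive"
                acc = round(100.0 * max(n_neg, n_pos) / total, 1)
            rows.append(
                {
                    "apoe4_count": apoe,
                    "age_group": AGE_GROUP_LABELS[grp],
                    "n_negative": n_neg,
                    "n_positive": n_pos,
                    "majority_class": majority,
                    "accuracy_pct": acc,
                }
            )
    return pd.DataFrame(rows)
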