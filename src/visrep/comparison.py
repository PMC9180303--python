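"""Audience-response metrics and between-group statistical comparison.

Engagement is likes plus comment count; a photo's comment sentiment is
the mean of its per-comment scores (missing when it has no comments —
excluded from group means rather than zero-imputed, since zero is a
valid sentiment). Group comparisons use two-sample t tests, Welch
(unequal variances, Welch–Satterthwaite df) by default, with a pooled
Student mode for sensitivity. Stars mark per-feature p < 0.05; a
Benjamini–Hochberg adjusted column is reported alongside but does not
drive the stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestOutcome",
    "engagement_score",
    "mean_comment_sentiment",
    "welch_t_test",
    "compare_groups",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TTestOutcome:
    """Two-sample t result; ``computable`` is False when the test is undefined."""

    t: float
    df: float
    p: float
    computable: bool = True

    def astuple(self) -> tuple[float, float, float]:
        return (self.t, self.df, self.p)


def engagement_score(likes: int, comment_sentiments) -> int:
    """Likes plus number of comments."""
    if likes < 0:
        raise ValueError("likes must be nonnegative")
    return int(likes) + len(comment_sentiments)


def mean_comment_sentiment(comment_sentiments) -> float:
    """Mean per-comment sentiment; NaN (missing) when there are no comments."""
    scores = np.asarray(list(comment_sentiments), dtype=float)
    if scores.size == 0:
        return float("nan")
    if np.any((scores < -1.0) | (scores > 1.0)):
        raise ValueError("sentiment scores must lie in [-1, 1]")
    return float(scores.mean())


def welch_t_test(group_a, group_b, equal_var: bool = False) -> TTestOutcome:
    """Two-sample t test, sign convention mean(a) − mean(b).

    Welch by default; ``equal_var=True`` gives the pooled Student test.
    Groups with fewer than two values, or zero variance in both groups,
    yield a not-computable outcome (NaN statistics) instead of an error,
    except that two identical constant groups are reported as t=0, p=1
    by symmetry.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return TTestOutcome(float("nan"), float("nan"), float("nan"), False)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestOutcome(0.0, float(a.size + b.size - 2), 1.0, True)
        return TTestOutcome(float("nan"), float("nan"), float("nan"), False)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestOutcome(float(res.statistic), float(res.df), float(res.pvalue), True)


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    order = np.argsort(p[ok])
    ranked = p[ok][order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(ranked, 1.0)
    out[ok] = vals
    return out


def compare_groups(
    feature_table: pd.DataFrame,
    labels,
    equal_var: bool = False,
    group_order: tuple | None = None,
) -> pd.DataFrame:
    """Per-feature two-group comparison table.

    ``feature_table`` holds one row per photo and one numeric column per
    feature (NaN entries are dropped feature-wise, e.g. missing comment
    sentiment). ``labels`` assigns each row to one of exactly two groups;
    the sign convention is mean(group1) − mean(group2) where group1 is
    the first label in ``group_order`` (default: sorted label order).
    """
    labels = np.asarray(labels)
    if len(labels) != len(feature_table):
        raise ValueError("labels length must match feature_table rows")
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"labels must define exactly two groups, got {len(uniq)}")
    if group_order is None:
        group_order = tuple(sorted(uniq, key=str))
    g1, g2 = group_order
    rows = []
    for feature in feature_table.columns:
        col = feature_table[feature].to_numpy(dtype=float)
        a = col[(labels == g1) & np.isfinite(col)]
        b = col[(labels == g2) & np.isfinite(col)]
        res = welch_t_test(a, b, equal_var=equal_var)
        rows.append(
            {
                "feature": feature,
                "mean_group1": float(a.mean()) if a.size else float("nan"),
                "mean_group2": float(b.mean()) if b.size else float("nan"),
                "t_statistic": res.t,
                "degrees_of_freedom": res.df,
                "p_value": res.p,
                "significant": bool(res.computable and res.p < ALPHA),
            }
        )
    table = pd.DataFrame(rows)
    table["p_bh"] = _bh_adjust(table["p_value"].to_numpy())
    table.attrs["group1"], table.attrs["group2"] = g1, g2
    return table
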