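"""Shared statistical helpers: rank tests, BH correction, correlation screens.

These wrap scipy/statsmodels so every module applies the same conventions
(two-sided tests, exact Wilcoxon where feasible, BH across the tested
feature set, pseudo-count guard for log fold changes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_rank_sum",
    "bh_adjust",
    "log2_fold_change",
    "feature_rank_tests",
    "feature_correlations",
]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when sample sizes permit and there are
    no ties (scipy's ``method="auto"``). Degenerate input where every value
    in both groups is identical is reported as p = 1 (no evidence of a
    shift), which scipy cannot represent because the rank variance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size) / 2.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment; NaN p-values stay NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def log2_fold_change(mean1: float, mean2: float, pseudo: float) -> float:
    return float(np.log2((mean1 + pseudo) / (mean2 + pseudo)))


def _pseudo_value(table: pd.DataFrame) -> float:
    """Half the smallest nonzero value in the table (log-of-zero guard)."""
    vals = table.to_numpy(dtype=float)
    nonzero = vals[np.isfinite(vals) & (vals > 0)]
    if nonzero.size == 0:
        return 0.5
    return float(nonzero.min() / 2.0)


def feature_rank_tests(table: pd.DataFrame, labels, group1=None, group2=None) -> pd.DataFrame:
    """Per-feature two-group Wilcoxon screen over a samples x features table.

    Parameters
    ----------
    table : DataFrame, samples in rows, features in columns.
    labels : group label per sample (aligned with ``table.index`` when a
        Series, positional otherwise). Exactly two groups required unless
        ``group1``/``group2`` name the contrast.

    Returns a DataFrame indexed by feature with columns ``lfc`` (log2 of
    group1/group2 mean ratio with a pseudo-value guard), ``p`` and ``q``.
    """
    labels = pd.Series(np.asarray(labels), index=table.index)
    groups = pd.unique(labels)
    if group1 is None or group2 is None:
        if len(groups) != 2:
            raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
        group1, group2 = groups
    idx1 = labels == group1
    idx2 = labels == group2
    if idx1.sum() < 2 or idx2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    pseudo = _pseudo_value(table)
    rows = []
    for feat in table.columns:
        x = table.loc[idx1, feat].to_numpy(dtype=float)
        y = table.loc[idx2, feat].to_numpy(dtype=float)
        stat, p = wilcoxon_rank_sum(x, y)
        rows.append((feat, log2_fold_change(x.mean(), y.mean(), pseudo), stat, p))
    out = pd.DataFrame(rows, columns=["feature", "lfc", "statistic", "p"]).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def feature_correlations(table: pd.DataFrame, covariate) -> pd.DataFrame:
    """Per-feature Pearson correlation against a sample-level covariate.

    Samples with a missing covariate (or missing feature value) are dropped
    pairwise. A zero-variance covariate is an error; zero-variance features
    yield NaN r/p and are excluded from the BH adjustment.
    """
    cov = pd.Series(np.asarray(covariate, dtype=float), index=table.index)
    finite_cov = cov.dropna()
    if finite_cov.size < 3:
        raise ValueError("need at least 3 samples with a finite covariate")
    if np.isclose(finite_cov.std(ddof=0), 0.0):
        raise ValueError("covariate has zero variance")
    rows = []
    for feat in table.columns:
        pair = pd.concat([table[feat], cov], axis=1, keys=["x", "c"]).dropna()
        if len(pair) < 3 or np.isclose(pair["x"].std(ddof=0), 0.0):
            rows.append((feat, np.nan, np.nan, len(pair)))
            continue
        r, p = stats.pearsonr(pair["x"], pair["c"])
        rows.append((feat, float(r), float(p), len(pair)))
    out = pd.DataFrame(rows, columns=["feature", "r", "p", "n"]).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
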