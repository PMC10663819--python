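"""Shared nonparametric-test helpers (vectorized over genes)."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, column-wise.

    ``x`` (n1 x G) vs ``y`` (n2 x G).  Uses the Mann-Whitney U statistic with
    tie correction; columns where every value is tied get p = 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided", method="auto")
    p = np.asarray(res.pvalue, dtype=np.float64)
    # all-tied columns: U test emits nan under the normal approximation
    tied = np.all(np.concatenate([x, y], axis=0) == x[0:1], axis=0)
    p = np.where(tied | ~np.isfinite(p), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def seurat_log2fc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log2 fold change between groups on log2-normalized data, column-wise.

    Means are taken on the de-logged scale with a +1 guard:
    ``log2((mean(2^x - 1) + 1) / (mean(2^y - 1) + 1))``.
    """
    mx = np.expm1(np.atleast_2d(x) * np.log(2)).mean(axis=0)
    my = np.expm1(np.atleast_2d(y) * np.log(2)).mean(axis=0)
    return np.log2(mx + 1.0) - np.log2(my + 1.0)


def bonferroni(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    return np.minimum(p * p.size, 1.0)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
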