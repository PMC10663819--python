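"""Family-level global expression scores and tissue contrasts.

For each cell, the global expression score of a molecule family (cytokines,
chemokines, immune checkpoints, growth factors, cell adhesion molecules) is
the sum of the cell's log-normalized expression over every ligand and
receptor gene annotated to that family.  Group means are centered-reduced as
z-scores across groups to show which cell types dominate each family, and
tumor-vs-juxtatumor differences are tested per cluster with Wilcoxon
rank-sum tests under BH-FDR correction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.base import BaseEstimator

from . import _stats
from .preprocessing import TISSUES

logger = logging.getLogger(__name__)

#: guard against 0/0 in the tissue fold change
LOG2FC_EPS = 1e-9


def per_cell_family_scores(adata: AnnData, family_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Cells x families matrix of summed normalized expression.

    Gene symbols that do not resolve against the matrix are skipped (logged);
    a family with no resolvable gene raises.
    """
    X = adata.X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    scores = {}
    for fam, genes in family_sets.items():
        idx = [var_index[g] for g in genes if g in var_index]
        n_missing = len(genes) - len(idx)
        if n_missing:
            logger.info("family %s: %d genes not in matrix", fam, n_missing)
        if not idx:
            raise ValueError(f"family {fam!r} has no resolvable genes")
        scores[fam] = X[:, idx].sum(axis=1)
    return pd.DataFrame(scores, index=adata.obs_names)


def cluster_family_zscores(
    cell_scores: pd.DataFrame,
    meta: pd.DataFrame,
    group_by=("cluster",),
    tissue: str | None = "tumor",
) -> pd.DataFrame:
    """Group-mean family scores centered-reduced as z-scores across groups.

    Returns a long table (group, family, mean_score, z).  By default groups
    are the clusters of tumor-tissue cells; set ``tissue=None`` to z-score
    across (cluster, tissue) groups jointly.
    """
    meta = meta.loc[cell_scores.index]
    mask = np.ones(len(meta), dtype=bool)
    if tissue is not None:
        mask = (meta["tissue"] == tissue).to_numpy()
        if not mask.any():
            raise ValueError(f"no cells in tissue {tissue!r}")
    sub_scores = cell_scores.loc[mask]
    sub_meta = meta.loc[mask]
    labels = (
        sub_meta[group_by[0]].astype(str)
        if len(group_by) == 1
        else sub_meta[list(group_by)].astype(str).agg("|".join, axis=1)
    )
    means = sub_scores.groupby(labels.values).mean()
    if means.shape[0] < 2:
        raise ValueError("z-scores need at least 2 groups")
    sd = means.std(axis=0, ddof=1)
    centered = means - means.mean(axis=0)
    z = centered / sd.replace(0.0, np.nan)
    zero_var = sd[sd == 0].index
    if len(zero_var):
        warnings.warn(f"zero-variance families set to z=0: {list(zero_var)}")
        z[zero_var] = 0.0
    z = z.fillna(0.0)
    out = (
        means.stack().rename("mean_score").to_frame()
        .join(z.stack().rename("z"))
        .reset_index(names=["group", "family"])
    )
    return out


def tissue_contrast(
    cell_scores: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.001,
    min_abs_log2fc: float = 0.25,
    cluster_pairing: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tumor-vs-juxtatumor contrast of family scores, per cluster.

    For each (cluster, family): a two-sided Wilcoxon rank-sum test on the
    per-cell scores of the cluster's tumor cells vs its juxtatumor cells,
    BH-FDR corrected across the whole cluster x family grid, with
    ``log2FC = log2((mean_tumor + eps) / (mean_juxta + eps))``.  Significant
    means adjusted p < ``alpha`` and ``|log2FC| > min_abs_log2fc``.

    ``cluster_pairing`` maps a tumor-only cluster onto its juxtatumor
    counterpart (e.g. the cancer cluster onto proximal tubules, its presumed
    cell of origin); clusters missing from one tissue and not in the pairing
    are skipped with a warning.
    """
    meta = meta.loc[cell_scores.index]
    pairing = cluster_pairing or {}
    rows = []
    pvals = []
    clusters = sorted(meta["cluster"].astype(str).unique())
    for cl in clusters:
        in_cl = meta["cluster"].astype(str) == cl
        tum = cell_scores.loc[(in_cl & (meta["tissue"] == TISSUES[0])).values]
        juxta_cluster = pairing.get(cl, cl)
        in_ref = meta["cluster"].astype(str) == juxta_cluster
        jux = cell_scores.loc[(in_ref & (meta["tissue"] == TISSUES[1])).values]
        if len(tum) == 0 or len(jux) == 0:
            warnings.warn(f"cluster {cl!r} absent from one tissue; contrast skipped")
            continue
        p = _stats.rank_sum_pvalues(tum.to_numpy(), jux.to_numpy())
        l2fc = np.log2((tum.mean(axis=0) + LOG2FC_EPS) / (jux.mean(axis=0) + LOG2FC_EPS))
        for k, fam in enumerate(cell_scores.columns):
            rows.append(
                {
                    "cluster": cl,
                    "family": fam,
                    "mean_tumor": float(tum[fam].mean()),
                    "mean_juxtatumor": float(jux[fam].mean()),
                    "log2fc": float(l2fc[fam]),
                    "p": float(p[k]),
                }
            )
            pvals.append(p[k])
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out.reindex(columns=["cluster", "family", "mean_tumor", "mean_juxtatumor",
                                    "log2fc", "p", "p_adj", "significant"])
    out["p_adj"] = _stats.bh_fdr(np.array(pvals))
    out["significant"] = (out["p_adj"] < alpha) & (out["log2fc"].abs() > min_abs_log2fc)
    return out


class FamilyScorer(BaseEstimator):
    """End-to-end family score analysis on an annotated, normalized AnnData.

    Attributes
    ----------
    cell_scores_ : cells x families DataFrame
    zscores_ : long table of group means and z-scores (tumor groups)
    contrast_ : tumor-vs-juxtatumor table (empty when one tissue is absent)
    """

    def __init__(
        self,
        family_sets: dict[str, set[str]] | None = None,
        alpha: float = 0.001,
        min_abs_log2fc: float = 0.25,
        zscore_tissue: str | None = "tumor",
        cluster_pairing: dict[str, str] | None = None,
    ):
        self.family_sets = family_sets
        self.alpha = alpha
        self.min_abs_log2fc = min_abs_log2fc
        self.zscore_tissue = zscore_tissue
        self.cluster_pairing = cluster_pairing

    def fit(self, X: AnnData, y=None):
        if not self.family_sets:
            raise ValueError("family_sets must be provided")
        self.cell_scores_ = per_cell_family_scores(X, self.family_sets)
        meta = X.obs
        self.zscores_ = cluster_family_zscores(
            self.cell_scores_, meta, tissue=self.zscore_tissue
        )
        if set(TISSUES) <= set(meta["tissue"].unique()):
            self.contrast_ = tissue_contrast(
                self.cell_scores_,
                meta,
                alpha=self.alpha,
                min_abs_log2fc=self.min_abs_log2fc,
                cluster_pairing=self.cluster_pairing,
            )
        else:
            self.contrast_ = pd.DataFrame()
        return self
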