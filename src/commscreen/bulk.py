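"""Bulk RNA-seq validation of candidate ligand-receptor pairs.

Counts are normalized with median-of-ratios size factors, each gene is
centered and reduced across samples, and for each candidate interaction a
per-sample ligand x receptor expression product is formed.  Products are
compared between tumor and normal samples with Wilcoxon rank-sum tests under
Bonferroni correction; a pair is called significant at adjusted p < 0.001
with log2 fold change >= 1.

By default the significance test runs on products of the normalized,
non-centered layer.  Products of centered-reduced (z-scored) values are
sign-ambiguous — when both genes shift up in the tumors, tumor products
(positive x positive) and control products (negative x negative) are both
positive, and in a balanced design their rank distributions coincide, so a
rank test on that layer has no power.  The scaled layer is still computed,
its products and tumor-minus-normal mean difference are reported, and
``test_layer="scaled"`` restores the test on it for comparison (in strongly
unbalanced cohorts, where the per-gene mean sits inside the tumor group,
the two layers give the same calls).  The fold change is always computed on
normalized-layer products with a +1 shift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _stats
from .comm_scoring import COMPLEX_RULES
from .lr_database import InteractionDB

logger = logging.getLogger(__name__)

CONDITIONS = ("tumor", "normal")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors (genes x samples counts).

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median over reference genes of count divided by
    the gene's geometric mean across samples.
    """
    arr = counts.to_numpy(dtype=np.float64)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene with nonzero counts in all samples; consider a "
            "pseudo-reference fallback"
        )
    logref = np.log(arr[ref])
    log_geomean = logref.mean(axis=1)
    ratios = logref - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors(counts)


def scale_genes(normalized: pd.DataFrame) -> pd.DataFrame:
    """Center-reduce each gene across samples (sample SD, ddof=1).

    Zero-variance genes are set to 0 and flagged via a logged warning.
    """
    if normalized.shape[1] < 2:
        raise ValueError("scaling needs at least 2 samples")
    mu = normalized.mean(axis=1)
    sd = normalized.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance genes set to 0 after scaling")
    scaled = normalized.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return scaled.fillna(0.0)


def _complex_rows(df: pd.DataFrame, subunits, rule: str) -> np.ndarray | None:
    present = [g for g in subunits if g in df.index]
    if len(present) < len(subunits):
        return None
    block = df.loc[present].to_numpy()
    return block.min(axis=0) if rule == "minimum" else block.mean(axis=0)


class BulkPairTester(BaseEstimator):
    """Tumor-vs-normal test of ligand x receptor expression products.

    Parameters
    ----------
    db : interaction database (or any record list) of candidate pairs
    alpha : Bonferroni-adjusted significance level (default 0.001)
    min_log2fc : fold-change gate on normalized-layer products (default 1)
    complex_rule : heterodimer aggregation
    fc_shift : shift added to mean products before the log ratio
    test_layer : layer whose products the rank test compares
        ("normalized", the default, or "scaled")

    Attributes
    ----------
    size_factors_, normalized_, scaled_ : normalization layers
    results_ : per-pair table (p, p_adj, log2fc, significant)
    skipped_ : interaction ids skipped for missing genes
    """

    def __init__(
        self,
        db: InteractionDB | None = None,
        alpha: float = 0.001,
        min_log2fc: float = 1.0,
        complex_rule: str = "minimum",
        fc_shift: float = 1.0,
        test_layer: str = "normalized",
    ):
        self.db = db
        self.alpha = alpha
        self.min_log2fc = min_log2fc
        self.complex_rule = complex_rule
        self.fc_shift = fc_shift
        self.test_layer = test_layer

    def fit(self, X: pd.DataFrame, y=None):
        """X: genes x samples raw counts; y: per-sample condition labels."""
        if self.db is None:
            raise ValueError("db must be provided")
        if self.complex_rule not in COMPLEX_RULES:
            raise ValueError(f"complex_rule must be one of {COMPLEX_RULES}")
        cond = pd.Series(y, index=X.columns) if not isinstance(y, pd.Series) else y
        cond = cond.astype(str)
        bad = set(cond.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {bad}")
        n_t = int((cond == "tumor").sum())
        n_n = int((cond == "normal").sum())
        if n_t < 2 or n_n < 2:
            raise ValueError("need at least 2 samples per condition")

        self.size_factors_ = size_factors(X)
        self.normalized_ = X / self.size_factors_
        self.scaled_ = scale_genes(self.normalized_)
        tmask = (cond == "tumor").to_numpy()

        rows, skipped = [], []
        products_scaled, products_norm = {}, {}
        for rec in self.db.records:
            l_s = _complex_rows(self.scaled_, rec.ligand_subunits, self.complex_rule)
            r_s = _complex_rows(self.scaled_, rec.receptor_subunits, self.complex_rule)
            l_n = _complex_rows(self.normalized_, rec.ligand_subunits, self.complex_rule)
            r_n = _complex_rows(self.normalized_, rec.receptor_subunits, self.complex_rule)
            if l_s is None or r_s is None:
                skipped.append(rec.interaction_id)
                logger.info("pair %s skipped: gene(s) missing", rec.label())
                continue
            prod_s = l_s * r_s
            prod_n = l_n * r_n
            products_scaled[rec.interaction_id] = prod_s
            products_norm[rec.interaction_id] = prod_n
            prod_t = prod_s if self.test_layer == "scaled" else prod_n
            p = float(_stats.rank_sum_pvalues(prod_t[tmask, None], prod_t[~tmask, None])[0])
            l2fc = float(
                np.log2(prod_n[tmask].mean() + self.fc_shift)
                - np.log2(prod_n[~tmask].mean() + self.fc_shift)
            )
            l2fc_scaled = float(prod_s[tmask].mean() - prod_s[~tmask].mean())
            rows.append(
                {
                    "interaction_id": rec.interaction_id,
                    "p": p,
                    "log2fc": l2fc,
                    "mean_diff_scaled": l2fc_scaled,
                }
            )
        res = pd.DataFrame(rows)
        if len(res):
            res["p_adj"] = np.minimum(res["p"] * len(res), 1.0)
            res["significant"] = (res["p_adj"] < self.alpha) & (res["log2fc"] >= self.min_log2fc)
        else:
            res = res.reindex(columns=["interaction_id", "p", "log2fc",
                                       "mean_diff_scaled", "p_adj", "significant"])
        self.results_ = res
        self.skipped_ = skipped
        self.products_scaled_ = pd.DataFrame(products_scaled, index=X.columns).T
        self.products_normalized_ = pd.DataFrame(products_norm, index=X.columns).T
        return self


def pair_product_test(
    counts: pd.DataFrame,
    condition,
    db: InteractionDB,
    rule: str = "minimum",
    alpha: float = 0.001,
    min_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Functional wrapper over :class:`BulkPairTester`; returns results_."""
    return (
        BulkPairTester(db=db, alpha=alpha, min_log2fc=min_log2fc, complex_rule=rule)
        .fit(counts, condition)
        .results_
    )
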