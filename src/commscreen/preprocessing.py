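"""Cell-level QC, library-size log-normalization, and cluster expression profiles.

Conventions
-----------
Expression lives in an :class:`anndata.AnnData` with cells as ``obs`` and
genes as ``var`` (the on-disk genes x cells orientation is transposed at
read time).  Raw integer counts are kept in ``layers["counts"]``; ``X``
holds the log-normalized values ``log2(count / cell_total * scale + 1)``,
so an entry is 0 exactly when the raw count is 0.

Cluster profiles are the per-(cluster[, tissue]) arithmetic mean of the
normalized values together with the fraction of cells with a nonzero raw
count — the quantities the communication scores are built from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

META_COLUMNS = ("cluster", "tissue", "patient", "dataset")
TISSUES = ("tumor", "juxtatumor")


class EmptyResultError(ValueError):
    """A filtering step removed everything."""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_mtx_dir(path: str | Path) -> AnnData:
    """Read a 10x-style triple (matrix.mtx, genes.tsv, barcodes.tsv).

    The matrix is genes x cells on disk; the returned AnnData is cells x genes
    with raw counts in ``layers["counts"]``.
    """
    import scipy.io

    path = Path(path)
    m = scipy.io.mmread(path / "matrix.mtx").tocsr().T.tocsr()
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = AnnData(
        X=m.astype(np.float64),
        obs=pd.DataFrame(index=barcodes.values),
        var=pd.DataFrame(index=genes.values),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


def read_dense_tsv(path: str | Path) -> AnnData:
    """Read a dense genes x cells TSV (first column = gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    adata = AnnData(
        X=df.T.to_numpy(dtype=np.float64),
        obs=pd.DataFrame(index=df.columns.astype(str)),
        var=pd.DataFrame(index=df.index.astype(str)),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Cell metadata TSV keyed by barcode with cluster/tissue/patient/dataset."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} missing columns: {missing}")
    return meta


def attach_meta(adata: AnnData, meta: pd.DataFrame) -> AnnData:
    """Join metadata onto ``obs``; every cell must be annotated."""
    unmatched = adata.obs_names.difference(meta.index)
    if len(unmatched):
        raise ValueError(f"{len(unmatched)} cells missing from metadata (e.g. {unmatched[0]})")
    for c in META_COLUMNS:
        adata.obs[c] = meta.loc[adata.obs_names, c].values
    return adata


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _counts(adata: AnnData) -> np.ndarray | sp.spmatrix:
    return adata.layers["counts"] if "counts" in adata.layers else adata.X


class CellQC(BaseEstimator, TransformerMixin):
    """Quality-control cell filter.

    Keeps cells with at least ``min_genes`` detected genes, at least
    ``min_umi`` total counts, and a mitochondrial fraction strictly below
    ``max_mito_frac`` (mitochondrial genes identified by symbol prefix).

    Attributes
    ----------
    keep_mask_ : boolean array over cells
    n_removed_ : dict with per-criterion removal counts
    """

    def __init__(
        self,
        min_genes: int = 200,
        min_umi: int = 1000,
        max_mito_frac: float = 0.20,
        mito_prefix: str = "MT-",
    ):
        self.min_genes = min_genes
        self.min_umi = min_umi
        self.max_mito_frac = max_mito_frac
        self.mito_prefix = mito_prefix

    def fit(self, X: AnnData, y=None):
        if self.min_genes < 0 or self.min_umi < 0 or self.max_mito_frac < 0:
            raise ValueError("QC thresholds must be non-negative")
        counts = _counts(X)
        if sp.issparse(counts):
            n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
            total = np.asarray(counts.sum(axis=1)).ravel()
        else:
            n_genes = (counts > 0).sum(axis=1)
            total = counts.sum(axis=1)
        mito = X.var_names.str.upper().str.startswith(self.mito_prefix.upper())
        if mito.any():
            sub = counts[:, np.asarray(mito)]
            mito_total = np.asarray(sub.sum(axis=1)).ravel()
        else:
            mito_total = np.zeros(X.n_obs)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 1.0)

        pass_genes = n_genes >= self.min_genes
        pass_umi = total >= self.min_umi
        pass_mito = mito_frac < self.max_mito_frac
        self.keep_mask_ = pass_genes & pass_umi & pass_mito
        self.n_removed_ = {
            "min_genes": int((~pass_genes).sum()),
            "min_umi": int((~pass_umi).sum()),
            "max_mito_frac": int((~pass_mito).sum()),
            "total": int((~self.keep_mask_).sum()),
        }
        logger.info("CellQC removed %s", self.n_removed_)
        return self

    def transform(self, X: AnnData) -> AnnData:
        if not hasattr(self, "keep_mask_") or len(self.keep_mask_) != X.n_obs:
            self.fit(X)
        if not self.keep_mask_.any():
            raise EmptyResultError("QC removed every cell")
        return X[self.keep_mask_].copy()


def filter_cells(
    adata: AnnData,
    min_genes: int = 200,
    min_umi: int = 1000,
    max_mito_frac: float = 0.20,
    mito_prefix: str = "MT-",
) -> AnnData:
    """Functional wrapper around :class:`CellQC`."""
    return CellQC(min_genes, min_umi, max_mito_frac, mito_prefix).fit_transform(adata)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class LogNormalizer(BaseEstimator, TransformerMixin):
    """Library-size normalization followed by a log2 transform.

    ``x = log2(count / cell_total * scale + pseudocount)`` with the default
    scale 10,000 and pseudocount 1, so zero counts map exactly to 0.  The
    parameters are recorded in ``uns["normalization"]`` for provenance.
    """

    def __init__(self, scale: float = 1e4, pseudocount: float = 1.0):
        self.scale = scale
        self.pseudocount = pseudocount

    def fit(self, X: AnnData, y=None):
        return self

    def transform(self, X: AnnData) -> AnnData:
        counts = _counts(X)
        if sp.issparse(counts):
            counts = np.asarray(counts.todense())
        counts = np.asarray(counts, dtype=np.float64)
        total = counts.sum(axis=1)
        if np.any(total <= 0):
            raise ValueError("cell with zero total count; run QC first")
        norm = np.log2(counts / total[:, None] * self.scale + self.pseudocount)
        out = X.copy()
        out.layers["counts"] = counts
        out.X = norm
        out.uns["normalization"] = {
            "scale": self.scale,
            "pseudocount": self.pseudocount,
            "log_base": 2,
        }
        return out


def normalize_log(adata: AnnData, scale: float = 1e4, pseudocount: float = 1.0) -> AnnData:
    return LogNormalizer(scale, pseudocount).fit_transform(adata)


# ---------------------------------------------------------------------------
# cluster profiles
# ---------------------------------------------------------------------------

@dataclass
class ClusterProfiles:
    """Per-group mean expression and percent-expressed tables.

    ``mean`` and ``pct`` are genes x groups DataFrames; group labels are the
    cluster label or ``cluster|tissue`` when grouped by both.  ``mean`` holds
    the average log-normalized expression (the l_i^C / r_j^C of the scores);
    ``pct`` the fraction of the group's cells with raw count > 0.
    """

    mean: pd.DataFrame
    pct: pd.DataFrame
    n_cells: pd.Series
    group_by: tuple[str, ...] = ("cluster",)
    min_pct_applied: float | None = None

    @property
    def groups(self) -> list[str]:
        return list(self.mean.columns)

    @property
    def genes(self) -> pd.Index:
        return self.mean.index

    def copy(self) -> "ClusterProfiles":
        return ClusterProfiles(
            self.mean.copy(), self.pct.copy(), self.n_cells.copy(),
            self.group_by, self.min_pct_applied,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (group, gene, mean, pct, n_cells)."""
        rows = []
        for g in self.groups:
            df = pd.DataFrame(
                {
                    "group": g,
                    "gene": self.mean.index,
                    "mean": self.mean[g].values,
                    "pct": self.pct[g].values,
                    "n_cells": self.n_cells[g],
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def group_key(cluster: str, tissue: str | None = None) -> str:
    return cluster if tissue is None else f"{cluster}|{tissue}"


class ClusterProfiler(BaseEstimator):
    """Compute per-group average transcriptomic profiles.

    Parameters
    ----------
    group_by
        ``("cluster",)`` or ``("cluster", "tissue")``.
    tissue
        Optionally restrict to one tissue before grouping (the communication
        analysis uses tumor cells only).

    Attributes
    ----------
    profiles_ : ClusterProfiles
    """

    def __init__(self, group_by: Sequence[str] = ("cluster",), tissue: str | None = None):
        self.group_by = tuple(group_by)
        self.tissue = tissue

    def fit(self, X: AnnData, y=None):
        adata = X
        if self.tissue is not None:
            adata = adata[adata.obs["tissue"] == self.tissue]
            if adata.n_obs == 0:
                raise EmptyResultError(f"no cells in tissue {self.tissue!r}")
        for c in self.group_by:
            if c not in adata.obs:
                raise ValueError(f"obs column {c!r} missing")
        labels = (
            adata.obs[self.group_by[0]].astype(str)
            if len(self.group_by) == 1
            else adata.obs[list(self.group_by)].astype(str).agg("|".join, axis=1)
        )
        counts = _counts(adata)
        if sp.issparse(counts):
            counts = np.asarray(counts.todense())
        norm = adata.X
        if sp.issparse(norm):
            norm = np.asarray(norm.todense())
        means, pcts, ns = {}, {}, {}
        for g in sorted(labels.unique()):
            idx = np.asarray(labels == g)
            if idx.sum() == 0:
                raise EmptyResultError(f"empty group {g!r}")
            means[g] = norm[idx].mean(axis=0)
            pcts[g] = (counts[idx] > 0).mean(axis=0)
            ns[g] = int(idx.sum())
        self.profiles_ = ClusterProfiles(
            mean=pd.DataFrame(means, index=adata.var_names),
            pct=pd.DataFrame(pcts, index=adata.var_names),
            n_cells=pd.Series(ns),
            group_by=self.group_by,
        )
        return self

    def transform(self, X: AnnData) -> ClusterProfiles:
        if not hasattr(self, "profiles_"):
            self.fit(X)
        return self.profiles_


def compute_profiles(
    adata: AnnData,
    group_by: Sequence[str] = ("cluster",),
    tissue: str | None = None,
) -> ClusterProfiles:
    return ClusterProfiler(group_by=group_by, tissue=tissue).fit(adata).profiles_


def apply_min_pct_filter(
    profiles: ClusterProfiles,
    genes: Iterable[str],
    min_pct: float = 0.10,
) -> ClusterProfiles:
    """Zero the mean of each listed gene in every group expressing it in
    strictly less than ``min_pct`` of cells (a gene at exactly ``min_pct``
    is kept).  Only the listed (communication) genes are touched.
    """
    out = profiles.copy()
    genes = set(genes)
    present = [g for g in genes if g in out.mean.index]
    absent = genes - set(present)
    if absent:
        logger.info("%d communication genes absent from the matrix", len(absent))
    if present:
        mask = out.pct.loc[present] < min_pct
        out.mean.loc[present] = out.mean.loc[present].where(~mask, 0.0)
    out.min_pct_applied = min_pct
    return out


def write_profiles(profiles: ClusterProfiles, path: str | Path) -> None:
    profiles.to_frame().to_csv(path, sep="\t", index=False)
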