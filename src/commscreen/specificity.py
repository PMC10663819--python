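"""Per-interaction specificity screening for a focal (cancer) cluster.

For an emitting cluster C and an interaction (i, j), the emitter-summed
interaction score aggregates the communication it drives toward every
cluster in the dataset (self included, so autocrine loops count):

    S_C(i, j) = l_i^C * sum_k r_j^k          (outgoing)

and symmetrically for incoming communication, with the receptor on the
focal cluster:

    S_C(i, j) = (sum_k l_i^k) * r_j^C        (incoming)

The screen retains interactions whose focal-cluster score is at least 1.5x
every other cluster's score (specificity), and whose focal-side molecule is
up-regulated in the focal cluster versus a reference cluster — the presumed
cell of origin from adjacent normal tissue — by a Wilcoxon rank-sum test
(log2FC >= 0.25, Bonferroni-adjusted p < 0.05).  Hits from several datasets
are intersected to keep channels replicated in at least two of them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.base import BaseEstimator

from . import _stats
from .comm_scoring import _side_matrix
from .lr_database import InteractionDB
from .preprocessing import ClusterProfiles, apply_min_pct_filter, compute_profiles

logger = logging.getLogger(__name__)

#: sentinel for an undefined specificity ratio (all competitors zero)
RATIO_INF = np.inf


@dataclass
class InteractionScore:
    """Eq.-style emitter/receiver-summed score for one interaction."""

    interaction_id: str
    direction: str  # "outgoing" | "incoming"
    focal_cluster: str
    value: float
    per_counterpart: pd.Series  # counterpart cluster -> contribution

    def __post_init__(self):
        assert self.direction in ("outgoing", "incoming")


def _interaction_score_table(
    db: InteractionDB,
    profiles: ClusterProfiles,
    direction: str,
    rule: str = "minimum",
    include_focal_in_sum: bool = True,
    focal: str | None = None,
) -> pd.DataFrame:
    """Interactions x candidate-clusters table of summed scores.

    For ``outgoing``, entry (i, C) = l_i^C * sum_k r_i^k; for ``incoming``,
    (i, C) = (sum_k l_i^k) * r_i^C.  When ``include_focal_in_sum`` is False
    the focal cluster is dropped from the counterpart sum (no autocrine
    term); the default keeps it, since autocrine loops are genuine hits.
    """
    L = _side_matrix(db, profiles, "ligand", rule)
    R = _side_matrix(db, profiles, "receptor", rule)
    own, other = (L, R) if direction == "outgoing" else (R, L)
    if include_focal_in_sum or focal is None:
        sums = other.sum(axis=1)
        return own.mul(sums, axis=0)
    # per-candidate-emitter sum excluding that emitter's own column would
    # change the comparison basis between candidates; the focal-exclusion
    # flag drops only the focal column from the shared sum.
    sums = other.drop(columns=[focal]).sum(axis=1)
    return own.mul(sums, axis=0)


def outgoing_interaction_scores(
    db: InteractionDB,
    profiles: ClusterProfiles,
    focal: str,
    rule: str = "minimum",
    include_focal_in_sum: bool = True,
) -> list[InteractionScore]:
    """Focal cluster's outgoing summed score per interaction."""
    L = _side_matrix(db, profiles, "ligand", rule)
    R = _side_matrix(db, profiles, "receptor", rule)
    receivers = list(R.columns) if include_focal_in_sum else [c for c in R.columns if c != focal]
    out = []
    for iid in L.index:
        per = L.loc[iid, focal] * R.loc[iid, receivers]
        out.append(InteractionScore(iid, "outgoing", focal, float(per.sum()), per))
    return out


def incoming_interaction_scores(
    db: InteractionDB,
    profiles: ClusterProfiles,
    focal: str,
    rule: str = "minimum",
    include_focal_in_sum: bool = True,
) -> list[InteractionScore]:
    """Mirror of the outgoing score with the receptor on the focal cluster."""
    L = _side_matrix(db, profiles, "ligand", rule)
    R = _side_matrix(db, profiles, "receptor", rule)
    emitters = list(L.columns) if include_focal_in_sum else [c for c in L.columns if c != focal]
    out = []
    for iid in L.index:
        per = L.loc[iid, emitters] * R.loc[iid, focal]
        out.append(InteractionScore(iid, "incoming", focal, float(per.sum()), per))
    return out


def specificity_filter(
    scores: pd.Series, focal: str, ratio: float = 1.5
) -> tuple[bool, float]:
    """Apply the focal-specificity rule to one interaction's per-cluster scores.

    Pass when the focal value is at least ``ratio`` times the largest
    competing cluster's value; when every competitor is 0, pass when the
    focal value is positive (the ratio is then reported as inf).
    """
    if focal not in scores.index:
        raise KeyError(f"focal cluster {focal!r} missing from scores")
    v_focal = float(scores[focal])
    competitors = scores.drop(index=focal).astype(float)
    v_max = float(competitors.max()) if len(competitors) else 0.0
    if v_max <= 0:
        return (v_focal > 0, RATIO_INF if v_focal > 0 else 0.0)
    realized = v_focal / v_max
    return (v_focal >= ratio * v_max, realized)


def wilcoxon_de(
    adata: AnnData,
    group1: np.ndarray,
    group2: np.ndarray,
    genes=None,
    min_log2fc: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    ``group1``/``group2`` are boolean masks or index arrays over ``obs``.
    Fold changes follow the de-logged-mean convention
    ``log2((mean(2^x - 1) + 1) / (mean(2^x - 1) + 1))``; genes with
    ``|log2FC|`` below ``min_log2fc`` are not tested, Bonferroni correction
    runs over the tested genes only, and a gene is selected when
    ``log2FC >= min_log2fc`` and adjusted p < ``alpha``.
    """
    X = adata.X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    var_names = adata.var_names
    if genes is not None:
        keep = var_names.isin(set(genes))
        X = X[:, keep]
        var_names = var_names[keep]
    g1 = np.asarray(X[_as_mask(group1, adata.n_obs)])
    g2 = np.asarray(X[_as_mask(group2, adata.n_obs)])
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    l2fc = _stats.seurat_log2fc(g1, g2)
    counts = adata.layers["counts"] if "counts" in adata.layers else None
    if counts is not None:
        if sp.issparse(counts):
            counts = np.asarray(counts.todense())
        if genes is not None:
            counts = counts[:, keep]
        pct1 = (counts[_as_mask(group1, adata.n_obs)] > 0).mean(axis=0)
        pct2 = (counts[_as_mask(group2, adata.n_obs)] > 0).mean(axis=0)
    else:
        pct1 = (g1 > 0).mean(axis=0)
        pct2 = (g2 > 0).mean(axis=0)

    tested = np.abs(l2fc) >= min_log2fc
    p = np.ones(len(var_names))
    if tested.any():
        p[tested] = _stats.rank_sum_pvalues(g1[:, tested], g2[:, tested])
    p_adj = np.ones(len(var_names))
    n_tested = int(tested.sum())
    if n_tested:
        p_adj[tested] = np.minimum(p[tested] * n_tested, 1.0)
    out = pd.DataFrame(
        {
            "gene": var_names,
            "log2fc": l2fc,
            "p": np.where(tested, p, np.nan),
            "p_adj": np.where(tested, p_adj, np.nan),
            "pct_group1": pct1,
            "pct_group2": pct2,
            "tested": tested,
        }
    ).set_index("gene")
    out["selected"] = tested & (l2fc >= min_log2fc) & (p_adj < alpha)
    return out


def _as_mask(group, n: int) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        if len(group) != n:
            raise ValueError("boolean mask length mismatch")
        return group
    mask = np.zeros(n, dtype=bool)
    mask[group] = True
    return mask


def vocabulary_genes(
    adata: AnnData,
    focal: str,
    others: list[str],
    comm_genes,
    alpha: float = 0.05,
) -> list[str]:
    """Focal-cluster-specific communication genes by pairwise DE.

    Against every other cluster a gene qualifies through either branch:

    1. log2FC >= 0.25 with adjusted p < ``alpha``; or
    2. log2FC >= 0.1, the other cluster expresses it in < 10% of cells, and
       the percent-expressed difference exceeds 5 points, with adjusted
       p < ``alpha``.

    The returned vocabulary is the intersection over all pairwise
    comparisons.
    """
    if not others:
        raise ValueError("need at least one comparison cluster")
    clusters = adata.obs["cluster"].astype(str)
    focal_mask = (clusters == focal).to_numpy()
    selected: set[str] | None = None
    for other in others:
        other_mask = (clusters == other).to_numpy()
        de = wilcoxon_de(adata, focal_mask, other_mask, genes=comm_genes,
                         min_log2fc=0.1, alpha=alpha)
        sig = de["p_adj"] < alpha
        branch1 = (de["log2fc"] >= 0.25) & sig
        branch2 = (
            (de["log2fc"] >= 0.1)
            & (de["pct_group2"] < 0.10)
            & ((de["pct_group1"] - de["pct_group2"]) > 0.05)
            & sig
        )
        qual = set(de.index[(branch1 | branch2).fillna(False)])
        selected = qual if selected is None else (selected & qual)
    return sorted(selected or set())


class SpecificityScreen(BaseEstimator):
    """Screen a dataset for focal-cluster-specific communication channels.

    fit() expects a log-normalized AnnData with ``cluster`` and ``tissue``
    obs columns.  Tumor-tissue cells define the cluster profiles; the
    reference cluster is taken from adjacent-normal (juxtatumor) tissue for
    the differential-expression gate.

    Parameters
    ----------
    db : interaction database
    focal : focal (cancer) cluster label
    reference : reference cluster label (cell of origin, juxtatumor side)
    ratio : specificity threshold (focal >= ratio x best competitor)
    min_pct : percent-expressed filter applied to communication genes
    de_min_log2fc, de_alpha : DE-gate thresholds
    complex_rule : heterodimer aggregation ("minimum" or "mean")
    include_focal_in_sum : keep the focal cluster in the counterpart sum
    de_gate_subunits : "all" (every subunit of the gated side selected) or "any"
    de_gate_both_sides : also require the non-focal side's molecule to pass DE
    per_pair_specificity : compare the best single pair score instead of the
        counterpart-summed score (sensitivity-analysis variant)

    Attributes
    ----------
    results_ : per interaction x direction screen table
    profiles_ : filtered tumor profiles used for scoring
    de_ : focal-vs-reference DE table over communication genes
    """

    def __init__(
        self,
        db: InteractionDB | None = None,
        focal: str = "cancer",
        reference: str = "PT",
        ratio: float = 1.5,
        min_pct: float = 0.10,
        de_min_log2fc: float = 0.25,
        de_alpha: float = 0.05,
        complex_rule: str = "minimum",
        include_focal_in_sum: bool = True,
        de_gate_subunits: str = "all",
        de_gate_both_sides: bool = False,
        per_pair_specificity: bool = False,
        dataset: str | None = None,
    ):
        self.db = db
        self.focal = focal
        self.reference = reference
        self.ratio = ratio
        self.min_pct = min_pct
        self.de_min_log2fc = de_min_log2fc
        self.de_alpha = de_alpha
        self.complex_rule = complex_rule
        self.include_focal_in_sum = include_focal_in_sum
        self.de_gate_subunits = de_gate_subunits
        self.de_gate_both_sides = de_gate_both_sides
        self.per_pair_specificity = per_pair_specificity
        self.dataset = dataset

    # -- internals ---------------------------------------------------------
    def _specificity_table(self, profiles: ClusterProfiles, direction: str) -> pd.DataFrame:
        db = self.db
        table = _interaction_score_table(
            db, profiles, direction, self.complex_rule,
            self.include_focal_in_sum, self.focal,
        )
        if self.per_pair_specificity:
            # compare the best single cluster-pair contribution per candidate
            L = _side_matrix(db, profiles, "ligand", self.complex_rule)
            R = _side_matrix(db, profiles, "receptor", self.complex_rule)
            own, other = (L, R) if direction == "outgoing" else (R, L)
            table = own * other.max(axis=1).to_numpy()[:, None]
        rows = []
        for iid in table.index:
            passed, realized = specificity_filter(table.loc[iid], self.focal, self.ratio)
            competitors = table.loc[iid].drop(index=self.focal)
            rows.append(
                {
                    "interaction_id": iid,
                    "direction": direction,
                    "focal_value": float(table.loc[iid, self.focal]),
                    "max_competitor": float(competitors.max()) if len(competitors) else 0.0,
                    "ratio": realized,
                    "passes_specificity": bool(passed),
                }
            )
        return pd.DataFrame(rows)

    def _de_gate(self, de: pd.DataFrame, record, direction: str) -> bool:
        sides = []
        sides.append(record.ligand_subunits if direction == "outgoing" else record.receptor_subunits)
        if self.de_gate_both_sides:
            sides.append(record.receptor_subunits if direction == "outgoing" else record.ligand_subunits)
        for subunits in sides:
            flags = [bool(de["selected"].get(g, False)) for g in subunits]
            ok = all(flags) if self.de_gate_subunits == "all" else any(flags)
            if not ok:
                return False
        return True

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X: AnnData, y=None):
        if self.db is None or len(self.db) == 0:
            raise ValueError("a non-empty interaction database is required")
        adata = X
        clusters = adata.obs["cluster"].astype(str)
        tissues = adata.obs["tissue"].astype(str)
        if not ((clusters == self.focal) & (tissues == "tumor")).any():
            raise ValueError(f"focal cluster {self.focal!r} absent from tumor tissue")
        if not ((clusters == self.reference) & (tissues == "juxtatumor")).any():
            raise ValueError(f"reference cluster {self.reference!r} absent from juxtatumor tissue")

        comm_genes = self.db.genes
        profiles = compute_profiles(adata, group_by=("cluster",), tissue="tumor")
        self.profiles_ = apply_min_pct_filter(profiles, comm_genes, self.min_pct)

        focal_mask = ((clusters == self.focal) & (tissues == "tumor")).to_numpy()
        ref_mask = ((clusters == self.reference) & (tissues == "juxtatumor")).to_numpy()
        self.de_ = wilcoxon_de(
            adata, focal_mask, ref_mask, genes=comm_genes,
            min_log2fc=self.de_min_log2fc, alpha=self.de_alpha,
        )

        records = {r.interaction_id: r for r in self.db.records}
        parts = []
        for direction in ("outgoing", "incoming"):
            t = self._specificity_table(self.profiles_, direction)
            t["passes_de"] = [
                self._de_gate(self.de_, records[i], direction) for i in t["interaction_id"]
            ]
            parts.append(t)
        res = pd.concat(parts, ignore_index=True)
        res["final"] = res["passes_specificity"] & res["passes_de"]
        res["focal_cluster"] = self.focal
        if self.dataset is not None:
            res["dataset"] = self.dataset
        self.results_ = res
        return self

    def hits(self, direction: str | None = None) -> pd.DataFrame:
        res = self.results_[self.results_["final"]]
        if direction is not None:
            res = res[res["direction"] == direction]
        return res.sort_values("focal_value", ascending=False)


def screen_dataset(
    db: InteractionDB,
    adata: AnnData,
    focal: str,
    reference: str,
    ratio: float = 1.5,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper over :class:`SpecificityScreen`; returns results_."""
    return (
        SpecificityScreen(db=db, focal=focal, reference=reference, ratio=ratio, **kwargs)
        .fit(adata)
        .results_
    )


def intersect_screens(
    results: dict[str, pd.DataFrame], min_datasets: int = 2
) -> pd.DataFrame:
    """Cross-dataset intersection of final hits.

    Returns one row per (interaction, direction) that is a final hit in at
    least ``min_datasets`` datasets, with its membership vector and a tier:
    ``all`` (every dataset) or ``>=min_datasets``.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 datasets to intersect")
    if len(set(results)) != len(results):
        raise ValueError("duplicated dataset labels")
    names = list(results)
    member: dict[tuple[str, str], dict[str, bool]] = {}
    for name, df in results.items():
        hits = df[df["final"]]
        for _, row in hits.iterrows():
            key = (row["interaction_id"], row["direction"])
            member.setdefault(key, {n: False for n in names})[name] = True
    rows = []
    for (iid, direction), m in member.items():
        n_found = sum(m.values())
        if n_found < min_datasets:
            continue
        tier = "all" if n_found == len(names) else f">={min_datasets}"
        rows.append(
            {"interaction_id": iid, "direction": direction, "n_datasets": n_found,
             "tier": tier, **{f"in_{n}": v for n, v in m.items()}}
        )
    out = pd.DataFrame(rows, columns=["interaction_id", "direction", "n_datasets", "tier"]
                       + [f"in_{n}" for n in names])
    if len(out):
        out = out.sort_values(["tier", "interaction_id", "direction"]).reset_index(drop=True)
    return out
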