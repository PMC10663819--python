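"""Cluster-pair communication scores.

The score from an emitting cluster C1 to a receiving cluster C2 is the sum,
over every interaction (i, j) in the ligand-receptor database, of the
emitter's average ligand expression times the receiver's average receptor
expression:

    S(C1 -> C2) = sum_{(i,j)} l_i^{C1} * r_j^{C2}

Heterodimeric complexes contribute a single value per side, aggregated over
subunits by the complex rule (minimum by default: the limiting subunit sets
the complex's availability; mean is available as an alternative).  Profiles
are expected to have the percent-expressed filter already applied, so a
subunit expressed in too few of a cluster's cells drives its side to zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .lr_database import InteractionDB
from .preprocessing import ClusterProfiles

logger = logging.getLogger(__name__)

COMPLEX_RULES = ("minimum", "mean")


def complex_expression(mean_expr: pd.Series, subunits, rule: str = "minimum") -> float:
    """Aggregate a complex's subunit means into one expression value.

    A single-subunit complex returns its own mean; absent subunits count
    as 0 expression.
    """
    if rule not in COMPLEX_RULES:
        raise ValueError(f"rule must be one of {COMPLEX_RULES}")
    subunits = list(subunits)
    if not subunits:
        raise ValueError("empty subunit list")
    vals = np.array([float(mean_expr.get(g, 0.0)) for g in subunits])
    return float(vals.min() if rule == "minimum" else vals.mean())


def _side_matrix(db: InteractionDB, profiles: ClusterProfiles, side: str, rule: str) -> pd.DataFrame:
    """Interactions x groups matrix of complex expression for one side."""
    groups = profiles.groups
    mean = profiles.mean
    out = np.zeros((len(db.records), len(groups)))
    gene_index = {g: i for i, g in enumerate(mean.index)}
    vals = mean.to_numpy()
    for r_i, rec in enumerate(db.records):
        subunits = rec.ligand_subunits if side == "ligand" else rec.receptor_subunits
        rows = []
        for g in subunits:
            i = gene_index.get(g)
            rows.append(vals[i] if i is not None else np.zeros(len(groups)))
        arr = np.vstack(rows)
        out[r_i] = arr.min(axis=0) if rule == "minimum" else arr.mean(axis=0)
    ids = [rec.interaction_id for rec in db.records]
    return pd.DataFrame(out, index=ids, columns=groups)


@dataclass
class CommunicationScore:
    """One emitter -> receiver score with per-interaction contributions."""

    emitter: str
    receiver: str
    contributions: pd.Series  # indexed by interaction_id
    families: pd.Series  # interaction_id -> family

    @property
    def total(self) -> float:
        return float(self.contributions.sum())

    @property
    def family_decomposition(self) -> pd.Series:
        return self.contributions.groupby(self.families).sum()


@dataclass
class ScoreMatrix:
    """K x K grid of communication scores (ordered pairs, self included)."""

    values: pd.DataFrame  # emitters x receivers, totals
    ligand_expr: pd.DataFrame  # interactions x groups
    receptor_expr: pd.DataFrame  # interactions x groups
    families: pd.Series
    rescaled: pd.DataFrame | None = None

    @property
    def clusters(self) -> list[str]:
        return list(self.values.index)

    def score(self, emitter: str, receiver: str) -> CommunicationScore:
        contrib = self.ligand_expr[emitter] * self.receptor_expr[receiver]
        return CommunicationScore(emitter, receiver, contrib, self.families)

    def to_frame(self) -> pd.DataFrame:
        """Long format: emitter, receiver, interaction_id, contribution, family."""
        rows = []
        for e in self.clusters:
            for r in self.clusters:
                s = self.score(e, r)
                rows.append(
                    pd.DataFrame(
                        {
                            "emitter": e,
                            "receiver": r,
                            "interaction_id": s.contributions.index,
                            "contribution": s.contributions.values,
                            "family": self.families.reindex(s.contributions.index).values,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


class CommunicationScorer(BaseEstimator):
    """Score communication between every ordered pair of clusters.

    Fitting on a filtered :class:`ClusterProfiles` computes the interaction-
    by-cluster ligand and receptor complex-expression matrices once; the
    pair totals are then their outer contraction.

    Attributes
    ----------
    matrix_ : ScoreMatrix
    """

    def __init__(self, db: InteractionDB | None = None, complex_rule: str = "minimum"):
        self.db = db
        self.complex_rule = complex_rule

    def fit(self, X: ClusterProfiles, y=None):
        if self.db is None:
            raise ValueError("db must be provided")
        if len(self.db) == 0:
            warnings.warn("empty interaction database; all scores are 0")
        L = _side_matrix(self.db, X, "ligand", self.complex_rule)
        R = _side_matrix(self.db, X, "receptor", self.complex_rule)
        totals = pd.DataFrame(
            L.to_numpy().T @ R.to_numpy(), index=L.columns, columns=R.columns
        )
        fams = pd.Series(
            {r.interaction_id: r.family for r in self.db.records}, dtype=object
        )
        self.matrix_ = ScoreMatrix(totals, L, R, fams)
        return self

    def transform(self, X: ClusterProfiles) -> ScoreMatrix:
        if not hasattr(self, "matrix_"):
            self.fit(X)
        return self.matrix_


def pair_score(
    db: InteractionDB,
    emitter_profile: pd.Series,
    receiver_profile: pd.Series,
    rule: str = "minimum",
) -> CommunicationScore:
    """Score a single emitter -> receiver pair from mean-expression vectors."""
    contrib = {}
    for rec in db.records:
        l = complex_expression(emitter_profile, rec.ligand_subunits, rule)
        r = complex_expression(receiver_profile, rec.receptor_subunits, rule)
        contrib[rec.interaction_id] = l * r
    fams = pd.Series({r.interaction_id: r.family for r in db.records}, dtype=object)
    return CommunicationScore(
        "emitter", "receiver", pd.Series(contrib, dtype=float), fams
    )


def all_pair_scores(
    db: InteractionDB, profiles: ClusterProfiles, rule: str = "minimum"
) -> ScoreMatrix:
    return CommunicationScorer(db=db, complex_rule=rule).fit(profiles).matrix_


def rescale_to_100(matrix: ScoreMatrix, scope: str = "global") -> ScoreMatrix:
    """Attach a 0-100 rescaled copy of the K x K score totals.

    Totals are divided by the grid maximum and multiplied by 100, so the
    largest pair scores 100 and zeros stay zero.  An all-zero grid is left
    unchanged with a warning.  Rescaling an already-rescaled matrix is a
    no-op on the rescaled layer (idempotent).
    """
    if scope != "global":
        raise ValueError("rescale_to_100 operates on the global score grid; "
                         "use interaction_grid for per-channel 0-100 heatmaps")
    out = ScoreMatrix(
        matrix.values.copy(), matrix.ligand_expr, matrix.receptor_expr, matrix.families
    )
    m = matrix.values.to_numpy().max()
    if m <= 0:
        warnings.warn("all-zero score matrix; rescaling skipped")
        out.rescaled = matrix.values.copy()
    else:
        out.rescaled = matrix.values / m * 100.0
    return out


def interaction_grid(
    matrix: ScoreMatrix, interaction_id: str, rescale: bool = True
) -> pd.DataFrame:
    """One interaction's emitter x receiver contribution grid, optionally on
    0-100 (each channel rescaled by its own maximum, as in per-channel
    heatmaps)."""
    l = matrix.ligand_expr.loc[interaction_id].to_numpy()
    r = matrix.receptor_expr.loc[interaction_id].to_numpy()
    grid = pd.DataFrame(
        np.outer(l, r), index=matrix.values.index, columns=matrix.values.columns
    )
    if rescale:
        m = grid.to_numpy().max()
        if m > 0:
            grid = grid / m * 100.0
        else:
            warnings.warn(f"all-zero grid for {interaction_id}; rescaling skipped")
    return grid


def plot_score_heatmap(matrix: ScoreMatrix, ax=None, use_rescaled: bool = True):
    """Minimal emitter x receiver heatmap of the score totals."""
    import matplotlib.pyplot as plt

    vals = matrix.rescaled if (use_rescaled and matrix.rescaled is not None) else matrix.values
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(vals.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(vals.columns)), vals.columns, rotation=90)
    ax.set_yticks(range(len(vals.index)), vals.index)
    ax.set_xlabel("receiver")
    ax.set_ylabel("emitter")
    ax.figure.colorbar(im, ax=ax)
    return ax
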