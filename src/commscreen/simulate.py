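"""Synthetic single-cell and bulk datasets with known planted communication.

The single-cell generator emulates the statistical structure the screening
pipeline assumes: discrete clusters, over-dispersed (negative binomial)
counts with gene-level means drawn log-normally, independent Bernoulli
dropout, a focal "cancer" cluster present only in tumor tissue, and a
matched reference ("PT") cluster at baseline expression present only in
adjacent-normal tissue.  Planted channels multiply the ligand and/or
receptor gene means of a chosen interaction in the focal cluster, so every
downstream decision (percent-expressed filter, specificity ratio, DE gate)
has a known expected outcome.

The bulk generator mirrors the tumor/normal product test: negative binomial
counts with log-normal per-sample library-size factors and a tumor-specific
fold on chosen ligand and receptor genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData

from .lr_database import InteractionDB, InteractionRecord

_SC_FAMILIES = ("cytokine", "chemokine", "immune_checkpoint", "growth_factor", "cell_adhesion")


# ---------------------------------------------------------------------------
# synthetic ligand-receptor databases
# ---------------------------------------------------------------------------

def make_synthetic_db(n_interactions: int = 40, hetero_every: int = 6) -> InteractionDB:
    """Deterministic toy interaction database over synthetic gene symbols.

    Ligands are LG###, receptors RG### (disjoint sets), families cycle
    through the five molecule families, and every ``hetero_every``-th record
    carries a 2-subunit receptor (and every third of those a 2-subunit
    ligand) to exercise complex handling.
    """
    records = []
    for i in range(n_interactions):
        lig = [f"LG{i:03d}"]
        rec = [f"RG{i:03d}"]
        if hetero_every and (i + 1) % hetero_every == 0:
            rec.append(f"RG{i:03d}B")
            if (i + 1) % (3 * hetero_every) == 0:
                lig.append(f"LG{i:03d}B")
        records.append(
            InteractionRecord(
                interaction_id=f"I{i:03d}",
                ligand_subunits=tuple(lig),
                receptor_subunits=tuple(rec),
                family=_SC_FAMILIES[i % len(_SC_FAMILIES)],
            )
        )
    return InteractionDB(records)


#: published per-family gene tallies and interaction quotas used for the
#: synthetic curated-table stand-in (sums to 618 genes / 1164 interactions)
CURATED_FAMILY_GENES = {
    "cytokine": 253,
    "immune_checkpoint": 76,
    "chemokine": 73,
    "growth_factor": 94,
    "cell_adhesion": 122,
}
CURATED_FAMILY_INTERACTIONS = {
    "cytokine": 476,
    "immune_checkpoint": 143,
    "chemokine": 138,
    "growth_factor": 177,
    "cell_adhesion": 230,
}
CURATED_BASE_SIZE = 752
CURATED_ADDITION_SIZE = 412

_FAM_PREFIX = {
    "cytokine": "CYT",
    "immune_checkpoint": "ICP",
    "chemokine": "CHE",
    "growth_factor": "GRF",
    "cell_adhesion": "ADH",
}


def make_curated_table_fixture() -> tuple[InteractionDB, InteractionDB]:
    """Synthetic stand-in for a curated ligand-receptor table.

    Builds, from synthetic gene symbols, a base database of 752 records and
    a disjoint addition set of 412 records whose merged family gene-set
    sizes match the published tallies (253 cytokines, 76 immune checkpoints,
    73 chemokines, 94 growth factors, 122 cell adhesion molecules).  Used to
    exercise read/merge/count bookkeeping end-to-end; it carries no real
    gene symbols or curation.
    """
    records: list[InteractionRecord] = []
    for fam, n_genes in CURATED_FAMILY_GENES.items():
        genes = [f"{_FAM_PREFIX[fam]}{i:03d}" for i in range(n_genes)]
        quota = CURATED_FAMILY_INTERACTIONS[fam]
        made = 0
        offset = 1
        while made < quota:
            for i in range(n_genes):
                if made >= quota:
                    break
                lig = [genes[i]]
                rec = [genes[(i + offset) % n_genes]]
                if made % 10 == 9:  # sprinkle heterodimeric receptors
                    rec.append(genes[(i + offset + 3) % n_genes])
                records.append(
                    InteractionRecord(
                        interaction_id=f"{_FAM_PREFIX[fam]}_{made:04d}",
                        ligand_subunits=tuple(lig),
                        receptor_subunits=tuple(rec),
                        family=fam,
                    )
                )
                made += 1
            offset += 1
    assert len(records) == CURATED_BASE_SIZE + CURATED_ADDITION_SIZE
    base = InteractionDB(records[:CURATED_BASE_SIZE])
    additions = InteractionDB(records[CURATED_BASE_SIZE:])
    return base, additions


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------

@dataclass
class PlantedChannel:
    """A planted cluster-specific communication channel."""

    interaction_id: str
    focal_cluster: str = "cancer"
    ligand_fold: float = 8.0
    receptor_fold: float = 1.0
    direction: str = "outgoing"

    def __post_init__(self):
        if self.ligand_fold < 1 or self.receptor_fold < 1:
            raise ValueError("planted folds must be >= 1")
        if self.direction not in ("outgoing", "incoming"):
            raise ValueError("direction must be outgoing or incoming")


@dataclass
class SimConfig:
    """Study conditions for the single-cell generator.

    Defaults are the screening scenario: 6 tumor clusters of 400 cells
    (focal "cancer" plus 5 microenvironment clusters), a baseline-expression
    "PT" reference cluster of 400 cells in juxtatumor tissue, 1000 genes
    with NB(mu=2, theta=2) counts, log-normal gene-level mean variation
    (sigma=0.5), and 30% dropout.
    """

    n_clusters: int = 6
    cells_per_cluster: int = 400
    n_genes: int = 1000
    mu: float = 2.0
    theta: float = 2.0
    dropout: float = 0.3
    gene_mean_sigma: float = 0.5
    focal_cluster: str = "cancer"
    reference_cluster: str = "PT"
    other_cluster_tissues: tuple[str, ...] = ("tumor",)
    patients: tuple[str, ...] = ("P1", "P2", "P3")
    dataset_name: str = "synthetic"
    planted_channels: tuple[PlantedChannel, ...] = ()
    planted_family_shift: tuple | None = None  # (cluster, family, fold)
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if not (0 <= self.dropout <= 1):
            raise ValueError("dropout must be in [0, 1]")

    @property
    def cluster_names(self) -> list[str]:
        return [self.focal_cluster] + [f"TME{i}" for i in range(1, self.n_clusters)]


@dataclass
class GroundTruth:
    """Generating parameters and expected qualitative outcomes."""

    channels: list[dict] = field(default_factory=list)
    gene_folds: dict = field(default_factory=dict)  # gene -> {cluster: fold}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    # NB with mean m and dispersion theta: p = theta / (theta + m)
    p = theta / (theta + np.maximum(mean, 1e-12))
    return rng.negative_binomial(theta, p)


def simulate_sc_dataset(
    cfg: SimConfig, db: InteractionDB
) -> tuple[AnnData, GroundTruth]:
    """Generate an annotated raw-count AnnData plus its ground truth.

    Gene universe = every database gene (in database order) padded with
    background genes BG#### up to ``cfg.n_genes``; planted folds multiply
    the NB mean of the channel's ligand (and/or receptor) genes in the
    focal cluster only.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    comm_genes = sorted(db.genes)
    if len(comm_genes) > cfg.n_genes:
        raise ValueError("n_genes smaller than the database gene universe")
    genes = comm_genes + [f"BG{i:04d}" for i in range(cfg.n_genes - len(comm_genes))]
    gene_index = {g: i for i, g in enumerate(genes)}

    # log-normal gene-level baseline means with overall mean cfg.mu
    s = cfg.gene_mean_sigma
    base = rng.lognormal(mean=np.log(cfg.mu) - 0.5 * s * s, sigma=s, size=len(genes))

    # groups: focal + TME clusters in tumor (and optionally juxtatumor),
    # reference cluster in juxtatumor only
    groups: list[tuple[str, str]] = []
    for cl in cfg.cluster_names:
        groups.append((cl, "tumor"))
        if cl != cfg.focal_cluster and "juxtatumor" in cfg.other_cluster_tissues:
            groups.append((cl, "juxtatumor"))
    groups.append((cfg.reference_cluster, "juxtatumor"))

    # per-(gene, cluster) planted folds
    gene_folds: dict[str, dict[str, float]] = {}
    truth = GroundTruth()
    for ch in cfg.planted_channels:
        rec = db.by_id(ch.interaction_id)
        if ch.focal_cluster not in cfg.cluster_names:
            raise ValueError(f"planted cluster {ch.focal_cluster!r} not in config")
        for g in rec.ligand_subunits:
            if g not in gene_index:
                raise ValueError(f"planted gene {g} absent from gene universe")
            gene_folds.setdefault(g, {})[ch.focal_cluster] = ch.ligand_fold
        for g in rec.receptor_subunits:
            if g not in gene_index:
                raise ValueError(f"planted gene {g} absent from gene universe")
            if ch.receptor_fold != 1.0:
                gene_folds.setdefault(g, {})[ch.focal_cluster] = ch.receptor_fold
        truth.channels.append(
            {
                "interaction_id": ch.interaction_id,
                "focal_cluster": ch.focal_cluster,
                "ligand_fold": ch.ligand_fold,
                "receptor_fold": ch.receptor_fold,
                "direction": ch.direction,
                "expect_specific": ch.ligand_fold >= 1.5 or ch.receptor_fold >= 1.5,
                "expect_de": ch.ligand_fold > 1 or ch.receptor_fold > 1,
            }
        )
    if cfg.planted_family_shift is not None:
        cl, fam, fold = cfg.planted_family_shift
        for rec in db.records:
            if rec.family == fam:
                for g in rec.genes:
                    gene_folds.setdefault(g, {})[cl] = fold
    truth.gene_folds = gene_folds

    blocks, obs_rows = [], []
    for cl, tissue in groups:
        mean = base.copy()
        for g, per_cluster in gene_folds.items():
            if cl in per_cluster and tissue == "tumor":
                mean[gene_index[g]] *= per_cluster[cl]
        m = np.broadcast_to(mean, (cfg.cells_per_cluster, len(genes)))
        counts = _nb_counts(rng, m, cfg.theta)
        if cfg.dropout > 0:
            keep = rng.random(counts.shape) >= cfg.dropout
            counts = counts * keep
        blocks.append(counts)
        for i in range(cfg.cells_per_cluster):
            obs_rows.append(
                {
                    "cluster": cl,
                    "tissue": tissue,
                    "patient": cfg.patients[i % len(cfg.patients)],
                    "dataset": cfg.dataset_name,
                }
            )
    X = np.vstack(blocks).astype(np.float64)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.layers["counts"] = adata.X.copy()
    return adata, truth


# ---------------------------------------------------------------------------
# bulk simulation
# ---------------------------------------------------------------------------

@dataclass
class BulkSimConfig:
    """Study conditions for the bulk tumor/normal generator."""

    n_genes: int = 1000
    n_tumor: int = 60
    n_normal: int = 60
    mu: float = 100.0
    theta: float = 10.0
    gene_mean_sigma: float = 1.0
    libsize_sigma: float = 0.3
    planted_pairs: tuple[tuple[str, float], ...] = ()  # (interaction_id, tumor fold on both partners)
    seed: int = 0

    def __post_init__(self):
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 samples per condition")


def simulate_bulk_dataset(
    cfg: BulkSimConfig, db: InteractionDB
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Generate genes x samples counts, condition labels, and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    comm_genes = sorted(db.genes)
    if len(comm_genes) > cfg.n_genes:
        raise ValueError("n_genes smaller than the database gene universe")
    genes = comm_genes + [f"BG{i:04d}" for i in range(cfg.n_genes - len(comm_genes))]
    gene_index = {g: i for i, g in enumerate(genes)}

    s = cfg.gene_mean_sigma
    base = rng.lognormal(mean=np.log(cfg.mu) - 0.5 * s * s, sigma=s, size=len(genes))

    tumor_fold = np.ones(len(genes))
    truth = GroundTruth()
    for iid, fold in cfg.planted_pairs:
        rec = db.by_id(iid)
        for g in rec.genes:
            tumor_fold[gene_index[g]] = fold
            truth.gene_folds.setdefault(g, {})["tumor"] = fold
        truth.channels.append(
            {"interaction_id": iid, "fold": fold, "expect_significant": fold >= 2}
        )

    n = cfg.n_tumor + cfg.n_normal
    libsize = rng.lognormal(mean=-0.5 * cfg.libsize_sigma**2, sigma=cfg.libsize_sigma, size=n)
    cond = np.array(["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal)
    counts = np.empty((len(genes), n), dtype=np.int64)
    for j in range(n):
        m = base * (tumor_fold if cond[j] == "tumor" else 1.0) * libsize[j]
        counts[:, j] = _nb_counts(rng, m, cfg.theta)
    samples = [f"S{j:03d}" for j in range(n)]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    condition = pd.Series(cond, index=samples, name="condition")
    return df, condition, truth


# ---------------------------------------------------------------------------
# writers matching the preprocessing readers
# ---------------------------------------------------------------------------

def write_mtx_dir(adata: AnnData, path: str | Path) -> None:
    """Write matrix.mtx (genes x cells) + genes.tsv + barcodes.tsv + meta.tsv."""
    import scipy.io
    import scipy.sparse as sp

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.csr_matrix(counts).T.astype(int))
    pd.Series(adata.var_names).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(path / "meta.tsv", sep="\t")
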