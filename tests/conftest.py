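import numpy as np
import pandas as pd
import pytest

import commscreen as cs


@pytest.fixture(scope="session")
def small_db():
    return cs.make_synthetic_db(12)


@pytest.fixture(scope="session")
def planted_dataset(small_db):
    """Default screening scenario with one planted outgoing channel (seed 0),
    QC'd and log-normalized.  Session-scoped: several tests share it."""
    cfg = cs.SimConfig(planted_channels=(cs.PlantedChannel("I003"),), seed=0)
    adata, truth = cs.simulate_sc_dataset(cfg, small_db)
    adata = cs.normalize_log(cs.filter_cells(adata))
    return adata, truth


def random_instance(rng, n_genes=25, n_clusters=6, n_interactions=20):
    """A random small scoring instance: db + per-cluster mean profiles."""
    from commscreen.lr_database import InteractionDB, InteractionRecord, FAMILIES

    genes = [f"G{i:02d}" for i in range(n_genes)]
    records, keys = [], set()
    trials = 0
    while len(records) < n_interactions and trials < 500:
        trials += 1
        lig = tuple(rng.choice(genes, size=rng.integers(1, 3), replace=False))
        rec = tuple(rng.choice(genes, size=rng.integers(1, 4), replace=False))
        key = (frozenset(lig), frozenset(rec))
        if key in keys:
            continue
        keys.add(key)
        records.append(
            InteractionRecord(
                interaction_id=f"R{len(records):03d}",
                ligand_subunits=lig,
                receptor_subunits=rec,
                family=FAMILIES[int(rng.integers(0, 5))],
            )
        )
    db = InteractionDB(records)
    clusters = [f"C{k}" for k in range(n_clusters)]
    mean = pd.DataFrame(
        rng.gamma(2.0, 1.0, size=(n_genes, n_clusters)), index=genes, columns=clusters
    )
    pct = pd.DataFrame(
        rng.uniform(0.2, 1.0, size=(n_genes, n_clusters)), index=genes, columns=clusters
    )
    profiles = cs.ClusterProfiles(
        mean=mean, pct=pct, n_cells=pd.Series(100, index=clusters)
    )
    return db, profiles


def naive_pair_total(db, emitter_mean, receiver_mean, rule):
    """Independent brute-force double loop over records and subunits."""
    total = 0.0
    for r in db.records:
        lv = [float(emitter_mean.get(g, 0.0)) for g in r.ligand_subunits]
        rv = [float(receiver_mean.get(g, 0.0)) for g in r.receptor_subunits]
        agg = min if rule == "minimum" else (lambda v: sum(v) / len(v))
        total += agg(lv) * agg(rv)
    return total
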