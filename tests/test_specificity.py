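import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

import commscreen as cs
from commscreen.lr_database import InteractionDB, InteractionRecord
from commscreen.specificity import (
    SpecificityScreen,
    incoming_interaction_scores,
    intersect_screens,
    outgoing_interaction_scores,
    specificity_filter,
    vocabulary_genes,
    wilcoxon_de,
)

from conftest import random_instance


def _profiles(mean_dict):
    mean = pd.DataFrame(mean_dict)
    return cs.ClusterProfiles(
        mean, pct=mean * 0 + 1.0, n_cells=pd.Series(10, index=mean.columns)
    )


def _db1():
    return InteractionDB([InteractionRecord("I0", ("L",), ("R",), "cytokine")])


class TestInteractionScores:
    def test_outgoing_sums_receptors_over_all_clusters(self):
        prof = _profiles({"A": {"L": 2.0, "R": 1.0}, "B": {"L": 0.0, "R": 2.0},
                          "C": {"L": 0.0, "R": 3.0}})
        (s,) = outgoing_interaction_scores(_db1(), prof, focal="A")
        assert s.value == pytest.approx(2 * 6)
        assert s.per_counterpart.sum() == pytest.approx(s.value)

    def test_zero_ligand_gives_zero(self):
        prof = _profiles({"A": {"L": 0.0, "R": 1.0}, "B": {"L": 1.0, "R": 1.0}})
        (s,) = outgoing_interaction_scores(_db1(), prof, focal="A")
        assert s.value == 0.0

    def test_incoming_mirrors_outgoing(self):
        prof = _profiles({"A": {"L": 1.0, "R": 3.0}, "B": {"L": 1.0, "R": 0.0},
                          "C": {"L": 2.0, "R": 0.0}})
        (s,) = incoming_interaction_scores(_db1(), prof, focal="A")
        assert s.value == pytest.approx(4 * 3)

    def test_autocrine_only_toy_outgoing_equals_incoming(self):
        prof = _profiles({"A": {"L": 1.5, "R": 2.5}, "B": {"L": 0.0, "R": 0.0}})
        (o,) = outgoing_interaction_scores(_db1(), prof, focal="A")
        (i,) = incoming_interaction_scores(_db1(), prof, focal="A")
        assert o.value == pytest.approx(i.value, abs=1e-12)

    def test_additivity_with_pair_scores(self):
        # sum over interactions of the emitter-summed score equals the sum
        # over receivers of the pair-score totals, on random instances
        rng = np.random.default_rng(9)
        for _ in range(5):
            db, profiles = random_instance(rng)
            matrix = cs.all_pair_scores(db, profiles)
            for emitter in profiles.groups:
                eq2 = sum(
                    s.value
                    for s in outgoing_interaction_scores(db, profiles, emitter)
                )
                eq1 = matrix.values.loc[emitter].sum()
                assert eq2 == pytest.approx(eq1, rel=1e-10)


class TestSpecificityFilter:
    def test_pass_at_threshold(self):
        ok, ratio = specificity_filter(pd.Series({"F": 9.0, "B": 6.0, "C": 5.0}), "F")
        assert ok and ratio == pytest.approx(1.5)

    def test_fail_below_threshold(self):
        ok, _ = specificity_filter(pd.Series({"F": 8.9, "B": 6.0, "C": 5.0}), "F")
        assert not ok

    def test_all_competitors_zero_passes_if_positive(self):
        ok, ratio = specificity_filter(pd.Series({"F": 0.2, "B": 0.0}), "F")
        assert ok and np.isinf(ratio)
        ok0, _ = specificity_filter(pd.Series({"F": 0.0, "B": 0.0}), "F")
        assert not ok0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = pd.Series(rng.gamma(1, 1, 5), index=list("FABCD"))
            d1, _ = specificity_filter(s, "F")
            d2, _ = specificity_filter(s * 37.5, "F")
            assert d1 == d2

    def test_missing_focal_raises(self):
        with pytest.raises(KeyError):
            specificity_filter(pd.Series({"A": 1.0}), "F")


def _de_adata(n=200, fold=1.0, n_genes=30, n_shifted=3, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.lognormal(np.log(2), 0.3, n_genes)
    shift = np.where(np.arange(n_genes) < n_shifted, fold, 1.0)
    mean = np.vstack([base * shift, base])  # group1 shifted on a few genes
    counts = np.concatenate(
        [rng.negative_binomial(2, 2 / (2 + mean[0]), size=(n, n_genes)),
         rng.negative_binomial(2, 2 / (2 + mean[1]), size=(n, n_genes))]
    ).astype(float)
    ad = AnnData(
        X=np.log2(counts / counts.sum(1, keepdims=True) * 1e4 + 1),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(2 * n)]),
        var=pd.DataFrame(index=[f"G{i}" for i in range(n_genes)]),
    )
    ad.layers["counts"] = counts
    g1 = np.arange(2 * n) < n
    return ad, g1


class TestWilcoxonDE:
    def test_identical_groups_select_nothing(self):
        ad, g1 = _de_adata(fold=1.0)
        de = wilcoxon_de(ad, g1, ~g1)
        assert not de["selected"].any()
        assert de["log2fc"].abs().max() < 0.25 or not de["tested"].all()

    def test_planted_four_fold_shift_selected(self):
        ad, g1 = _de_adata(fold=4.0, seed=1)
        de = wilcoxon_de(ad, g1, ~g1)
        assert de["selected"].iloc[:3].all()
        assert not de["selected"].iloc[3:].any()

    def test_bonferroni_over_tested_genes_only(self):
        ad, g1 = _de_adata(fold=4.0, seed=2)
        de = wilcoxon_de(ad, g1, ~g1)
        tested = de[de["tested"]]
        np.testing.assert_allclose(
            tested["p_adj"], np.minimum(tested["p"] * len(tested), 1.0), rtol=1e-12
        )

    def test_empty_group_raises(self):
        ad, g1 = _de_adata(n=5)
        with pytest.raises(ValueError):
            wilcoxon_de(ad, np.zeros(10, dtype=bool), ~np.zeros(10, dtype=bool))

    def test_null_selection_rate_controlled(self):
        # label shuffles: Bonferroni keeps selections at ~zero
        rng = np.random.default_rng(3)
        ad, g1 = _de_adata(fold=1.0, n=100, seed=4)
        n_sel = 0
        for _ in range(20):
            perm = rng.permutation(len(g1))
            n_sel += int(wilcoxon_de(ad, g1[perm], ~g1[perm])["selected"].sum())
        assert n_sel <= 2


class TestVocabularyGenes:
    def _adata(self):
        # G0: strong fold vs both clusters (branch 1)
        # G1: small fold, rare in others (branch 2)
        # G2: up vs B only -> excluded by the intersection
        rng = np.random.default_rng(5)
        n = 250
        groups = {"F": {}, "B": {}, "C": {}}
        groups["F"]["G0"], groups["B"]["G0"], groups["C"]["G0"] = 6.0, 2.0, 2.0
        groups["F"]["G1"], groups["B"]["G1"], groups["C"]["G1"] = 0.35, 0.05, 0.05
        groups["F"]["G2"], groups["B"]["G2"], groups["C"]["G2"] = 6.0, 2.0, 6.0
        counts = []
        clusters = []
        for cl, means in groups.items():
            m = np.array([means["G0"], means["G1"], means["G2"]])
            counts.append(rng.negative_binomial(2, 2 / (2 + m), size=(n, 3)))
            clusters += [cl] * n
        counts = np.concatenate(counts).astype(float)
        pad = rng.poisson(3.0, size=(len(counts), 40))  # background library
        counts = np.hstack([counts, pad])
        ad = AnnData(
            X=np.log2(counts / counts.sum(1, keepdims=True) * 1e4 + 1),
            obs=pd.DataFrame(
                {"cluster": clusters}, index=[f"c{i}" for i in range(len(clusters))]
            ),
            var=pd.DataFrame(index=["G0", "G1", "G2"] + [f"BG{i}" for i in range(40)]),
        )
        ad.layers["counts"] = counts
        return ad

    def test_branches_and_intersection(self):
        ad = self._adata()
        genes = vocabulary_genes(ad, "F", ["B", "C"], comm_genes={"G0", "G1", "G2"})
        assert "G0" in genes  # branch 1
        assert "G1" in genes  # branch 2 (rare in others)
        assert "G2" not in genes  # fails one pairwise comparison

    def test_empty_others_raise(self):
        with pytest.raises(ValueError):
            vocabulary_genes(self._adata(), "F", [], comm_genes={"G0"})


class TestScreen:
    def test_planted_channel_is_unique_final_hit(self, small_db, planted_dataset):
        adata, truth = planted_dataset
        scr = SpecificityScreen(db=small_db, focal="cancer", reference="PT").fit(adata)
        hits = scr.hits("outgoing")
        assert list(hits["interaction_id"]) == ["I003"]
        assert (hits["ratio"] >= 1.5).all()

    def test_ubiquitous_interactions_fail_specificity(self, small_db, planted_dataset):
        adata, _ = planted_dataset
        scr = SpecificityScreen(db=small_db, focal="cancer", reference="PT").fit(adata)
        res = scr.results_
        others = res[(res["interaction_id"] != "I003") & (res["direction"] == "outgoing")]
        assert not others["final"].any()

    def test_specific_but_not_upregulated_fails_de_gate(self, small_db):
        # ligand folded in the focal cluster AND in the juxtatumor reference:
        # specific among tumor clusters, but not up vs the reference
        cfg = cs.SimConfig(
            n_clusters=4, cells_per_cluster=150, n_genes=300, seed=21,
            planted_channels=(cs.PlantedChannel("I001", ligand_fold=12.0),),
        )
        adata, _ = cs.simulate_sc_dataset(cfg, small_db)
        lig = small_db.by_id("I001").ligand_subunits[0]
        ref = (adata.obs["cluster"] == "PT").to_numpy()
        gi = list(adata.var_names).index(lig)
        adata.X[np.ix_(ref, [gi])] *= 12.0  # reference matches the focal level
        adata.layers["counts"] = adata.X.copy()
        adata = cs.normalize_log(adata)
        scr = SpecificityScreen(db=small_db, focal="cancer", reference="PT").fit(adata)
        row = scr.results_.query("interaction_id == 'I001' and direction == 'outgoing'").iloc[0]
        assert row["passes_specificity"] and not row["passes_de"] and not row["final"]

    def test_missing_reference_cluster_raises(self, small_db, planted_dataset):
        adata, _ = planted_dataset
        with pytest.raises(ValueError):
            SpecificityScreen(db=small_db, focal="cancer", reference="NOPE").fit(adata)


class TestIntersect:
    def _result(self, hits):
        rows = [
            {"interaction_id": iid, "direction": d, "final": True} for iid, d in hits
        ]
        rows.append({"interaction_id": "IX", "direction": "outgoing", "final": False})
        return pd.DataFrame(rows)

    def test_tiers(self):
        res = {
            "d1": self._result([("I1", "outgoing"), ("I2", "outgoing")]),
            "d2": self._result([("I1", "outgoing"), ("I2", "outgoing")]),
            "d3": self._result([("I1", "outgoing")]),
        }
        table = intersect_screens(res).set_index("interaction_id")
        assert table.loc["I1", "tier"] == "all"
        assert table.loc["I2", "tier"] == ">=2"

    def test_single_dataset_hits_excluded(self):
        res = {
            "d1": self._result([("I9", "incoming")]),
            "d2": self._result([]),
            "d3": self._result([]),
        }
        assert len(intersect_screens(res)) == 0

    def test_fewer_than_two_datasets_raise(self):
        with pytest.raises(ValueError):
            intersect_screens({"d1": self._result([])})
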