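import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from commscreen.preprocessing import (
    CellQC,
    ClusterProfiles,
    EmptyResultError,
    apply_min_pct_filter,
    attach_meta,
    compute_profiles,
    filter_cells,
    normalize_log,
    read_dense_tsv,
    read_mtx_dir,
)
from commscreen.simulate import SimConfig, make_synthetic_db, simulate_sc_dataset, write_mtx_dir


def _adata(counts, genes=None, obs=None):
    counts = np.asarray(counts, dtype=float)
    genes = genes or [f"G{i}" for i in range(counts.shape[1])]
    ad = AnnData(
        X=counts.copy(),
        obs=obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])]),
        var=pd.DataFrame(index=genes),
    )
    ad.layers["counts"] = counts.copy()
    return ad


class TestCellQC:
    def _three_cells(self):
        # columns: MT-1 plus 599 nuclear genes
        genes = ["MT-1"] + [f"G{i}" for i in range(599)]
        rows = []
        # cell 0: 150 genes, 1200 UMI, 5% mito -> removed (min_genes)
        c = np.zeros(600); c[1:150] = 8; c[0] = 60; rows.append(c)
        # cell 1: 500 genes, 2000 UMI, 25% mito -> removed (mito)
        c = np.zeros(600); c[1:500] = 3; c[0] = 499; rows.append(c)
        # cell 2: 500 genes, 2000 UMI, 5% mito -> retained
        c = np.zeros(600); c[1:500] = 4; c[0] = 105; rows.append(c)
        return _adata(np.array(rows), genes=genes)

    def test_gates(self):
        ad = self._three_cells()
        qc = CellQC().fit(ad)
        assert list(qc.keep_mask_) == [False, False, True]
        assert qc.n_removed_["min_genes"] == 1
        assert qc.n_removed_["max_mito_frac"] == 1

    def test_idempotent(self):
        ad = filter_cells(self._three_cells())
        ad2 = filter_cells(ad)
        assert ad2.n_obs == ad.n_obs

    def test_all_removed_raises(self):
        ad = _adata(np.ones((2, 5)))
        with pytest.raises(EmptyResultError):
            filter_cells(ad)


class TestNormalize:
    def test_closed_form(self):
        ad = _adata([[10, 9990], [5, 4995]])
        out = normalize_log(ad)
        # count 10 in a 10000-total cell at scale 10000 -> log2(11)
        assert out.X[0, 0] == pytest.approx(np.log2(11), abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        ad = _adata([[0, 100], [3, 97]])
        out = normalize_log(ad)
        assert out.X[0, 0] == 0.0
        assert (out.X == 0).sum() == (ad.layers["counts"] == 0).sum()

    def test_library_size_invariance(self):
        ad = _adata([[2, 4, 6], [4, 8, 12]])
        out = normalize_log(ad)
        np.testing.assert_allclose(out.X[0], out.X[1], atol=1e-12)

    def test_zero_total_cell_raises(self):
        with pytest.raises(ValueError):
            normalize_log(_adata([[0, 0], [1, 2]]))

    def test_provenance_recorded(self):
        out = normalize_log(_adata([[1, 2]]), scale=5000, pseudocount=1)
        assert out.uns["normalization"] == {"scale": 5000, "pseudocount": 1, "log_base": 2}


def _meta(clusters, tissues=None):
    n = len(clusters)
    return pd.DataFrame(
        {
            "cluster": clusters,
            "tissue": tissues or ["tumor"] * n,
            "patient": ["P1"] * n,
            "dataset": ["d"] * n,
        },
        index=[f"c{i}" for i in range(n)],
    )


class TestProfiles:
    def test_mean_and_pct(self):
        ad = _adata([[0], [0], [3]])
        ad.X = np.array([[0.0], [0.0], [3.0]])
        ad.obs = _meta(["A", "A", "A"])
        prof = compute_profiles(ad)
        assert prof.mean.loc["G0", "A"] == pytest.approx(1.0)
        assert prof.pct.loc["G0", "A"] == pytest.approx(1 / 3)
        assert prof.n_cells["A"] == 3

    def test_single_cell_group_is_identity(self):
        ad = _adata([[1, 2, 3]])
        ad.obs = _meta(["A"])
        prof = compute_profiles(ad)
        np.testing.assert_allclose(prof.mean["A"].values, [1, 2, 3])

    def test_cell_order_permutation_invariant(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2, size=(20, 5)).astype(float)
        clusters = ["A"] * 10 + ["B"] * 10
        ad = _adata(X); ad.obs = _meta(clusters)
        perm = rng.permutation(20)
        ad2 = _adata(X[perm])
        ad2.obs = _meta([clusters[i] for i in perm])
        p1, p2 = compute_profiles(ad), compute_profiles(ad2)
        np.testing.assert_allclose(p1.mean.values, p2.mean.values, atol=1e-12)
        np.testing.assert_allclose(p1.pct.values, p2.pct.values, atol=1e-12)

    def test_grouping_by_cluster_and_tissue(self):
        ad = _adata([[1], [3], [5]])
        ad.obs = _meta(["A", "A", "A"], ["tumor", "tumor", "juxtatumor"])
        prof = compute_profiles(ad, group_by=("cluster", "tissue"))
        assert set(prof.groups) == {"A|tumor", "A|juxtatumor"}

    def test_means_bounded_by_group_extrema(self):
        rng = np.random.default_rng(1)
        X = rng.gamma(2, 1, size=(30, 8))
        ad = _adata(X); ad.obs = _meta(["A"] * 15 + ["B"] * 15)
        prof = compute_profiles(ad)
        for g, mask in (("A", slice(0, 15)), ("B", slice(15, 30))):
            assert (prof.mean[g].values <= X[mask].max(axis=0) + 1e-12).all()
            assert (prof.mean[g].values >= X[mask].min(axis=0) - 1e-12).all()


class TestMinPctFilter:
    def _profiles(self):
        mean = pd.DataFrame({"A": [2.0, 1.0], "B": [3.0, 1.0]}, index=["G1", "G2"])
        pct = pd.DataFrame({"A": [0.05, 0.10], "B": [0.40, 0.50]}, index=["G1", "G2"])
        return ClusterProfiles(mean, pct, pd.Series({"A": 10, "B": 10}))

    def test_zeroed_only_in_low_pct_cluster(self):
        out = apply_min_pct_filter(self._profiles(), {"G1"})
        assert out.mean.loc["G1", "A"] == 0.0
        assert out.mean.loc["G1", "B"] == 3.0

    def test_boundary_pct_is_kept(self):
        out = apply_min_pct_filter(self._profiles(), {"G2"})
        assert out.mean.loc["G2", "A"] == 1.0  # pct exactly 0.10, strict less-than

    def test_untouched_genes_and_monotonicity(self):
        prof = self._profiles()
        out = apply_min_pct_filter(prof, {"G1"})
        assert (out.mean.loc["G2"] == prof.mean.loc["G2"]).all()
        assert (out.mean.values <= prof.mean.values + 1e-15).all()

    def test_absent_gene_is_ignored(self):
        out = apply_min_pct_filter(self._profiles(), {"NOPE"})
        assert (out.mean.values == self._profiles().mean.values).all()


class TestIO:
    def test_mtx_round_trip(self, tmp_path):
        db = make_synthetic_db(5)
        cfg = SimConfig(n_clusters=2, cells_per_cluster=10, n_genes=30, seed=0)
        adata, _ = simulate_sc_dataset(cfg, db)
        write_mtx_dir(adata, tmp_path)
        back = read_mtx_dir(tmp_path)
        np.testing.assert_array_equal(
            np.asarray(back.layers["counts"].todense()), adata.layers["counts"]
        )
        assert list(back.var_names) == list(adata.var_names)
        meta = pd.read_csv(tmp_path / "meta.tsv", sep="\t", index_col=0, dtype=str)
        attach_meta(back, meta)
        assert list(back.obs["cluster"]) == list(adata.obs["cluster"])

    def test_dense_tsv_reader(self, tmp_path):
        df = pd.DataFrame([[1, 0], [2, 5]], index=["G1", "G2"], columns=["c1", "c2"])
        path = tmp_path / "m.tsv"
        df.to_csv(path, sep="\t")
        ad = read_dense_tsv(path)
        assert ad.shape == (2, 2)  # cells x genes
        assert ad.X[1, 0] == 0.0  # cell c2, gene G1
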