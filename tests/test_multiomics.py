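import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from clinomics.data_io import ClinicalTable, LabelSpec, OmicMatrix
from clinomics.multiomics import (SimilarityMatrix, build_collection,
                                  consensus_cluster, interomic_correlation,
                                  nemo_cluster, snf_cluster, snf_fuse,
                                  spectral_partition)
from clinomics.multiomics import _affinity, _full_kernel, _sparse_kernel
from clinomics.simulate import make_dataset


def planted_collection(n_per=20, k=2, n_feat=60, effect=4.0, seed=0,
                       n_omics=2):
    """k planted sample blocks expressed independently in each omic."""
    rng = np.random.default_rng(seed)
    n = n_per * k
    samples = [f"s{i}" for i in range(n)]
    truth = np.repeat(np.arange(1, k + 1), n_per)
    omics = []
    for v in range(n_omics):
        X = rng.standard_normal((n_feat, n))
        n_shift = max(1, n_feat // 10)
        for c in range(1, k + 1):
            idx = rng.choice(n_feat, n_shift, replace=False)
            X[np.ix_(idx, np.where(truth == c)[0])] += effect
        omics.append(OmicMatrix(f"omic{v}", [f"f{v}_{i}" for i in range(n_feat)],
                                samples, X))
    clinical = ClinicalTable(samples)
    clinical.add_label("subtype", pd.Series([f"c{c}" for c in truth], index=samples),
                       LabelSpec("subtype", "categorical"))
    return build_collection(omics, clinical), truth


class TestBuildCollection:
    def test_intersect_restricts_all(self):
        samples = ["a", "b", "c", "d"]
        m1 = OmicMatrix("x", ["g1"], ["a", "b", "c"], np.ones((1, 3)))
        m2 = OmicMatrix("y", ["g1"], ["b", "c", "d"], np.ones((1, 3)))
        clin = ClinicalTable(samples)
        coll = build_collection([m1, m2], clin, "intersect")
        assert coll.omics["x"].sample_ids == ["b", "c"]
        assert coll.omics["y"].sample_ids == ["b", "c"]

    def test_union_keeps_coverage(self):
        m1 = OmicMatrix("x", ["g1"], ["a", "b"], np.ones((1, 2)))
        m2 = OmicMatrix("y", ["g1"], ["b", "c"], np.ones((1, 2)))
        clin = ClinicalTable(["a", "b", "c"])
        coll = build_collection([m1, m2], clin, "union")
        assert coll.sample_universe == ["a", "b", "c"]

    def test_duplicate_names_error(self):
        m = OmicMatrix("x", ["g1"], ["a"], np.ones((1, 1)))
        with pytest.raises(ValueError, match="duplicate"):
            build_collection([m, m.copy()], ClinicalTable(["a"]))

    def test_empty_intersection_error(self):
        m1 = OmicMatrix("x", ["g1"], ["a"], np.ones((1, 1)))
        m2 = OmicMatrix("y", ["g1"], ["b"], np.ones((1, 1)))
        with pytest.raises(ValueError, match="intersection"):
            build_collection([m1, m2], ClinicalTable(["a", "b"]), "intersect")


class TestSNF:
    def test_recovers_planted_blocks(self):
        coll, truth = planted_collection(seed=1)
        part, fused = snf_cluster(coll, k=2, seed=0)
        assert adjusted_rand_score(truth, part.labels_for(fused.sample_ids)) == 1.0
        W = fused.matrix
        within = np.concatenate([W[:20, :20].ravel(), W[20:, 20:].ravel()])
        between = W[:20, 20:].ravel()
        assert within.mean() > between.mean()

    def test_fused_matrix_contracts(self):
        coll, _ = planted_collection(seed=2)
        fused = snf_fuse(coll)
        A = fused.matrix
        assert np.allclose(A, A.T, atol=1e-9)
        assert (A >= -1e-12).all()
        rows = fused.row_normalized().sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-9)

    def test_identical_omics_equal_single_view_diffusion(self):
        """Cross-diffusion over copies of one omic reduces to that omic's own
        diffusion (fixed-point sanity)."""
        coll, _ = planted_collection(seed=3, n_omics=1)
        om = list(coll.omics.values())[0]
        twin = om.copy()
        twin.omic_name = "twin"
        clin = coll.clinical
        coll2 = build_collection([om, twin], clin)
        fused = snf_fuse(coll2, K=10, T=8)
        # manual single-view diffusion with the same kernels
        from clinomics.multiomics import _sample_distances
        W = _affinity(_sample_distances(om), 10, 0.5)
        P, S = _full_kernel(W), _sparse_kernel(W, 10)
        for _ in range(8):
            P = S @ P @ S.T
            P = (P + P.T) / 2.0 + np.eye(len(P))
        P = P / P.sum(axis=1, keepdims=True)
        P = (P + P.T) / 2.0
        np.testing.assert_allclose(fused.matrix, P, atol=1e-6)

    def test_mismatched_samples_rejected(self):
        m1 = OmicMatrix("x", ["g1", "g2"], ["a", "b", "c"], np.eye(2, 3))
        m2 = OmicMatrix("y", ["g1", "g2"], ["a", "b", "d"], np.eye(2, 3))
        clin = ClinicalTable(["a", "b", "c", "d"])
        from clinomics.data_io import DatasetCollection
        coll = DatasetCollection(omics={"x": m1, "y": m2}, clinical=clin)
        with pytest.raises(ValueError, match="identical sample"):
            snf_cluster(coll, k=2)


class TestSpectral:
    def test_exact_two_block_affinity_recovers_components(self):
        n = 12
        W = np.zeros((n, n))
        W[:6, :6] = 0.8
        W[6:, 6:] = 0.8
        np.fill_diagonal(W, 1.0)
        sim = SimilarityMatrix([f"s{i}" for i in range(n)], W)
        part = spectral_partition(sim, 2, seed=0)
        labels = part.labels_for(sim.sample_ids)
        assert adjusted_rand_score([0] * 6 + [1] * 6, labels) == 1.0


class TestNEMO:
    def test_planted_blocks_auto_k(self):
        coll, truth = planted_collection(seed=4)
        part = nemo_cluster(coll, seed=0)
        assert part.k == 2
        assert adjusted_rand_score(truth, part.labels_for(
            list(coll.omics.values())[0].sample_ids)) == 1.0

    def test_omic_order_invariance(self):
        coll, _ = planted_collection(seed=5)
        omics = list(coll.omics.values())
        rev = build_collection(omics[::-1], coll.clinical)
        a = nemo_cluster(coll, seed=1)
        b = nemo_cluster(rev, seed=1)
        ids = omics[0].sample_ids
        assert adjusted_rand_score(a.labels_for(ids), b.labels_for(ids)) == 1.0


class TestConsensus:
    def test_separable_blocks_pac_zero(self):
        coll, truth = planted_collection(seed=6, effect=5.0)
        res = consensus_cluster(coll, k_range=(2,), n_resamples=25, seed=0)
        C = res.consensus[2]
        tri = C[np.triu_indices(len(truth), 1)]
        assert res.pac[2] == 0.0
        assert np.isin(tri, (0.0, 1.0)).all()
        # consensus 1 exactly for co-membership
        same = (truth[:, None] == truth[None, :])[np.triu_indices(len(truth), 1)]
        assert np.array_equal(tri == 1.0, same)

    def test_contract_bounds_and_symmetry(self):
        coll, _ = planted_collection(seed=7, effect=1.0)
        res = consensus_cluster(coll, k_range=(2, 3), n_resamples=15, seed=1)
        for C in res.consensus.values():
            assert np.allclose(C, C.T)
            assert (C >= 0).all() and (C <= 1).all()
            assert np.allclose(np.diag(C), 1.0)

    def test_selects_planted_k3(self):
        coll, truth = planted_collection(n_per=15, k=3, effect=4.0, seed=8)
        res = consensus_cluster(coll, k_range=(2, 3, 4, 5), n_resamples=30, seed=2)
        assert res.selected_k == 3
        ids = res.sample_ids
        assert adjusted_rand_score(truth, res.partition.labels_for(ids)) > 0.9

    def test_validation(self):
        coll, _ = planted_collection(seed=9)
        with pytest.raises(ValueError, match="k_range"):
            consensus_cluster(coll, k_range=())
        with pytest.raises(ValueError, match="sample_fraction"):
            consensus_cluster(coll, k_range=(2,), sample_fraction=0.3)


class TestInterOmic:
    def test_planted_anticorrelation_detected(self):
        coll, truth = make_dataset(n_samples=120, k_subtypes=2, seed=10,
                                   n_features={"expression": 150,
                                               "methylation": 60, "cnv": 30})
        coll = build_collection(list(coll.omics.values()), coll.clinical)
        tab = interomic_correlation(coll, "expression", "methylation",
                                    method="spearman")
        top = tab.iloc[0]
        assert top.feature_a in truth.anti_correlated_features
        assert top.r < -0.8

    def test_monotone_transform_gives_r_minus_one(self):
        rng = np.random.default_rng(11)
        samples = [f"s{i}" for i in range(30)]
        x = rng.standard_normal(30)
        e = OmicMatrix("expr", ["g"], samples, x[None, :])
        meth = OmicMatrix("meth", ["g"], samples,
                          (1 / (1 + np.exp(x)))[None, :])  # decreasing in x
        coll = build_collection([e, meth], ClinicalTable(samples))
        tab = interomic_correlation(coll, "expr", "meth", method="spearman")
        assert tab.r.iloc[0] == pytest.approx(-1.0)

    def test_all_pairs_topn_row_count(self):
        rng = np.random.default_rng(12)
        samples = [f"s{i}" for i in range(20)]
        a = OmicMatrix("a", [f"x{i}" for i in range(6)], samples,
                       rng.standard_normal((6, 20)))
        b = OmicMatrix("b", [f"y{i}" for i in range(7)], samples,
                       rng.standard_normal((7, 20)))
        coll = build_collection([a, b], ClinicalTable(samples))
        tab = interomic_correlation(coll, "a", "b", pairing="all_pairs_topN",
                                    top_n=10)
        assert len(tab) == 10

    def test_no_shared_features_error(self):
        samples = ["a", "b", "c"]
        m1 = OmicMatrix("x", ["g1"], samples, np.arange(3.0)[None, :])
        m2 = OmicMatrix("y", ["h1"], samples, np.arange(3.0)[None, :])
        coll = build_collection([m1, m2], ClinicalTable(samples))
        with pytest.raises(ValueError, match="shared feature"):
            interomic_correlation(coll, "x", "y")
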