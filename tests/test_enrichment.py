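import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clinomics.data_io import (ClinicalTable, GeneSetCollection, LabelSpec,
                               Partition)
from clinomics.enrichment import (gene_set_enrichment, hypergeom_upper_tail,
                                  multi_label_enrichment,
                                  single_label_enrichment)


def enumerate_upper_tail(overlap, N, K, n):
    """Oracle: exhaustively enumerate all C(N, n) draws."""
    pop = [1] * K + [0] * (N - K)
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += sum(pop[i] for i in draw) >= overlap
    return hits / total


class TestHypergeometric:
    def test_matches_enumeration_small_sweep(self):
        """p equals exhaustive enumeration over a grid of small populations."""
        for N in (4, 7, 10):
            for K in range(N + 1):
                for n in range(N + 1):
                    for x in range(min(K, n) + 2):
                        assert hypergeom_upper_tail(x, N, K, n) == pytest.approx(
                            enumerate_upper_tail(x, N, K, n), abs=1e-12)

    def test_perfect_overlap_example(self):
        # cluster of 5 of 10 samples exactly matching the 5 positives
        assert hypergeom_upper_tail(5, 10, 5, 5) == pytest.approx(
            1 / math.comb(10, 5))

    def test_overlap_zero_is_certain(self):
        assert hypergeom_upper_tail(0, 100, 10, 10) == 1.0


def clinical_with(labels: dict, samples) -> ClinicalTable:
    ct = ClinicalTable(samples)
    for name, (kind, values, extra) in labels.items():
        if kind == "survival":
            ct.add_label(name, pd.DataFrame(values, index=samples),
                         LabelSpec(name, kind))
        else:
            ct.add_label(name, pd.Series(values, index=samples),
                         LabelSpec(name, kind, extra))
    return ct


class TestMultiLabelEnrichment:
    def test_perfect_binary_label_p(self):
        samples = [f"s{i}" for i in range(10)]
        part = Partition.from_labels("samples", samples, [1] * 5 + [2] * 5)
        ct = clinical_with(
            {"flag": ("categorical", ["pos"] * 5 + ["neg"] * 5, None)}, samples)
        rep = multi_label_enrichment(part, ct)
        cell = rep[(rep.cluster == 1) & rep.summary.str.contains("category=pos")]
        assert cell.p.iloc[0] == pytest.approx(1 / 252)

    def test_constant_label_skipped(self):
        samples = [f"s{i}" for i in range(6)]
        part = Partition.from_labels("samples", samples, [1, 1, 1, 2, 2, 2])
        ct = clinical_with({"const": ("categorical", ["x"] * 6, None)}, samples)
        rep = multi_label_enrichment(part, ct)
        assert rep.summary.str.contains("skipped").all()
        assert rep.p.isna().all()

    def test_all_four_types_reported(self):
        samples = [f"s{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        part = Partition.from_labels("samples", samples, [1] * 6 + [2] * 6)
        ct = clinical_with({
            "cat": ("categorical", list("aabbab") * 2, None),
            "num": ("numeric", rng.normal(size=12), None),
            "ordn": ("ordinal", ["lo", "mid", "hi"] * 4, ["lo", "mid", "hi"]),
            "OS": ("survival", {"time": rng.exponential(10, 12),
                                "event": rng.integers(0, 2, 12)}, None),
        }, samples)
        rep = multi_label_enrichment(part, ct)
        lvl = rep[rep.cluster == "all"]
        assert set(lvl.label_type) == {"categorical", "numeric", "ordinal", "survival"}
        assert lvl.q.notna().all()

    def test_bh_stratified_by_type(self):
        """Adding a label of a different type leaves existing q-values unchanged."""
        samples = [f"s{i}" for i in range(20)]
        rng = np.random.default_rng(1)
        part = Partition.from_labels("samples", samples, [1] * 10 + [2] * 10)
        base = {f"num{i}": ("numeric", rng.normal(size=20), None) for i in range(4)}
        ct1 = clinical_with(base, samples)
        ct2 = clinical_with({**base, "cat": ("categorical", list("ab") * 10, None)},
                            samples)
        q1 = multi_label_enrichment(part, ct1)
        q2 = multi_label_enrichment(part, ct2)
        lvl1 = q1[(q1.cluster == "all")].set_index("label").q
        lvl2 = q2[(q2.cluster == "all") & (q2.label_type == "numeric")].set_index("label").q
        pd.testing.assert_series_equal(lvl1, lvl2.loc[lvl1.index])

    def test_requires_two_clusters(self):
        samples = ["a", "b"]
        part = Partition.from_labels("samples", samples, [1, 1])
        ct = clinical_with({"x": ("categorical", ["u", "v"], None)}, samples)
        with pytest.raises(ValueError, match="2 clusters"):
            multi_label_enrichment(part, ct)


class TestSingleLabelEnrichment:
    def test_count_table_totals(self):
        samples = [f"s{i}" for i in range(9)]
        part = Partition.from_labels("samples", samples, [1, 1, 1, 2, 2, 2, 3, 3, 3])
        ct = clinical_with({"cat": ("categorical", list("xyzxyzxyz"), None)}, samples)
        rep, dist = single_label_enrichment(part, ct, "cat")
        assert dist.to_numpy().sum() == 9
        assert dist.shape == (3, 3)

    def test_cluster_equals_category_minimal_p(self):
        samples = [f"s{i}" for i in range(8)]
        part = Partition.from_labels("samples", samples, [1] * 4 + [2] * 4)
        ct = clinical_with({"cat": ("categorical", ["a"] * 4 + ["b"] * 4, None)},
                           samples)
        rep, _ = single_label_enrichment(part, ct, "cat")
        cells = rep[rep.cluster != "all"].dropna(subset=["p"])
        perfect = cells[(cells.cluster == 1) & cells.summary.str.contains("category=a")]
        assert perfect.p.iloc[0] == cells.p.min()

    def test_numeric_order_invariance(self):
        samples = [f"s{i}" for i in range(10)]
        vals = np.arange(10.0)
        part = Partition.from_labels("samples", samples, [1, 2] * 5)
        ct = clinical_with({"num": ("numeric", vals, None)}, samples)
        rep1, dist1 = single_label_enrichment(part, ct, "num")
        perm = np.random.default_rng(0).permutation(10)
        samples_p = [samples[i] for i in perm]
        ct2 = clinical_with({"num": ("numeric", vals[perm], None)}, samples_p)
        part2 = Partition.from_labels(
            "samples", samples_p, [part.assignments[s] for s in samples_p])
        rep2, dist2 = single_label_enrichment(part2, ct2, "num")
        pd.testing.assert_frame_equal(dist1, dist2)
        pd.testing.assert_series_equal(rep1.set_index(["cluster", "test"]).p,
                                       rep2.set_index(["cluster", "test"]).p)

    def test_unknown_label(self):
        samples = ["a", "b"]
        part = Partition.from_labels("samples", samples, [1, 2])
        ct = clinical_with({"x": ("categorical", ["u", "v"], None)}, samples)
        with pytest.raises(KeyError):
            single_label_enrichment(part, ct, "nope")


class TestGeneSetEnrichment:
    def test_full_overlap_closed_form(self):
        background = [f"g{i}" for i in range(100)]
        part = Partition.from_labels("features", background,
                                     [1] * 10 + [2] * 90)
        sets = GeneSetCollection(sets={"hit": ("", background[:10]),
                                       "miss": ("", background[50:60])})
        rep = gene_set_enrichment(part, sets, background)
        hit = rep[(rep.cluster == 1) & (rep.set == "hit")]
        assert hit.p.iloc[0] == pytest.approx(1 / math.comb(100, 10))
        miss = rep[(rep.cluster == 1) & (rep.set == "miss")]
        assert miss.overlap.iloc[0] == 0 and miss.p.iloc[0] == 1.0

    def test_top_n_per_cluster(self):
        background = [f"g{i}" for i in range(40)]
        part = Partition.from_labels("features", background, [1] * 20 + [2] * 20)
        sets = GeneSetCollection(sets={f"s{i}": ("", background[i:i + 8])
                                       for i in range(10)})
        rep = gene_set_enrichment(part, sets, background, top_n=5)
        assert (rep.groupby("cluster").size() <= 5).all()

    def test_inert_background_extension_preserves_order(self):
        background = [f"g{i}" for i in range(30)]
        part = Partition.from_labels("features", background, [1] * 15 + [2] * 15)
        sets = GeneSetCollection(sets={"a": ("", background[:10]),
                                       "b": ("", background[5:20]),
                                       "c": ("", background[20:28])})
        r1 = gene_set_enrichment(part, sets, background, top_n=10)
        extended = background + [f"extra{i}" for i in range(30)]
        # extra genes are in the background but in no set and no cluster —
        # ranking within each cluster must be preserved
        r2 = gene_set_enrichment(part, sets, extended, top_n=10)
        for c in (1, 2):
            o1 = r1[r1.cluster == c].set_index("set").p.rank().sort_index()
            o2 = r2[r2.cluster == c].set_index("set").p.rank().sort_index()
            pd.testing.assert_series_equal(o1, o2)

    def test_uncovered_features_error(self):
        part = Partition.from_labels("features", ["g1", "g2"], [1, 2])
        sets = GeneSetCollection(sets={"s": ("", ["g1"])})
        with pytest.raises(ValueError, match="background"):
            gene_set_enrichment(part, sets, ["g1"])
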