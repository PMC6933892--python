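import json

import numpy as np
import pandas as pd
import pytest

from clinomics import data_io as dio
from clinomics.data_io import (ClinicalTable, DatasetCollection, LabelSpec,
                               OmicMatrix, Partition)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestTabularMatrix:
    def test_basic_parse(self, tmp_path):
        p = write(tmp_path, "m.tsv", "id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
        m = dio.read_tabular_matrix(p)
        assert m.feature_ids == ["g1", "g2", "g3"]
        assert m.sample_ids == ["s1", "s2"]
        assert m.values.shape == (3, 2)
        assert m.values[2, 1] == 6.0

    def test_orientation_transpose_identity(self, tmp_path):
        p = write(tmp_path, "m.tsv", "id\ta\tb\tc\nr1\t1\t2\t3\nr2\t4\t5\t6\n")
        feat = dio.read_tabular_matrix(p, orientation="features_in_rows")
        samp = dio.read_tabular_matrix(p, orientation="samples_in_rows")
        assert samp.values.shape == feat.values.T.shape
        np.testing.assert_array_equal(samp.values, feat.values.T)
        assert samp.feature_ids == feat.sample_ids

    def test_missing_tokens_masked(self, tmp_path):
        p = write(tmp_path, "m.tsv", "id\ts1\ts2\ng1\tNA\t2\ng2\t3\tnull\n")
        m = dio.read_tabular_matrix(p)
        assert m.mask[0, 0] and m.mask[1, 1]
        assert m.mask.sum() == 2

    @pytest.mark.parametrize("body,err", [
        ("id\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n", "duplicate"),
        ("id\ts1\ts2\ng1\t1\n", "ragged"),
        ("id\ts1\ts2\ng1\t1\tabc\n", "non-numeric"),
    ])
    def test_errors(self, tmp_path, body, err):
        p = write(tmp_path, "bad.tsv", body)
        with pytest.raises(ValueError, match=err):
            dio.read_tabular_matrix(p)


class TestXenaPair:
    def test_pair_with_survival(self, tmp_path):
        mp = write(tmp_path, "mat.tsv",
                   "sample\tA\tB\tC\ng1\t1\t2\t3\ng2\t4\t5\t6\n")
        pp = write(tmp_path, "ph.tsv",
                   "sample\tstage\tOS.time\tOS\nA\tII\t100\t1\nB\tI\t200\t0\nC\tII\t50\t1\n")
        m, clin = dio.read_xena_pair(mp, pp, survival_pairs={"surv": ("OS.time", "OS")})
        assert m.n_samples == 3
        assert clin.kind("stage") == "categorical"
        t, e = clin.get_survival("surv")
        assert t["A"] == 100 and e["B"] == 0

    def test_intersection_warns(self, tmp_path):
        mp = write(tmp_path, "mat.tsv", "id\ta\tb\ng1\t1\t2\n")
        pp = write(tmp_path, "ph.tsv", "sample\tx\nb\t1\nc\t2\n")
        with pytest.warns(UserWarning, match="intersection"):
            m, clin = dio.read_xena_pair(mp, pp)
        assert m.sample_ids == ["b"]

    def test_empty_intersection_errors(self, tmp_path):
        mp = write(tmp_path, "mat.tsv", "id\ta\ng1\t1\n")
        pp = write(tmp_path, "ph.tsv", "sample\tx\nz\t1\n")
        with pytest.raises(ValueError, match="shared"):
            dio.read_xena_pair(mp, pp)

    def test_negative_survival_time_errors(self, tmp_path):
        mp = write(tmp_path, "mat.tsv", "id\ta\tb\ng1\t1\t2\n")
        pp = write(tmp_path, "ph.tsv", "sample\tT\tE\na\t-5\t1\nb\t3\t0\n")
        with pytest.raises(ValueError, match="negative"):
            dio.read_xena_pair(mp, pp, survival_pairs={"OS": ("T", "E")})


GEO_FIXTURE = """!Series_title\t"synthetic test series"
!Sample_geo_accession\t"GSM1"\t"GSM2"
!Sample_characteristics_ch1\t"stage: II"\t"stage: I"
!Sample_characteristics_ch1\t"age: 61"\t"age: 45"
!series_matrix_table_begin
"ID_REF"\t"GSM1"\t"GSM2"
"p1"\t1.5\t2.5
"p2"\t3.5\t4.5
!series_matrix_table_end
"""


class TestGeoSeriesMatrix:
    def test_fixture_parse(self, tmp_path):
        p = write(tmp_path, "geo.txt", GEO_FIXTURE)
        m, clin = dio.read_geo_series_matrix(p)
        assert m.values.shape == (2, 2)
        assert m.feature_ids == ["p1", "p2"]
        assert clin.kind("stage") == "categorical"
        assert clin.kind("age") == "numeric"
        assert clin.get("age")["GSM1"] == 61.0

    def test_no_characteristics(self, tmp_path):
        lines = [ln for ln in GEO_FIXTURE.splitlines(keepends=True)
                 if not ln.startswith("!Sample_characteristics")]
        p = write(tmp_path, "geo.txt", "".join(lines))
        m, clin = dio.read_geo_series_matrix(p)
        assert m.values.shape == (2, 2)
        assert clin.label_names == []

    def test_missing_markers_error(self, tmp_path):
        p = write(tmp_path, "geo.txt", GEO_FIXTURE.replace("!series_matrix_table_begin\n", ""))
        with pytest.raises(ValueError, match="markers"):
            dio.read_geo_series_matrix(p)


class TestPartitionFile:
    def test_first_appearance_coding(self, tmp_path):
        p = write(tmp_path, "p.tsv", "s1\tA\ns2\tB\ns3\tA\n")
        part = dio.read_partition(p)
        assert part.k == 2
        assert part.assignments == {"s1": 1, "s2": 2, "s3": 1}

    def test_single_group(self, tmp_path):
        p = write(tmp_path, "p.tsv", "s1\tX\ns2\tX\n")
        assert dio.read_partition(p).k == 1

    def test_conflicting_duplicate_errors(self, tmp_path):
        p = write(tmp_path, "p.tsv", "s1\tA\ns1\tB\n")
        with pytest.raises(ValueError, match="conflicting"):
            dio.read_partition(p)

    def test_empty_errors(self, tmp_path):
        p = write(tmp_path, "p.tsv", "")
        with pytest.raises(ValueError, match="empty"):
            dio.read_partition(p)


class TestGeneSets:
    def test_gmt_roundtrip(self, tmp_path):
        p = write(tmp_path, "s.gmt",
                  "setA\tdescA\tg1\tg2\tg2\nsetB\t\tg3\n")
        sets = dio.read_gene_sets(p)
        assert sets.names == ["setA", "setB"]
        assert sets.members("setA") == ["g1", "g2"]  # dedup within a line
        assert sets.members("setB") == ["g3"]        # empty description ok

    def test_errors(self, tmp_path):
        with pytest.raises(ValueError, match="3 fields"):
            dio.read_gene_sets(write(tmp_path, "a.gmt", "justname\tdesc\n"))
        with pytest.raises(ValueError, match="duplicate"):
            dio.read_gene_sets(write(tmp_path, "b.gmt", "s\td\tg1\ns\td\tg2\n"))


def make_collection() -> DatasetCollection:
    samples = ["a", "b", "c"]
    m1 = OmicMatrix("expr", ["g1", "g2"], samples,
                    np.array([[1.0, np.nan, 3.0], [0.25, 0.5, 0.75]]),
                    value_scale="log2")
    m2 = OmicMatrix("meth", ["g1"], samples, np.array([[0.1, 0.9, 0.5]]))
    ct = ClinicalTable(samples)
    ct.add_label("stage", pd.Series(["I", "II", "I"], index=samples),
                 LabelSpec("stage", "categorical"))
    ct.add_label("grade", pd.Series(["lo", "hi", "lo"], index=samples),
                 LabelSpec("grade", "ordinal", levels=["lo", "hi"]))
    ct.add_label("age", pd.Series([50.5, 61.0, np.nan], index=samples),
                 LabelSpec("age", "numeric"))
    ct.add_label("OS", pd.DataFrame({"time": [10.0, 20.0, 30.0],
                                     "event": [1.0, 0.0, 1.0]}, index=samples),
                 LabelSpec("OS", "survival"))
    return DatasetCollection(omics={"expr": m1, "meth": m2}, clinical=ct)


class TestCollectionRoundTrip:
    def test_roundtrip_preserves_everything(self, tmp_path):
        coll = make_collection()
        dio.write_collection(coll, tmp_path / "coll")
        back = dio.read_collection(tmp_path / "coll")
        assert set(back.omics) == {"expr", "meth"}
        for name in coll.omics:
            a, b = coll.omics[name], back.omics[name]
            assert a.feature_ids == b.feature_ids
            assert a.sample_ids == b.sample_ids
            np.testing.assert_allclose(a.values, b.values, atol=1e-9)
            np.testing.assert_array_equal(a.mask, b.mask)
            assert a.value_scale == b.value_scale
        for name in coll.clinical.label_names:
            assert back.clinical.kind(name) == coll.clinical.kind(name)
        assert back.clinical.specs["grade"].levels == ["lo", "hi"]
        t0, _ = coll.clinical.get_survival("OS")
        t1, _ = back.clinical.get_survival("OS")
        np.testing.assert_allclose(t1.to_numpy(), t0.to_numpy())

    def test_unknown_label_type_errors(self, tmp_path):
        coll = make_collection()
        dio.write_collection(coll, tmp_path / "c")
        manifest = json.loads((tmp_path / "c" / "manifest.json").read_text())
        manifest["clinical"]["labels"][0]["type"] = "bogus"
        (tmp_path / "c" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="unknown label type"):
            dio.read_collection(tmp_path / "c")

    def test_missing_file_errors(self, tmp_path):
        coll = make_collection()
        dio.write_collection(coll, tmp_path / "c")
        (tmp_path / "c" / "omic_meth.tsv").unlink()
        with pytest.raises(FileNotFoundError):
            dio.read_collection(tmp_path / "c")

    def test_single_omic_valid(self, tmp_path):
        coll = make_collection()
        single = DatasetCollection(omics={"expr": coll.omics["expr"]},
                                   clinical=coll.clinical)
        dio.write_collection(single, tmp_path / "one")
        assert list(dio.read_collection(tmp_path / "one").omics) == ["expr"]


class TestTypesAndInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            OmicMatrix("x", ["g1", "g1"], ["s1"], np.zeros((2, 1)))
        with pytest.raises(ValueError, match="duplicate"):
            ClinicalTable(["a", "a"])

    def test_partition_requires_nonempty_clusters(self):
        with pytest.raises(ValueError, match="non-empty"):
            Partition(axis="samples", assignments={"a": 1, "b": 3}, k=3)

    def test_autotype_rules(self):
        df = pd.DataFrame({
            "num": ["1.5", "2.5", "3.5"],
            "cat": ["x", "y", "x"],
            "os_time": [5, 6, 7],
            "os_event": [1, 0, 1],
        }, index=["a", "b", "c"])
        ct = dio.autotype_labels(df)
        assert ct.kind("num") == "numeric"
        assert ct.kind("cat") == "categorical"
        assert ct.kind("os") == "survival"

    def test_ordinal_requires_levels(self):
        with pytest.raises(ValueError, match="levels"):
            LabelSpec("g", "ordinal")
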