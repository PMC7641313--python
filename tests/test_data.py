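import numpy as np
import pandas as pd
import pytest

from naimpute import (
    completeness_summary,
    filter_by_cv,
    filter_by_na,
    read_annotation,
    read_design,
    read_groups,
    read_matrix,
    write_matrix,
    write_table,
)
from naimpute.data import SampleDesign

from conftest import make_matrix


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadMatrix:
    def test_empty_cell_becomes_missing(self, tmp_path):
        p = _write(tmp_path, "m.csv", "feature_id,s1,s2\nf1,1.5,2.5\nf2,,3.5\nf3,4.5,5.5\n")
        m = read_matrix(p, scale="log2")
        assert m.n_missing == 1
        assert np.isnan(m.data.loc["f2", "s1"])

    def test_raw_zero_is_missing_and_log2_applied(self, tmp_path):
        p = _write(tmp_path, "m.csv", "feature_id,s1,s2\nf1,8,0\nf2,2,4\n")
        m = read_matrix(p, scale="raw")
        assert m.scale == "log2"
        assert np.isnan(m.data.loc["f1", "s2"])
        assert m.data.loc["f1", "s1"] == pytest.approx(3.0)  # log2(8)

    def test_na_tokens(self, tmp_path):
        p = _write(tmp_path, "m.tsv", "feature_id\ts1\ts2\nf1\tNA\t2\nf2\tNaN\t3\n")
        assert read_matrix(p, scale="log2").n_missing == 2

    def test_duplicate_feature_id_raises(self, tmp_path):
        p = _write(tmp_path, "m.csv", "feature_id,s1,s2\nf1,1,2\nf1,3,4\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_matrix(p)

    def test_single_sample_raises(self, tmp_path):
        p = _write(tmp_path, "m.csv", "feature_id,s1\nf1,1\n")
        with pytest.raises(ValueError, match="2 sample"):
            read_matrix(p)

    def test_non_numeric_cell_raises(self, tmp_path):
        p = _write(tmp_path, "m.csv", "feature_id,s1,s2\nf1,abc,2\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_matrix(p)

    def test_roundtrip_identity(self, tmp_path):
        m = make_matrix([[1.0, np.nan, 3.0], [4.0, 5.0, np.nan], [1.5, 2.5, 3.5],
                         [7.0, 8.0, 9.0], [0.5, np.nan, 1.5]])
        out = tmp_path / "round.tsv"
        write_matrix(m, out)
        m2 = read_matrix(out, scale="log2")
        pd.testing.assert_frame_equal(m.data, m2.data, check_names=False)
        # idempotence: read(write(read(f))) == read(f)
        write_matrix(m2, tmp_path / "round2.tsv")
        m3 = read_matrix(tmp_path / "round2.tsv", scale="log2")
        pd.testing.assert_frame_equal(m2.data, m3.data)


class TestCompanionTables:
    def test_annotation_two_charges_share_sequence(self, tmp_path):
        p = _write(
            tmp_path, "a.tsv",
            "feature_id\tpeptide_sequence\tcharge\tprotein_id\n"
            "f1\tPEPTIDE\t2\tP1\nf2\tPEPTIDE\t3\tP1\n",
        )
        ann = read_annotation(p)
        assert (ann.table["peptide_sequence"] == "PEPTIDE").all()
        assert set(ann.table["charge"]) == {2, 3}

    def test_unknown_feature_rows_skipped_with_warning(self, tmp_path):
        m = make_matrix([[1, 2], [3, 4]], features=["f1", "f2"])
        p = _write(
            tmp_path, "a.tsv",
            "feature_id\tpeptide_sequence\tcharge\tprotein_id\n"
            "f1\tAAA\t2\tP1\nzzz\tBBB\t2\tP2\n",
        )
        with pytest.warns(UserWarning, match="unknown features"):
            ann = read_annotation(p, m)
        assert list(ann.table["feature_id"]) == ["f1"]

    def test_groups_roundtrip(self, tmp_path, small_dataset):
        out = tmp_path / "g.tsv"
        write_table(small_dataset.complexes, out)
        cat = read_groups(out, "complex")
        assert cat.groups == small_dataset.complexes.groups

    def test_design_roundtrip_and_validation(self, tmp_path, small_dataset):
        out = tmp_path / "d.tsv"
        write_table(small_dataset.design, out)
        d = read_design(out)
        assert d.group_labels == ["A", "B"]
        d.validate_against(small_dataset.matrix)
        with pytest.raises(ValueError, match="not in matrix"):
            SampleDesign(pd.DataFrame({"sample_id": ["nope", "x"], "group_label": ["A", "B"]})).validate_against(
                small_dataset.matrix
            )


class TestCompleteness:
    def test_no_missing(self):
        m = make_matrix(np.ones((4, 3)))
        s = completeness_summary(m)
        assert s["fraction_features_with_any_na"] == 0.0
        assert s["n_missing_cells"] == 0

    def test_counts_on_constructed_grid(self):
        X = np.arange(100, dtype=float).reshape(10, 10) + 1
        for i in range(5):
            X[i, i * 2] = np.nan  # 5 cells in 5 distinct features
        s = completeness_summary(make_matrix(X))
        assert s["n_missing_cells"] == 5
        assert s["fraction_features_with_any_na"] == 0.5
        assert sum(s["per_sample_counts"].values()) == s["n_missing_cells"]

    def test_quarter_fraction(self):
        X = np.ones((4, 4))
        X[0, 0] = X[0, 1] = np.nan
        s = completeness_summary(make_matrix(X))
        assert s["fraction_features_with_any_na"] == 0.25


class TestFilterByNA:
    def test_threshold_removes_heavy_feature(self):
        X = np.ones((2, 10))
        X[0, :3] = np.nan  # 30% missing
        m = filter_by_na(make_matrix(X), 0.2)
        assert m.feature_ids == ["f1"]

    def test_threshold_one_is_identity(self):
        X = np.ones((5, 4))
        X[2, :3] = np.nan
        m = make_matrix(X)
        assert filter_by_na(m, 1.0).feature_ids == m.feature_ids

    def test_threshold_zero_keeps_complete_only(self):
        X = np.ones((3, 4))
        X[1, 0] = np.nan
        assert filter_by_na(make_matrix(X), 0.0).feature_ids == ["f0", "f2"]

    def test_against_brute_force(self):
        rng = np.random.default_rng(3)
        X = rng.normal(20, 1, (100, 10))
        X[rng.random((100, 10)) < 0.3] = np.nan
        X[np.isnan(X).all(axis=1)] = 1.0  # no all-missing rows
        m = make_matrix(X)
        kept = filter_by_na(m, 0.5).feature_ids
        expected = [f for f, row in zip(m.feature_ids, X) if np.isnan(row).sum() / 10 <= 0.5]
        assert kept == expected

    def test_all_removed_raises(self):
        X = np.full((3, 4), np.nan)
        X[:, 0] = 1.0
        with pytest.raises(ValueError, match="exceed"):
            filter_by_na(make_matrix(X), 0.1)


class TestFilterByCV:
    def test_constant_feature_retained(self):
        m = make_matrix(np.log2([[10, 10, 10], [10, 10, 10]]))
        assert filter_by_cv(m, 1.0).n_features == 2

    def test_known_cv_removed(self):
        # raw [5, 15]: CV = 100 * 7.0711 / 10 ~ 70.7% > 50%
        m = make_matrix(np.log2([[5, 15], [10, 10]]))
        kept = filter_by_cv(m, 50.0)
        assert kept.feature_ids == ["f1"]

    def test_undefined_cv_retained_with_warning(self):
        X = np.log2([[10.0, np.nan, np.nan], [10, 11, 12]])
        with pytest.warns(UserWarning, match="CV undefined"):
            kept = filter_by_cv(make_matrix(X), 5.0)
        assert "f0" in kept.feature_ids

    def test_per_group_requires_exceedance_everywhere(self):
        # feature varies wildly in group A only -> survives the grouped filter
        X = np.log2([[2, 40, 10, 10], [10, 10, 10, 10]])
        design = SampleDesign(
            pd.DataFrame({"sample_id": ["s0", "s1", "s2", "s3"], "group_label": ["A", "A", "B", "B"]})
        )
        m = make_matrix(X)
        assert filter_by_cv(m, 50.0, design).n_features == 2
        assert filter_by_cv(m, 50.0).n_features == 1
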