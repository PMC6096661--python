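"""Container, half-vectorization and long-format I/O behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from masem.dataset import (
    DatasetError,
    MasemDataset,
    StudyRecord,
    dataset_from_matrices,
    read_dataset,
    unvech,
    vech,
    vech_indices,
    write_dataset,
)


class TestVech:
    def test_three_by_three_column_major(self):
        m = np.array([[1.0, 0.1, 0.2], [0.1, 1.0, 0.3], [0.2, 0.3, 1.0]])
        assert np.array_equal(vech(m), [0.1, 0.2, 0.3])

    def test_identity_gives_zero_vector(self):
        assert np.array_equal(vech(np.eye(5)), np.zeros(10))

    def test_fourteen_variables_give_91_elements(self):
        assert len(vech_indices(14)) == 91

    def test_non_square_rejected(self):
        with pytest.raises(DatasetError):
            vech(np.zeros((2, 3)))

    @given(st.integers(2, 8), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_roundtrip_identity_on_unit_diagonal_symmetric(self, p, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(-1, 1, size=p * (p - 1) // 2)
        m = unvech(v)
        assert np.allclose(vech(m), v)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)


class TestValidation:
    def test_out_of_range_correlation_names_study_and_pair(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text(
            "study_id,n,group,var_row,var_col,r\n"
            "a,100,,v1,v2,0.3\n"
            "b,100,,v1,v2,1.2\n"
        )
        with pytest.raises(DatasetError, match=r"study b.*v1.*v2"):
            read_dataset(str(f), ["v1", "v2"])

    def test_duplicate_pair_is_error(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text(
            "study_id,n,group,var_row,var_col,r\n"
            "a,100,,v1,v2,0.3\n"
            "a,100,,v2,v1,0.3\n"
        )
        with pytest.raises(DatasetError, match="duplicate"):
            read_dataset(str(f), ["v1", "v2"])

    def test_inconsistent_n_within_study(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text(
            "study_id,n,group,var_row,var_col,r\n"
            "a,100,,v1,v2,0.3\n"
            "a,200,,v1,v3,0.2\n"
        )
        with pytest.raises(DatasetError, match="inconsistent"):
            read_dataset(str(f), ["v1", "v2", "v3"])

    def test_undeclared_variable_names_line(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("study_id,n,group,var_row,var_col,r\na,100,,v1,vX,0.3\n")
        with pytest.raises(DatasetError, match="line 2"):
            read_dataset(str(f), ["v1", "v2"])

    def test_wrong_header_rejected(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("id,n,group,var_row,var_col,r\na,100,,v1,v2,0.3\n")
        with pytest.raises(DatasetError, match="header"):
            read_dataset(str(f), ["v1", "v2"])

    def test_small_n_rejected(self):
        with pytest.raises(DatasetError, match="n must be"):
            StudyRecord("a", 3, np.eye(2))


class TestRoundTrip:
    def test_complete_two_study_file(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text(
            "study_id,n,group,var_row,var_col,r\n"
            "a,100,pat,v2,v1,0.30\n"
            "a,100,pat,v3,v1,0.20\n"
            "a,100,pat,v3,v2,0.40\n"
            "b,150,non,v2,v1,0.25\n"
            "b,150,non,v3,v1,0.15\n"
            "b,150,non,v3,v2,0.35\n"
        )
        data = read_dataset(str(f), ["v1", "v2", "v3"])
        assert data.k == 2 and data.p == 3
        assert data.group_levels == ["pat", "non"]
        assert not np.isnan([s.corr for s in data.studies]).any()
        assert data.studies[0].corr[1, 0] == 0.30

    def test_missing_pair_recorded_as_missing_not_zero(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text(
            "study_id,n,group,var_row,var_col,r\n"
            "a,100,,v2,v1,0.3\n"
            "a,100,,v3,v2,0.4\n"
            "b,100,,v2,v1,0.3\n"
            "b,100,,v3,v1,0.2\n"
            "b,100,,v3,v2,0.4\n"
        )
        data = read_dataset(str(f), ["v1", "v2", "v3"])
        a = next(s for s in data.studies if s.study_id == "a")
        b = next(s for s in data.studies if s.study_id == "b")
        assert np.isnan(a.corr[2, 0]) and np.isnan(a.corr[0, 2])
        assert not np.isnan(b.corr).any()

    def test_write_then_read_reproduces_observed_tuples(self, tmp_path, rng):
        corr_a = unvech(np.array([0.3, np.nan, 0.4]))
        corr_b = unvech(rng.uniform(-0.5, 0.5, 3))
        data = dataset_from_matrices(
            ["v1", "v2", "v3"],
            {"a": corr_a, "b": corr_b},
            {"a": 80, "b": 120},
            groups={"a": "g1", "b": "g2"},
        )
        path = tmp_path / "out.csv"
        write_dataset(data, str(path))
        back = read_dataset(str(path), ["v1", "v2", "v3"])
        assert back.k == 2
        for orig, rt in zip(data.studies, back.studies):
            assert orig.study_id == rt.study_id
            assert orig.n == rt.n and orig.group == rt.group
            both = ~np.isnan(orig.corr)
            assert np.array_equal(both, ~np.isnan(rt.corr))
            assert np.allclose(orig.corr[both], rt.corr[both])

    def test_naive_pooled_errors_when_pair_never_observed(self):
        corr = unvech(np.array([0.3, np.nan, 0.4]))
        data = dataset_from_matrices(["v1", "v2", "v3"], {"a": corr}, {"a": 50})
        with pytest.raises(DatasetError, match="no study"):
            data.naive_pooled()
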