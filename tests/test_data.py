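import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stopforest as sf
from stopforest.data import ConfigurationError, DataError, percentile


def _write(tmp_path, text, name="d.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadCsv:
    def test_identity_load(self, tmp_path):
        p = _write(tmp_path, "a,b,y\n1,2,3\n4,5,6\n7,8,9\n")
        ds = sf.load_csv(p, "y")
        assert ds.n == 3 and ds.p == 2
        assert ds.feature_names == ("a", "b")
        np.testing.assert_array_equal(ds.outcome, [3, 6, 9])
        np.testing.assert_array_equal(ds.weights, 1.0)

    def test_incomplete_rows_dropped_and_logged(self, tmp_path, caplog):
        p = _write(tmp_path, "a,y\n1,3\n,4\n2,5\n3,6\n")
        with caplog.at_level(logging.INFO, logger="stopforest.data"):
            ds = sf.load_csv(p, "y")
        assert ds.n == 3
        assert any("1 row" in r.message for r in caplog.records)

    def test_non_numeric_cell_counts_as_missing(self, tmp_path):
        p = _write(tmp_path, "a,y\n1,3\nfoo,4\n2,5\n")
        assert sf.load_csv(p, "y").n == 2

    def test_missing_outcome_column(self, tmp_path):
        p = _write(tmp_path, "a,b\n1,2\n")
        with pytest.raises(ConfigurationError):
            sf.load_csv(p, "y")

    def test_zero_weight_rejected(self, tmp_path):
        p = _write(tmp_path, "a,y,w\n1,2,1\n3,4,0\n")
        with pytest.raises(DataError):
            sf.load_csv(p, "y", weight_column="w")

    def test_all_rows_missing(self, tmp_path):
        p = _write(tmp_path, "a,y\n,1\n,2\n")
        with pytest.raises(DataError):
            sf.load_csv(p, "y")

    def test_roundtrip(self, tmp_path, friedman_noisy):
        p = tmp_path / "rt.csv"
        sf.write_csv(friedman_noisy, p)
        back = sf.load_csv(p, "y")
        np.testing.assert_allclose(back.features, friedman_noisy.features)
        np.testing.assert_allclose(back.outcome, friedman_noisy.outcome)
        assert back.feature_names == friedman_noisy.feature_names


class TestSummarise:
    def test_constant_vector(self):
        s = sf.summarise([1, 1, 1, 1], centiles=(25,))
        assert s.total_variance == 0 and s.total_range == 0 and s.icr[25.0] == 0

    def test_range(self):
        assert sf.summarise([2, 7]).total_range == 5

    def test_icr_linear_interpolation(self):
        # 0..10: the 25th/75th percentiles interpolate to 2.5 and 7.5
        s = sf.summarise(np.arange(11.0), centiles=(25,))
        assert s.icr[25.0] == pytest.approx(5.0)
        assert percentile(np.arange(11.0), 25) == pytest.approx(2.5)

    def test_population_variance_divisor(self):
        assert sf.summarise([0.0, 2.0]).total_variance == pytest.approx(1.0)

    def test_empty_vector(self):
        with pytest.raises(DataError):
            sf.summarise([])

    def test_bad_centile(self):
        with pytest.raises(ConfigurationError):
            sf.summarise([1, 2, 3], centiles=(60,))

    @given(
        y=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
        shift=st.floats(-100, 100),
        scale=st.floats(0.1, 10),
    )
    def test_shift_and_scale_laws(self, y, shift, scale):
        y = np.asarray(y)
        base = sf.summarise(y, centiles=(10, 25))
        shifted = sf.summarise(y + shift, centiles=(10, 25))
        scaled = sf.summarise(y * scale, centiles=(10, 25))
        assert shifted.total_variance == pytest.approx(base.total_variance, abs=1e-6)
        assert shifted.total_range == pytest.approx(base.total_range, abs=1e-9)
        assert shifted.icr[25.0] == pytest.approx(base.icr[25.0], abs=1e-9)
        assert scaled.total_variance == pytest.approx(base.total_variance * scale**2, rel=1e-9, abs=1e-9)
        assert scaled.total_range == pytest.approx(base.total_range * scale, rel=1e-9, abs=1e-9)
        assert scaled.icr[10.0] == pytest.approx(base.icr[10.0] * scale, rel=1e-9, abs=1e-9)

    @given(y=st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    def test_icr_nonincreasing_and_bounded_by_range(self, y):
        s = sf.summarise(np.asarray(y), centiles=(5, 10, 25, 40))
        vals = [s.icr[x] for x in (5.0, 10.0, 25.0, 40.0)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(v <= s.total_range + 1e-12 for v in vals)


class TestSplitAndFolds:
    def test_split_identity(self, friedman_noisy):
        a, b = sf.train_test_split(friedman_noisy, friedman_noisy)
        assert a is friedman_noisy and b is friedman_noisy

    def test_split_schema_mismatch(self, friedman_noisy, piecewise_clean):
        with pytest.raises(ConfigurationError):
            sf.train_test_split(friedman_noisy, piecewise_clean)

    def test_kfold_singletons(self):
        folds = sf.kfold_indices(10, 10, seed=0)
        assert sorted(len(f) for f in folds) == [1] * 10

    def test_kfold_167_by_10(self):
        sizes = sorted(len(f) for f in sf.kfold_indices(167, 10, seed=1))
        assert sizes == [16] * 3 + [17] * 7

    def test_kfold_k_exceeds_n(self):
        with pytest.raises(ConfigurationError):
            sf.kfold_indices(5, 6, seed=0)

    @given(n=st.integers(4, 200), k=st.integers(2, 10), seed=st.integers(0, 100))
    def test_kfold_partition_properties(self, n, k, seed):
        if k > n:
            k = n
        folds = sf.kfold_indices(n, k, seed)
        allidx = np.concatenate(folds)
        assert len(allidx) == n and len(np.unique(allidx)) == n
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        again = sf.kfold_indices(n, k, seed)
        for f, g in zip(folds, again):
            np.testing.assert_array_equal(f, g)


class TestDatasetInvariants:
    def test_rejects_nan(self):
        with pytest.raises(DataError):
            sf.Dataset(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]))

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(DataError):
            sf.Dataset(np.ones((2, 1)), np.ones(2), np.array([1.0, -1.0]))

    def test_subset_keeps_weights(self, friedman_noisy):
        ds = sf.Dataset(
            friedman_noisy.features,
            friedman_noisy.outcome,
            np.linspace(1, 2, friedman_noisy.n),
        )
        sub = ds.subset(np.array([3, 5]))
        np.testing.assert_allclose(sub.weights, ds.weights[[3, 5]])
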