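import numpy as np
import pandas as pd
import pytest

import stopforest as sf
from stopforest.data import ConfigurationError, DataError
from stopforest.evaluation import derive_seed


def _params(**kw):
    kw.setdefault("ntree", 15)
    kw.setdefault("stopping", sf.StoppingConfig(min_parent_size=5))
    kw.setdefault("seed", 3)
    return sf.ForestParams(**kw)


class TestMspe:
    def test_unweighted(self):
        assert sf.mspe([1, 2], [1, 4]) == pytest.approx(2.0)

    def test_weighted(self):
        assert sf.mspe([1, 2], [1, 4], weights=[1, 3]) == pytest.approx(3.0)

    def test_perfect_prediction(self):
        assert sf.mspe([1.5, 2.5], [1.5, 2.5]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            sf.mspe([1, 2], [1])

    def test_weight_rescaling_invariance(self):
        y, yhat = np.array([1.0, 2, 3]), np.array([2.0, 2, 1])
        w = np.array([1.0, 2, 5])
        assert sf.mspe(y, yhat, w) == pytest.approx(sf.mspe(y, yhat, 17.3 * w))
        assert sf.mspe(y, yhat, np.ones(3)) == pytest.approx(sf.mspe(y, yhat))


class TestHoldout:
    def test_memorization_near_zero(self, piecewise_clean):
        p = _params(ntree=50, stopping=sf.StoppingConfig(min_leaf_size=1))
        res = sf.holdout_mspe(piecewise_clean, piecewise_clean, p)
        assert res.mspe < 0.5 * np.var(piecewise_clean.outcome)

    def test_root_only_closed_form(self, piecewise_noisy):
        p = _params(ntree=10, stopping=sf.StoppingConfig(theta_range=1.0))
        res = sf.holdout_mspe(piecewise_noisy, piecewise_noisy, p)
        forest = sf.fit(piecewise_noisy, p)
        const = sf.predict(forest, piecewise_noisy.features[:1])[0]
        expected = np.mean((piecewise_noisy.outcome - const) ** 2)
        assert res.mspe == pytest.approx(expected, rel=1e-12)

    def test_deterministic(self, piecewise_noisy):
        p = _params(ntree=8)
        a = sf.holdout_mspe(piecewise_noisy, piecewise_noisy, p)
        b = sf.holdout_mspe(piecewise_noisy, piecewise_noisy, p)
        assert a.mspe == b.mspe

    def test_uses_test_weights(self, piecewise_noisy):
        heavy = sf.Dataset(
            piecewise_noisy.features,
            piecewise_noisy.outcome,
            np.linspace(0.5, 4.0, piecewise_noisy.n),
            piecewise_noisy.feature_names,
            piecewise_noisy.outcome_name,
        )
        p = _params(ntree=8)
        weighted = sf.holdout_mspe(piecewise_noisy, heavy, p)
        unweighted = sf.holdout_mspe(piecewise_noisy, piecewise_noisy, p)
        assert weighted.mspe != pytest.approx(unweighted.mspe, rel=1e-6)


class TestCrossValidation:
    def test_constant_outcome_zero_error(self):
        ds = sf.Dataset(np.arange(20.0)[:, None], np.full(20, 5.0))
        res = sf.cv_mspe(ds, _params(ntree=3), k=5, cv_seed=0)
        assert res.mspe == 0.0

    def test_leave_one_out_matches_direct_loop(self):
        ds = sf.gen_piecewise(10, (0.5,), (0.0, 8.0), 0.5, seed=4)
        p = _params(ntree=5)
        res = sf.cv_mspe(ds, p, k=10, cv_seed=2)
        # independent re-implementation: explicit leave-one-out loop
        folds = sf.kfold_indices(10, 10, 2)
        sse = wt = 0.0
        for fi, fold in enumerate(folds):
            rest = np.setdiff1d(np.arange(10), fold)
            forest = sf.fit(
                ds.subset(rest),
                sf.ForestParams(
                    ntree=5, stopping=p.stopping, maxnodes=p.maxnodes,
                    seed=derive_seed(p.seed, fi),
                ),
            )
            err = ds.outcome[fold] - sf.predict(forest, ds.features[fold])
            sse += float(np.sum(ds.weights[fold] * err**2))
            wt += float(np.sum(ds.weights[fold]))
        assert res.mspe == pytest.approx(sse / wt, rel=1e-12)

    def test_pooling_not_mean_of_fold_means(self, piecewise_noisy):
        # 200 rows over 7 folds: unequal folds make the two definitions differ
        res = sf.cv_mspe(piecewise_noisy, _params(ntree=5), k=7, cv_seed=1)
        pooled = sum(res.per_fold_sse) / sum(res.per_fold_weight)
        mean_of_folds = np.mean(
            [s / w for s, w in zip(res.per_fold_sse, res.per_fold_weight)]
        )
        assert res.mspe == pytest.approx(pooled, rel=1e-15)
        assert res.mspe != pytest.approx(mean_of_folds, rel=1e-9)

    def test_deterministic_given_seeds(self, piecewise_noisy):
        a = sf.cv_mspe(piecewise_noisy, _params(ntree=4), k=5, cv_seed=9)
        b = sf.cv_mspe(piecewise_noisy, _params(ntree=4), k=5, cv_seed=9)
        assert a.mspe == b.mspe


class TestTune:
    def test_single_point_grid(self, piecewise_noisy):
        sw = sf.tune(piecewise_noisy, "leaf", [5], _params(ntree=5), k=5, cv_seed=1)
        assert sw.min_mspe == sw.mspes[0] and sw.best_threshold == 5

    def test_degenerate_variance_sweep_is_constant_predictor(self, piecewise_noisy):
        sw = sf.tune(piecewise_noisy, "range", [1.0], _params(ntree=5), k=5, cv_seed=1)
        # every fold's forest predicts a constant; error near outcome variance
        assert sw.min_mspe == pytest.approx(np.var(piecewise_noisy.outcome), rel=0.2)

    def test_min_is_min(self, piecewise_noisy):
        sw = sf.tune(
            piecewise_noisy, "variance", [0.001, 0.05, 0.5], _params(ntree=5), k=5, cv_seed=1
        )
        assert sw.min_mspe == min(sw.mspes)
        assert all(sw.min_mspe <= m for m in sw.mspes)

    def test_empty_grid(self, piecewise_noisy):
        with pytest.raises(ConfigurationError):
            sf.tune(piecewise_noisy, "leaf", [], _params())

    def test_unknown_rule(self, piecewise_noisy):
        with pytest.raises(ConfigurationError):
            sf.tune(piecewise_noisy, "gini", [1], _params())

    def test_holdout_mode(self, piecewise_noisy, piecewise_clean):
        test = sf.gen_piecewise(80, (0.3, 0.6), (0.0, 5.0, 10.0), 1.0, seed=5)
        sw = sf.tune(
            piecewise_noisy, "leaf", [1, 10], _params(ntree=5), test=test
        )
        assert len(sw.mspes) == 2 and all(m > 0 for m in sw.mspes)


class TestRelativeExcess:
    def test_arithmetic(self):
        table = pd.DataFrame({"d1": [0.2729, 0.2235], "d2": [2.0, 4.0]}, index=["a", "b"])
        ex = sf.relative_excess(table)
        assert ex.loc["a", "d1"] == pytest.approx(22.103, abs=0.01)
        assert ex.loc["b", "d1"] == 0.0
        assert ex.loc["b", "d2"] == pytest.approx(100.0)

    def test_argmin_row_is_zero(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(1, 2, size=(4, 6))
        ex = sf.relative_excess(m)
        assert np.all(ex.min(axis=0) == 0.0)
        assert np.all(ex >= 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            sf.relative_excess(np.array([[1.0, -2.0], [3.0, 4.0]]))
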