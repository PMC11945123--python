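"""Metrics, median-threshold AUC, CV harness, conversions and Welch tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqbind import evaluation as ev


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = ev.regression_metrics(y, y)
        assert (m.pcc, m.r2, m.mse, m.mae) == (1.0, 1.0, 0.0, 0.0)

    def test_anti_correlated(self):
        m = ev.regression_metrics([1, 2, 3], [3, 2, 1])
        assert m.pcc == pytest.approx(-1.0)
        assert m.mse == pytest.approx(8 / 3)
        assert m.mae == pytest.approx(4 / 3)

    def test_constant_shift(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = ev.regression_metrics(y, y + 1)
        assert m.pcc == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)
        sstot = ((y - y.mean()) ** 2).sum()
        assert m.r2 == pytest.approx(1 - len(y) / sstot)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ev.regression_metrics([1, 1, 1], [1, 2, 3])


class TestMedianAUC:
    def test_perfect_anti_constant(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert ev.median_auc(y, y) == 1.0
        assert ev.median_auc(y, -y) == 0.0
        assert ev.median_auc(y, np.zeros(6)) == 0.5

    def test_all_equal_labels_rejected(self):
        with pytest.raises(ValueError, match="label class"):
            ev.median_auc([2.0, 2.0, 2.0, 2.0], [1, 2, 3, 4])

    def test_random_scores_near_half(self):
        """Uninformative scores give AUC 0.5 +- 0.02 at n=1e4."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.uniform(2, 12, size=10_000)
            scores = rng.uniform(size=10_000)
            assert ev.median_auc(y, scores) == pytest.approx(0.5, abs=0.02)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=40, unique=True),
           st.floats(0.1, 5.0))
    def test_invariant_under_monotone_transform(self, y, scale):
        y = np.array(y)
        rng = np.random.default_rng(0)
        scores = rng.normal(size=len(y))
        a = ev.median_auc(y, scores)
        b = ev.median_auc(y, np.exp(scale * scores))
        assert a == pytest.approx(b, abs=1e-12)


class _MeanModel:
    """Degenerate learner used to exercise the CV harness deterministically."""

    def fit(self, X, y):
        self.coef_ = np.linalg.lstsq(np.c_[X, np.ones(len(X))], y, rcond=None)[0]
        return self

    def predict(self, X):
        return np.c_[X, np.ones(len(X))] @ self.coef_


class TestKFoldCV:
    def make(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = X @ [1.0, -0.5, 0.2] + 5 + rng.normal(0, 0.1, n)
        return X, y

    def test_partition_contract(self):
        X, y = self.make()
        folds, _ = ev.kfold_cv(X, y, lambda s: _MeanModel(), k=10, seed=1)
        all_test = sorted(i for f in folds for i in f.test_ids)
        assert all_test == list(range(100))
        for f in folds:
            assert not set(f.train_ids) & set(f.test_ids)
            assert len(f.test_ids) == 10

    def test_average_is_mean_of_folds(self):
        X, y = self.make()
        folds, avg = ev.kfold_cv(X, y, lambda s: _MeanModel(), k=5, seed=2)
        assert avg.pcc == pytest.approx(np.mean([f.metrics.pcc for f in folds]), abs=1e-12)
        assert avg.mse == pytest.approx(np.mean([f.metrics.mse for f in folds]), abs=1e-12)

    def test_equal_fold_mse_matches_pooled(self):
        X, y = self.make(n=100)
        folds, avg = ev.kfold_cv(X, y, lambda s: _MeanModel(), k=10, seed=3)
        pooled = []
        for f in folds:
            model = _MeanModel().fit(X[f.train_ids], y[f.train_ids])
            pooled.extend((model.predict(X[f.test_ids]) - y[f.test_ids]) ** 2)
        assert avg.mse == pytest.approx(np.mean(pooled), abs=1e-12)

    def test_same_seed_same_assignment(self):
        X, y = self.make()
        f1, _ = ev.kfold_cv(X, y, lambda s: _MeanModel(), k=4, seed=7)
        f2, _ = ev.kfold_cv(X, y, lambda s: _MeanModel(), k=4, seed=7)
        assert [f.test_ids for f in f1] == [f.test_ids for f in f2]

    def test_repeats_extend_folds(self):
        X, y = self.make(n=40)
        folds, _ = ev.kfold_cv(X, y, lambda s: _MeanModel(), k=4, seed=0, repeats=2)
        assert len(folds) == 8

    def test_k_larger_than_n_raises(self):
        X, y = self.make(n=5)
        with pytest.raises(ValueError):
            ev.kfold_cv(X, y, lambda s: _MeanModel(), k=10)


class TestConvertAffinity:
    def test_pk6_is_one_micromolar(self):
        assert ev.convert_affinity(6.0, "pK", "uM") == pytest.approx(1.0)
        assert ev.convert_affinity(1.0, "uM", "pK") == pytest.approx(6.0)

    def test_zero_free_energy_is_molar_kd(self):
        assert ev.convert_affinity(0.0, "dG", "M") == pytest.approx(1.0)
        assert ev.convert_affinity(0.0, "dG", "pK") == pytest.approx(0.0)

    def test_pk6_free_energy_closed_form(self):
        dg = ev.convert_affinity(6.0, "pK", "dG")
        expected = ev.GAS_CONSTANT_KCAL * ev.DEFAULT_TEMPERATURE_K * math.log(1e-6)
        assert dg == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pk", [0.0, 3.0, 6.0, 9.0, 12.0])
    def test_round_trips(self, pk):
        m = ev.convert_affinity(pk, "pK", "M")
        um = ev.convert_affinity(m, "M", "uM")
        back = ev.convert_affinity(um, "uM", "pK")
        assert back == pytest.approx(pk, abs=1e-10)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            ev.convert_affinity(-1.0, "nM", "pK")

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            ev.convert_affinity(1.0, "pK", "furlongs")


class TestActiveDecoyAnalysis:
    def test_identical_groups(self):
        g = np.array([5.0, 6.0, 7.0])
        res = ev.active_decoy_analysis(g, g)
        assert res.mean_difference == 0.0
        assert res.welch_t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(0)
        decoys = rng.normal(5.0, 0.1, size=100)
        actives = decoys + 1.0
        res = ev.active_decoy_analysis(actives, decoys)
        assert res.mean_difference == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_welch_t_matches_closed_form(self):
        rng = np.random.default_rng(1)
        a = rng.normal(7, 0.5, size=37)
        d = rng.normal(5, 1.2, size=143)
        res = ev.active_decoy_analysis(a, d)
        expected = (a.mean() - d.mean()) / math.sqrt(
            a.var(ddof=1) / len(a) + d.var(ddof=1) / len(d))
        assert res.welch_t == pytest.approx(expected, abs=1e-10)

    def test_threshold_counts(self):
        res = ev.active_decoy_analysis([7.0, 7.5, 5.0], [4.0, 5.0, 6.0])
        assert res.n_active_above_threshold == 2
        assert res.n_decoy_above_threshold == 1

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ev.active_decoy_analysis([5.0], [4.0, 4.5])
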