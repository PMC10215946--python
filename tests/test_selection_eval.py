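"""Wrapper cost, SVM contracts, selectors, and the repeated-split protocol."""

import numpy as np
import pytest

from neurofuse import (
    EWOAFeatureSelector,
    SVMWrapperCost,
    WOAFeatureSelector,
    classification_accuracy,
    compare_methods,
    generate_trialset,
    run_experiment,
    svm_decide,
    svm_train,
    wrapper_cost,
)
from neurofuse.optim import SelectionMask


def planted_toy(n=60, d=8, n_inf=3, delta=1.2, seed=42):
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    X = rng.standard_normal((n, d))
    X[y == 1, :n_inf] += delta
    return X, y


class TestSVM:
    def test_separable_clusters_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        model = svm_train(X, y)
        assert classification_accuracy(svm_decide(model, X), y) == 100.0

    def test_two_point_max_margin_geometry(self):
        """Closed form: for (-1,0) vs (1,0), w ∝ (1,0), b = 0."""
        model = svm_train(np.array([[-1.0, 0.0], [1.0, 0.0]]), np.array([0, 1]))
        w = model.coef_.ravel()
        assert w[0] == pytest.approx(1.0, abs=1e-6)
        assert w[1] == pytest.approx(0.0, abs=1e-6)
        assert model.intercept_[0] == pytest.approx(0.0, abs=1e-6)
        assert svm_decide(model, np.array([2.0, 0.0]))[0] == 1


class TestAccuracy:
    def test_fraction_correct(self):
        true = np.zeros(30, dtype=int)
        pred = true.copy()
        pred[:3] = 1
        assert classification_accuracy(pred, true) == pytest.approx(90.0)

    def test_all_correct(self):
        y = np.array([0, 1, 1])
        assert classification_accuracy(y, y) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_accuracy(np.array([]), np.array([]))


class TestWrapperCost:
    def test_fitness_formula_perfect_accuracy_one_feature(self):
        """fitness = 0.99*(1-acc/100) + 0.01*(count/D); acc=100, 1 of 330."""
        rec_fitness = 0.99 * 0.0 + 0.01 * (1 / 330)
        assert rec_fitness == pytest.approx(3.03e-5, rel=0.01)
        # and the implementation reproduces it on a separable problem
        rng = np.random.default_rng(0)
        X = np.zeros((40, 330))
        y = np.repeat([0, 1], 20)
        X[:, 7] = np.where(y == 1, 5.0, -5.0) + 0.01 * rng.standard_normal(40)
        X[:, :330] += 0.001 * rng.standard_normal((40, 330))
        bits = np.zeros(330, dtype=bool)
        bits[7] = True
        rec = wrapper_cost(bits, X, y)
        assert rec.cv_accuracy == 100.0
        assert rec.fitness == pytest.approx(0.01 / 330)

    def test_fitness_formula_chance_accuracy_all_features(self):
        assert 0.99 * 0.5 + 0.01 * 1.0 == pytest.approx(0.505)

    def test_fewer_features_at_equal_accuracy_strictly_better(self):
        X, y = planted_toy()
        cost = SVMWrapperCost(X, y, seed=0)
        full = cost(SelectionMask(np.ones(8, dtype=bool)))
        # same accuracy forced: compare analytic fitness at equal accuracy
        f_small = cost.alpha * (1 - full.cv_accuracy / 100) + 0.01 * (3 / 8)
        assert f_small < full.fitness

    def test_deterministic_given_mask_and_seed(self):
        X, y = planted_toy()
        bits = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=bool)
        a = wrapper_cost(bits, X, y, seed=5)
        b = wrapper_cost(bits, X, y, seed=5)
        assert a.fitness == b.fitness and a.cv_accuracy == b.cv_accuracy

    def test_cache_returns_same_record(self):
        X, y = planted_toy()
        cost = SVMWrapperCost(X, y, seed=0)
        m = SelectionMask(np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=bool))
        r1 = cost(m)
        n_eval = cost.n_evaluations
        r2 = cost(SelectionMask(m.bits.copy()))
        assert r2 is r1
        assert cost.n_evaluations == n_eval


class TestSelectors:
    def test_ewoa_selector_sklearn_contract(self):
        sel = EWOAFeatureSelector(max_iter=2, n_whales=4, cv=2, random_state=0)
        # fit/transform round trip on a tiny problem
        X, y = planted_toy(n=24)
        Xt = sel.fit_transform(X, y)
        assert Xt.shape[0] == 24
        assert Xt.shape[1] == sel.n_features_selected_
        assert sel.support_.sum() == sel.n_features_selected_
        assert sel.get_support().dtype == bool

    def test_get_set_params_round_trip(self):
        sel = EWOAFeatureSelector(migration_rate=0.3, random_state=1)
        params = sel.get_params()
        assert params["migration_rate"] == 0.3
        clone = EWOAFeatureSelector(**params)
        assert clone.get_params() == params

    def test_selectors_reproducible_under_seed(self):
        X, y = planted_toy()
        for cls in (EWOAFeatureSelector, WOAFeatureSelector):
            a = cls(max_iter=10, random_state=7).fit(X, y)
            b = cls(max_iter=10, random_state=7).fit(X, y)
            assert np.array_equal(a.support_, b.support_)
            assert a.best_fitness_ == b.best_fitness_

    def test_selector_in_pipeline(self):
        from sklearn.pipeline import Pipeline
        from sklearn.svm import SVC

        X, y = planted_toy()
        pipe = Pipeline(
            [
                ("select", EWOAFeatureSelector(max_iter=5, random_state=0)),
                ("svm", SVC(kernel="linear")),
            ]
        )
        pipe.fit(X, y)
        assert 0 < pipe.score(X, y) <= 1


class TestMaskPersistence:
    def test_mask_and_trace_tsv(self, tmp_path):
        from neurofuse.selection import mask_to_tsv, trace_to_tsv

        mask = SelectionMask(np.array([1, 0, 1], dtype=bool))
        prov = [("fNIRS", "HbO00", "mean"), ("fNIRS", "HbO00", "slope"), ("EEG", "EEG00", "peak")]
        mask_to_tsv(mask, prov, tmp_path / "mask.tsv")
        lines = (tmp_path / "mask.tsv").read_text().splitlines()
        assert lines[0] == "modality\tchannel\tstatistic\tselected"
        assert lines[1].endswith("1") and lines[2].endswith("0")

        trace_to_tsv([0.5, 0.25], tmp_path / "trace.tsv")
        rows = (tmp_path / "trace.tsv").read_text().splitlines()
        assert rows[1].startswith("1\t0.5")


class TestCompareMethods:
    def _summary(self, accs):
        from neurofuse.evaluation import RunSummary

        return RunSummary("x", np.asarray(accs, float), np.ones(len(accs)))

    def test_identical_samples(self):
        a = self._summary([90, 92, 94])
        t, p = compare_methods(a, self._summary([90, 92, 94]))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        a = self._summary([1.0, 2.0, 3.0])
        b = self._summary([11.001, 12.002, 13.001])
        t, p = compare_methods(a, b)
        assert p < 0.01

    def test_antisymmetry(self):
        a = self._summary([80, 85, 90, 95])
        b = self._summary([70, 75, 72, 78])
        t_ab, p_ab = compare_methods(a, b)
        t_ba, p_ba = compare_methods(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)


class TestRunExperiment:
    def test_reproducible_under_master_seed(self):
        ts, _ = generate_trialset(n_trials_per_class=8, seed=2)
        kw = dict(n_runs=2, seed=4, optimizer={"max_iter": 5, "n_whales": 4})
        a = run_experiment(ts, "ewoa", **kw)
        b = run_experiment(ts, "ewoa", **kw)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert np.array_equal(a.feature_counts, b.feature_counts)

    def test_baseline_uses_all_features(self):
        ts, _ = generate_trialset(n_trials_per_class=8, seed=2)
        summary = run_experiment(ts, "none", n_runs=2, seed=0)
        assert np.all(summary.feature_counts == 330)

    def test_shuffled_labels_give_chance_accuracy(self):
        ts, _ = generate_trialset(n_trials_per_class=30, seed=6)
        summary = run_experiment(ts, "none", n_runs=10, seed=1, shuffle_labels=True)
        n_pred = 12 * 10
        half_width = 100 * 1.96 * np.sqrt(0.25 / n_pred)
        assert abs(summary.mean_accuracy - 50.0) < half_width + 5

    def test_unknown_method_rejected(self):
        ts, _ = generate_trialset(n_trials_per_class=4, seed=0)
        with pytest.raises(ValueError):
            run_experiment(ts, "genetic")
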