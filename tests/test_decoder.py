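import numpy as np
import pytest

from ensdec import (DecoderConfig, balanced_subsample, build_fold_plan,
                    cv_accuracy, shuffled_label_accuracy, permutation_p,
                    binomial_p, TunedLinearSVC, FoldPlan)

FAST = DecoderConfig(c_grid=(1.0,), n_balance_repeats=2, seed=0)


def _four_conditions(n_per, rng):
    conds = np.repeat(["i|u", "i|d", "c|u", "c|d"], n_per)
    return rng.permutation(conds)


class TestBalancedSubsample:
    def test_min_count_arithmetic(self):
        labels = np.array(["a"] * 12 + ["b"] * 8 + ["c"] * 10 + ["d"] * 8)
        idx = balanced_subsample(labels, 0)
        assert len(idx) == 32
        vals, counts = np.unique(labels[idx], return_counts=True)
        assert (counts == 8).all()

    def test_already_balanced_returns_all(self):
        labels = np.repeat(["a", "b"], 10)
        assert set(balanced_subsample(labels, 0)) == set(range(20))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        labels = rng.choice(["a", "b", "c"], 60)
        assert np.array_equal(balanced_subsample(labels, 42),
                              balanced_subsample(labels, 42))

    def test_empty_condition_errors(self):
        with pytest.raises(ValueError):
            balanced_subsample(np.array([], dtype=str), 0)


class TestCVAccuracy:
    def test_separable_unit_decoded_perfectly(self):
        rng = np.random.default_rng(0)
        y = rng.permutation(np.repeat(["L", "R"], 60))
        X = np.where(y == "L", 2.0, 20.0)[:, None] + rng.normal(0, 0.5, (120, 1))
        res = cv_accuracy(X, y, FAST)
        assert res.mean_accuracy >= 0.99

    def test_chance_for_uninformative_features(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.permutation(np.repeat(["L", "R"], 100))
            X = rng.poisson(5.0, size=(200, 4)).astype(float)
            cfg = DecoderConfig(c_grid=(1.0,), n_balance_repeats=1, seed=seed)
            accs.append(cv_accuracy(X, y, cfg).mean_accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=2 * np.sqrt(0.25 / 200))

    def test_determinism_with_shared_plan(self):
        rng = np.random.default_rng(1)
        y = rng.permutation(np.repeat(["L", "R"], 40))
        X = rng.poisson(5.0, size=(80, 3)).astype(float)
        plan = build_fold_plan(y, y, FAST)
        a = cv_accuracy(X, y, FAST, plan=plan).mean_accuracy
        b = cv_accuracy(X, y, FAST, plan=plan).mean_accuracy
        assert a == b

    def test_each_trial_tested_once_per_repeat(self):
        rng = np.random.default_rng(2)
        cond = _four_conditions(20, rng)
        y = np.array([c.split("|")[0] for c in cond])
        plan = build_fold_plan(cond, y, FAST)
        for idx, fold_id in plan.repeats:
            assert len(idx) == len(set(idx))
            assert fold_id.min() == 0 and fold_id.max() == FAST.n_folds - 1
            # union of test folds = the balanced set, each exactly once
            assert sum((fold_id == f).sum() for f in range(FAST.n_folds)) == len(idx)

    def test_degenerate_labels_error(self):
        X = np.zeros((20, 2))
        with pytest.raises(ValueError):
            cv_accuracy(X, np.repeat("L", 20), FAST)

    def test_plan_serialization_round_trip(self):
        rng = np.random.default_rng(3)
        y = rng.permutation(np.repeat(["L", "R"], 30))
        plan = build_fold_plan(y, y, FAST)
        back = FoldPlan.from_dict(plan.to_dict())
        for (i1, f1), (i2, f2) in zip(plan.repeats, back.repeats):
            assert np.array_equal(i1, i2) and np.array_equal(f1, f2)


class TestNullsAndPValues:
    def test_shuffles_center_on_chance(self):
        rng = np.random.default_rng(4)
        y = rng.permutation(np.repeat(["L", "R"], 60))
        X = np.where(y == "L", 2.0, 10.0)[:, None] + rng.normal(0, 1, (120, 1))
        null = shuffled_label_accuracy(X, y, FAST, n_shuffles=8)
        assert len(null) == 8
        assert abs(np.mean(null) - 0.5) < 0.1
        obs = cv_accuracy(X, y, FAST).mean_accuracy
        assert obs > max(null)

    def test_zero_shuffles_empty(self):
        assert shuffled_label_accuracy(np.zeros((10, 1)),
                                       np.repeat(["a", "b"], 5), FAST, 0) == []

    @pytest.mark.parametrize("observed,null,expected", [
        (0.9, [0.5] * 99, 1 / 100),
        (0.1, [0.5] * 99, 1.0),
        (0.5, [0.4, 0.4, 0.4, 0.4, 0.5, 0.6, 0.6, 0.6, 0.6], 6 / 10),
    ])
    def test_permutation_p_definition(self, observed, null, expected):
        assert permutation_p(observed, null) == pytest.approx(expected)

    def test_binomial_alternative(self):
        assert binomial_p(60, 100) < 0.05 < binomial_p(52, 100)


class TestTunedLinearSVC:
    def test_sklearn_contract(self):
        from sklearn.utils.validation import check_is_fitted
        rng = np.random.default_rng(5)
        y = rng.permutation(np.repeat([0, 1], 50))
        X = np.column_stack([np.where(y == 0, 1.0, 4.0)
                             + rng.normal(0, 1, 100),
                             rng.normal(0, 1, 100)])
        clf = TunedLinearSVC(c_grid=(0.1, 1.0, 10.0), seed=0)
        assert clf.get_params()["inner_folds"] == 5
        clf.fit(X, y)
        check_is_fitted(clf)
        assert clf.best_C_ in (0.1, 1.0, 10.0)
        assert (clf.predict(X) == y).mean() > 0.8

    def test_grid_search_avoids_leakage_under_null(self):
        # with a wide grid, held-out accuracy stays near chance on pure noise
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.permutation(np.repeat(["L", "R"], 50))
            X = rng.normal(size=(100, 8))
            cfg = DecoderConfig(c_grid=(1e-3, 1e-1, 10.0, 1e3),
                                n_balance_repeats=1, seed=seed)
            accs.append(cv_accuracy(X, y, cfg).mean_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.06
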