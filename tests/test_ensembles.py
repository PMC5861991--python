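import numpy as np
import pytest

from ensdec import (DecoderConfig, build_fold_plan, cv_accuracy, rank_units,
                    build_bsu_curve, build_be_curve,
                    decorrelate_within_condition, curve_with_controls,
                    summarize_curve, GreedyEnsembleSelector,
                    GeneratorConfig, generate_session, extract_counts,
                    POSTCUE_WINDOW)
from ensdec.ensembles import EnsembleCurve

FAST = DecoderConfig(c_grid=(1.0,), n_balance_repeats=2, seed=0)


def _informative_data(seed, n_units=6, n_trials=160, n_good=2, sep=3.0):
    rng = np.random.default_rng(seed)
    loc = rng.permutation(np.repeat(["i", "c"], n_trials // 2))
    dr = rng.permutation(np.repeat(["u", "d"], n_trials // 2))
    cond = np.char.add(loc, dr)
    X = rng.poisson(5.0, size=(n_trials, n_units)).astype(float)
    for u in range(n_good):
        X[:, u] += np.where(loc == "i", sep * (u + 1) / n_good, 0.0)
    return X, loc, cond


class TestRanking:
    def test_informative_unit_ranks_first(self):
        X, y, cond = _informative_data(0, n_units=4, n_good=1, sep=6.0)
        plan = build_fold_plan(cond, y, FAST)
        order, accs = rank_units(X, y, FAST, cond, plan)
        assert order[0] == 0
        assert accs[0] == max(accs)

    def test_deterministic_ordering(self):
        X, y, cond = _informative_data(1)
        plan = build_fold_plan(cond, y, FAST)
        o1, _ = rank_units(X, y, FAST, cond, plan)
        o2, _ = rank_units(X, y, FAST, cond, plan)
        assert np.array_equal(o1, o2)


class TestCurves:
    def test_bsu_membership_is_rank_order(self):
        X, y, cond = _informative_data(2)
        plan = build_fold_plan(cond, y, FAST)
        order, _ = rank_units(X, y, FAST, cond, plan)
        curve = build_bsu_curve(X, y, FAST, cond, plan=plan)
        assert curve.membership_order == list(order)

    def test_be_matches_exhaustive_candidate_oracle(self):
        """Every BE step picks the argmax over an independent re-evaluation
        of all candidate additions under the shared plan."""
        X, y, cond = _informative_data(3, n_units=5)
        plan = build_fold_plan(cond, y, FAST)
        curve = build_be_curve(X, y, FAST, cond, plan=plan)
        members = [curve.membership_order[0]]
        for step in range(1, 5):
            best_u, best_acc = None, -1.0
            for u in range(5):
                if u in members:
                    continue
                acc = cv_accuracy(X[:, sorted(members + [u])], y, FAST,
                                  plan=plan).mean_accuracy
                if acc > best_acc + 1e-12:
                    best_u, best_acc = u, acc
            assert curve.membership_order[step] == best_u
            assert curve.accuracy_per_size[step] == pytest.approx(best_acc)
            members.append(best_u)

    def test_endpoint_identity_and_be2_dominance(self):
        X, y, cond = _informative_data(4)
        plan = build_fold_plan(cond, y, FAST)
        bsu = build_bsu_curve(X, y, FAST, cond, plan=plan)
        be = build_be_curve(X, y, FAST, cond, plan=plan)
        assert be.membership_order[0] == bsu.membership_order[0]
        assert be.accuracy_per_size[-1] == bsu.accuracy_per_size[-1]
        assert be.accuracy_per_size[1] >= bsu.accuracy_per_size[1]
        assert sorted(be.membership_order) == sorted(bsu.membership_order)

    def test_all_noise_curve_near_chance(self):
        rng = np.random.default_rng(5)
        y = rng.permutation(np.repeat(["i", "c"], 80))
        X = rng.poisson(5.0, (160, 4)).astype(float)
        curve = build_bsu_curve(X, y, FAST, y)
        assert np.all(np.abs(curve.accuracy_per_size - 0.5) < 0.15)


class TestDecorrelation:
    def test_marginals_exactly_preserved(self):
        rng = np.random.default_rng(6)
        cond = rng.choice(["a", "b"], 100)
        X = rng.poisson(4.0, (100, 5))
        Xs = decorrelate_within_condition(X, cond, seed=1)
        for c in ("a", "b"):
            m = cond == c
            for u in range(5):
                assert sorted(X[m, u]) == sorted(Xs[m, u])

    def test_correlations_destroyed(self):
        rng = np.random.default_rng(7)
        cond = np.repeat(["a", "b"], 150)
        shared = rng.normal(0, 2, 300)
        X = rng.poisson(8.0, (300, 6)) + shared[:, None]
        corrs = []
        for seed in range(10):
            Xs = decorrelate_within_condition(X, cond, seed=seed)
            resid = Xs - np.vstack([Xs[cond == c].mean(0)
                                    for c in cond])
            c = np.corrcoef(resid.T)
            corrs.append(c[np.triu_indices(6, 1)].mean())
        assert abs(np.mean(corrs)) < 0.03
        raw_resid = X - np.vstack([X[cond == c].mean(0) for c in cond])
        raw_c = np.corrcoef(raw_resid.T)[np.triu_indices(6, 1)].mean()
        assert raw_c > 0.2

    def test_single_trial_condition_left_alone(self):
        X = np.arange(10).reshape(5, 2)
        cond = np.array(["a", "a", "a", "a", "b"])
        Xs = decorrelate_within_condition(X, cond, seed=0)
        assert np.array_equal(Xs[4], X[4])


class TestSummary:
    @pytest.mark.parametrize("accs,expect", [
        ([0.6, 0.9, 0.85], (0.9, 2, 2)),       # 90% threshold 0.81
        ([0.7, 0.7, 0.7], (0.7, 1, 1)),
        ([0.5, 0.73, 0.7, 0.8], (0.8, 4, 2)),  # threshold 0.72
        ([0.9, 0.6, 0.6], (0.9, 1, 1)),
    ])
    def test_summary_definition(self, accs, expect):
        curve = EnsembleCurve("BE", "raw", list(range(len(accs))),
                              np.asarray(accs), np.zeros(len(accs)),
                              "target_location", 0)
        s = summarize_curve(curve)
        assert (s.max_accuracy, s.size_at_max, s.size_at_90pct_of_max) == expect
        assert s.total_n == len(accs)


@pytest.fixture(scope="module")
def controls():
    X, y, cond = _informative_data(8, n_units=5)
    return curve_with_controls(X, y, FAST, cond, n_decorr=6, n_chance=4,
                               methods=("BSU",), seed=0), X


class TestControls:
    def test_chance_curves_near_half(self, controls):
        res, _ = controls
        chance = res["curves"][("BSU", "label_shuffled")]
        assert np.all(np.abs(chance.accuracy_per_size - 0.5) < 0.2)

    def test_decorrelated_keeps_membership(self, controls):
        res, _ = controls
        raw = res["curves"][("BSU", "raw")]
        dec = res["curves"][("BSU", "decorrelated")]
        assert dec.membership_order == raw.membership_order

    def test_per_size_tests_present(self, controls):
        res, _ = controls
        assert len(res["tests"][("BSU", "chance")]) == 5
        assert all(0 < t["p"] <= 1 for t in res["tests"][("BSU", "chance")])
        assert len(res["tests"][("BSU", "decorrelated")]) == 5

    def test_zero_decorr_omits_variant(self):
        X, y, cond = _informative_data(9, n_units=3)
        res = curve_with_controls(X, y, FAST, cond, n_decorr=0, n_chance=0,
                                  methods=("BSU",))
        assert ("BSU", "decorrelated") not in res["curves"]
        assert ("BSU", "label_shuffled") not in res["curves"]


class TestSelectorEstimator:
    def test_fit_transform_contract(self):
        X, y, cond = _informative_data(10, n_units=5, n_good=1, sep=6.0)
        sel = GreedyEnsembleSelector(method="BE", config=FAST, max_size=4)
        assert sel.get_params()["method"] == "BE"
        sel.fit(X, y, condition_labels=cond)
        assert len(sel.membership_order_) == 4
        assert sel.membership_order_[0] == 0
        Xt = sel.transform(X)
        assert Xt.shape == (len(y), sel.best_size_)
        assert sel.get_support().sum() == sel.best_size_
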