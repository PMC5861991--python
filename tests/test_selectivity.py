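import numpy as np
import pandas as pd
import pytest

from ensdec import (GeneratorConfig, generate_session, extract_counts,
                    POSTCUE_WINDOW, CUE_WINDOW, BASELINE_WINDOW,
                    task_relatedness, classify_selectivity, dprime,
                    proportion_permutation_test, wald_halfwidth,
                    wilson_halfwidth, two_way_anova_2x2)
from ensdec.io import CountMatrix, EpochWindow


def _labels(n, rng):
    return pd.DataFrame({
        "target_location": rng.permutation(np.repeat(["ipsi", "contra"], n // 2)),
        "motion_direction": rng.permutation(np.repeat(["up", "down"], n // 2)),
        "outcome": ["hit"] * n,
    })


def _matrix(counts, labels, window=POSTCUE_WINDOW):
    n, u = counts.shape
    return CountMatrix(counts, window, np.arange(n), np.arange(u), labels)


class TestAnova:
    def test_matches_statsmodels_type3(self, small_counts):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        loc = small_counts.binary_labels("target_location")
        dr = small_counts.binary_labels("motion_direction")
        mine = two_way_anova_2x2(small_counts.counts, loc, dr)
        for u in [0, 7, 19]:
            df = pd.DataFrame({"y": small_counts.counts[:, u], "l": loc, "d": dr})
            fit = smf.ols("y ~ C(l, Sum) * C(d, Sum)", data=df).fit()
            tab = anova_lm(fit, typ=3)
            assert mine["p_location"][u] == pytest.approx(
                tab.loc["C(l, Sum)", "PR(>F)"], rel=1e-8)
            assert mine["p_direction"][u] == pytest.approx(
                tab.loc["C(d, Sum)", "PR(>F)"], rel=1e-8)
            assert mine["p_interaction"][u] == pytest.approx(
                tab.loc["C(l, Sum):C(d, Sum)", "PR(>F)"], rel=1e-8)

    def test_zero_variance_unit_is_none(self):
        rng = np.random.default_rng(0)
        labels = _labels(40, rng)
        counts = np.column_stack([np.full(40, 3), rng.poisson(5, 40)])
        res = classify_selectivity(_matrix(counts, labels))
        assert res.category.iloc[0] == "none"
        assert res.p_location.iloc[0] == 1.0

    def test_missing_factor_level_errors(self):
        rng = np.random.default_rng(0)
        labels = _labels(40, rng)
        labels["motion_direction"] = "up"
        with pytest.raises(ValueError):
            classify_selectivity(_matrix(rng.poisson(5, (40, 2)), labels))

    def test_parameter_recovery_on_tuned_units(self, small_session):
        session, truth = small_session
        cm = extract_counts(session, POSTCUE_WINDOW)
        res = classify_selectivity(cm).merge(
            truth.units[["unit_id", "category", "preferred_location",
                         "preferred_direction"]],
            on="unit_id", suffixes=("", "_true"))
        strong = res[res.category_true != "none"]
        agree = (strong.category == strong.category_true).mean()
        assert agree >= 0.8
        loc_sel = res[res.category.isin(["location", "both"])
                      & res.category_true.isin(["location", "both"])]
        assert (loc_sel.preferred_location == loc_sel.preferred_location_true).all()


class TestTaskRelatedness:
    def test_tuned_session_flags_responsive_units(self, small_session):
        session, _ = small_session
        pc = extract_counts(session, POSTCUE_WINDOW)
        cue = extract_counts(session, CUE_WINDOW)
        base = extract_counts(session, BASELINE_WINDOW)
        out = task_relatedness(pc, cue, base)
        assert out.task_related.any()
        assert not out.loc[~out.included, "task_related"].any()

    def test_rate_floor_excludes_silent_units(self):
        rng = np.random.default_rng(2)
        labels = _labels(60, rng)
        # unit 0 fires ~0.03 Hz overall; unit 1 is a healthy 10 Hz unit
        silent = rng.poisson(0.02, 60)
        lively = rng.poisson(5.0, 60)
        pc = _matrix(np.column_stack([silent, lively]), labels, POSTCUE_WINDOW)
        cue = _matrix(np.column_stack([silent, lively]), labels, CUE_WINDOW)
        base = _matrix(np.zeros((60, 2), dtype=int), labels, BASELINE_WINDOW)
        out = task_relatedness(pc, cue, base)
        assert not out.included.iloc[0]
        assert np.isnan(out.p_postcue.iloc[0])
        assert out.task_related.iloc[1]

    def test_mismatched_units_error(self, small_session):
        session, _ = small_session
        pc = extract_counts(session, POSTCUE_WINDOW)
        cue = extract_counts(session, CUE_WINDOW)
        base = extract_counts(session, BASELINE_WINDOW)
        with pytest.raises(ValueError):
            task_relatedness(pc.restrict_units(pc.unit_ids[:5]), cue, base)


class TestDprime:
    def test_formula_cases(self):
        labels = np.repeat(["a", "b"], 50)
        rng = np.random.default_rng(1)
        # means 12 vs 8, both variances 4 -> d' = 2
        x1 = 12 + 2 * rng.standard_normal(50)
        x2 = 8 + 2 * rng.standard_normal(50)
        X = np.concatenate([x1, x2])[:, None]
        m1, m2 = X[:50].mean(), X[50:].mean()
        v1, v2 = X[:50].var(ddof=1), X[50:].var(ddof=1)
        expected = abs(m1 - m2) / np.sqrt((v1 + v2) / 2)
        assert dprime(X, labels)[0] == pytest.approx(expected)
        assert expected == pytest.approx(2.0, abs=0.5)

    def test_equal_means_give_zero(self):
        labels = np.repeat(["a", "b"], 4)
        X = np.array([1, 1, 3, 3, 2, 2, 2, 2], dtype=float)[:, None]
        # means equal (2 vs 2) but variances differ -> 0
        assert dprime(X, labels)[0] == 0.0

    def test_too_few_trials_is_missing(self):
        labels = np.array(["a", "b", "b", "b"])
        X = np.arange(4, dtype=float)[:, None]
        assert np.isnan(dprime(X, labels)[0])


class TestProportions:
    @pytest.mark.parametrize("count,n,printed", [
        (167, 462, 0.0438), (80, 462, 0.0345), (147, 391, 0.048)])
    def test_wald_halfwidth_reproduces_reported_values(self, count, n, printed):
        assert wald_halfwidth(count, n) == pytest.approx(printed, abs=5e-4)

    def test_wilson_differs_from_wald(self):
        assert wilson_halfwidth(167, 462) != pytest.approx(
            wald_halfwidth(167, 462), abs=1e-5)

    def test_zero_count_interval(self):
        assert wald_halfwidth(0, 100) == 0.0

    def test_null_proportions_near_alpha(self, null_session):
        session, _ = null_session
        cm = extract_counts(session, POSTCUE_WINDOW)
        summary = proportion_permutation_test(cm, alpha=0.05, n_perm=150, seed=0)
        assert summary.null_proportions["location"] == pytest.approx(0.05, abs=0.03)
        assert summary.null_proportions["direction"] == pytest.approx(0.05, abs=0.03)
        assert all(p > 0.001 for p in summary.chi2_p.values())

    def test_tuned_proportions_beat_null(self, small_counts):
        summary = proportion_permutation_test(small_counts, n_perm=150, seed=1)
        assert summary.observed_proportions["location"] \
            > summary.null_proportions["location"]
        assert summary.chi2_p["location"] < 0.01

    def test_no_units_error(self, small_counts):
        with pytest.raises(ValueError):
            proportion_permutation_test(small_counts.restrict_units([]))
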