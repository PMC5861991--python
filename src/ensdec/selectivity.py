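"""Single-unit selectivity: task-relatedness screen, two-way ANOVA
classification, d-prime, and the permutation test on selectivity proportions.

Units are screened for task-relatedness by comparing cue-period and postcue
firing rates to a baseline window around stimulus onset (two-sided Wilcoxon
rank-sum).  Task-related units are then classified with a two-factor
fixed-effects ANOVA (attended location x motion direction, interaction
included but not used for categorization), and the observed category
proportions are compared with a trial-label permutation null via chi-square
tests.  Confidence half-widths for proportions are available in both the
normal-approximation (Wald, default) and Wilson score forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io import CountMatrix

CATEGORIES = ("location", "direction", "both", "none")
RATE_FLOOR_HZ = 0.1


# -- vectorised 2x2 two-way ANOVA ------------------------------------------

def two_way_anova_2x2(counts: np.ndarray, loc_labels: np.ndarray,
                      dir_labels: np.ndarray) -> dict:
    """Two-factor fixed-effects ANOVA with interaction for 2x2 designs,
    vectorised over units (columns of ``counts``).

    Implemented as an effect-coded OLS fit; with two levels per factor each
    term has 1 df and the squared coefficient t equals the term's F.  For
    balanced designs this coincides with the classical sum-of-squares ANOVA;
    for mildly unbalanced designs it tests each term adjusted for the others.
    Zero-variance units get p = 1 for every term.
    """
    Y = np.asarray(counts, dtype=float)
    n = Y.shape[0]
    loc_levels = np.unique(loc_labels)
    dir_levels = np.unique(dir_labels)
    if len(loc_levels) != 2 or len(dir_levels) != 2:
        raise ValueError("both factors must have exactly two levels present")
    l = np.where(np.asarray(loc_labels) == loc_levels[0], 1.0, -1.0)
    d = np.where(np.asarray(dir_labels) == dir_levels[0], 1.0, -1.0)
    X = np.column_stack([np.ones(n), l, d, l * d])
    df_resid = n - 4
    if df_resid < 1:
        raise ValueError("need more than 4 trials for the two-way ANOVA")

    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)                      # (4, n_units)
    resid = Y - X @ B
    ss_res = (resid ** 2).sum(axis=0)
    sigma2 = ss_res / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        t = B / se
        p = 2.0 * stats.t.sf(np.abs(t), df_resid)

    zero_var = Y.var(axis=0) == 0
    perfect = (~zero_var) & (ss_res <= 1e-12)
    for row in range(4):
        p[row, zero_var] = 1.0
        p[row, perfect] = 0.0
    return {"p_location": p[1], "p_direction": p[2], "p_interaction": p[3],
            "t_location": t[1], "t_direction": t[2], "df_resid": df_resid}


# -- d-prime ----------------------------------------------------------------

def dprime(counts: CountMatrix | np.ndarray, factor_labels: np.ndarray | str) -> np.ndarray:
    """Sensitivity index per unit between the two levels of a factor.

    d' = |mean_1 - mean_2| / sqrt((var_1 + var_2) / 2), signed toward the
    preferred (higher-mean) level, hence >= 0.  Returns NaN for units where a
    level has fewer than 2 trials, 0 when means are equal, inf when the means
    differ but both variances are 0.
    """
    if isinstance(counts, CountMatrix):
        X = np.asarray(counts.counts, dtype=float)
        labels = counts.binary_labels(str(factor_labels))
    else:
        X = np.asarray(counts, dtype=float)
        labels = np.asarray(factor_labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("factor must have exactly two levels present")
    a, b = labels == levels[0], labels == levels[1]
    if a.sum() < 2 or b.sum() < 2:
        return np.full(X.shape[1], np.nan)
    m1, m2 = X[a].mean(axis=0), X[b].mean(axis=0)
    v1 = X[a].var(axis=0, ddof=1)
    v2 = X[b].var(axis=0, ddof=1)
    pooled = np.sqrt((v1 + v2) / 2.0)
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(diff == 0, 0.0, np.where(pooled > 0, diff / pooled, np.inf))
    return d


# -- task-relatedness screen ------------------------------------------------

def task_relatedness(postcue: CountMatrix, cue: CountMatrix,
                     baseline: CountMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Flag units whose cue or postcue rate differs from baseline.

    Two-sided Wilcoxon rank-sum per unit for each of the two comparisons;
    a unit is task-related when either p < ``alpha``.  Units whose overall
    rate across the three windows is <= 0.1 Hz are excluded before testing
    (``included`` False, p-values NaN).
    """
    if not (np.array_equal(postcue.unit_ids, cue.unit_ids)
            and np.array_equal(postcue.unit_ids, baseline.unit_ids)):
        raise ValueError("count matrices must share the same unit ordering")

    total_spikes = (postcue.counts.sum(axis=0) + cue.counts.sum(axis=0)
                    + baseline.counts.sum(axis=0))
    total_time = (postcue.n_trials * postcue.window.duration_s
                  + cue.n_trials * cue.window.duration_s
                  + baseline.n_trials * baseline.window.duration_s)
    overall_rate = total_spikes / total_time
    included = overall_rate > RATE_FLOOR_HZ

    n_units = postcue.n_units
    p_post = np.full(n_units, np.nan)
    p_cue = np.full(n_units, np.nan)
    post_r, cue_r, base_r = postcue.rates(), cue.rates(), baseline.rates()
    for u in np.flatnonzero(included):
        p_post[u] = stats.ranksums(post_r[:, u], base_r[:, u]).pvalue
        p_cue[u] = stats.ranksums(cue_r[:, u], base_r[:, u]).pvalue
    p_task = np.fmin(p_post, p_cue)
    flagged = included & ((p_post < alpha) | (p_cue < alpha))
    return pd.DataFrame({
        "unit_id": postcue.unit_ids, "overall_rate_hz": overall_rate,
        "included": included, "p_postcue": p_post, "p_cue": p_cue,
        "p_task": p_task, "task_related": flagged,
    })


# -- two-way classification -------------------------------------------------

def classify_selectivity(counts: CountMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-unit selectivity category from the two-way ANOVA main effects.

    ``location`` / ``direction`` when only that main effect is significant at
    ``alpha``, ``both`` when both are, else ``none`` (a significant
    interaction alone does not assign a category).  The preferred level of a
    significant factor is the one with the higher mean rate.
    """
    loc = counts.binary_labels("target_location")
    dr = counts.binary_labels("motion_direction")
    res = two_way_anova_2x2(counts.counts, loc, dr)
    sig_loc = res["p_location"] < alpha
    sig_dir = res["p_direction"] < alpha
    category = np.where(sig_loc & sig_dir, "both",
                        np.where(sig_loc, "location",
                                 np.where(sig_dir, "direction", "none")))

    X = counts.counts.astype(float)
    loc_levels = np.unique(loc)
    dir_levels = np.unique(dr)
    mean_l0 = X[loc == loc_levels[0]].mean(axis=0)
    mean_l1 = X[loc == loc_levels[1]].mean(axis=0)
    mean_d0 = X[dr == dir_levels[0]].mean(axis=0)
    mean_d1 = X[dr == dir_levels[1]].mean(axis=0)
    preferred_location = np.where(mean_l0 >= mean_l1, loc_levels[0], loc_levels[1])
    preferred_direction = np.where(mean_d0 >= mean_d1, dir_levels[0], dir_levels[1])

    return pd.DataFrame({
        "unit_id": counts.unit_ids,
        "p_location": res["p_location"], "p_direction": res["p_direction"],
        "p_interaction": res["p_interaction"], "category": category,
        "preferred_location": preferred_location,
        "preferred_direction": preferred_direction,
        "dprime_location": dprime(X, loc),
        "dprime_direction": dprime(X, dr),
    })


# -- proportion intervals ---------------------------------------------------

def wald_halfwidth(count: int, n: int, conf: float = 0.95) -> float:
    """Half-width of the normal-approximation binomial interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = count / n
    z = stats.norm.ppf(0.5 + conf / 2.0)
    return float(z * np.sqrt(p * (1.0 - p) / n))


def wilson_halfwidth(count: int, n: int, conf: float = 0.95) -> float:
    """Half-width of the Wilson score interval (half the interval length)."""
    lo, hi = proportion_confint(count, n, alpha=1.0 - conf, method="wilson")
    return float((hi - lo) / 2.0)


@dataclass
class ProportionSummary:
    """Observed vs permutation-null selectivity proportions."""

    n_units: int
    observed_counts: dict
    observed_proportions: dict
    halfwidth_wald: dict
    halfwidth_wilson: dict
    null_proportions: dict
    chi2_p: dict
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units, "observed_counts": self.observed_counts,
            "observed_proportions": self.observed_proportions,
            "halfwidth_wald": self.halfwidth_wald,
            "halfwidth_wilson": self.halfwidth_wilson,
            "null_proportions": self.null_proportions,
            "chi2_p": self.chi2_p, "n_perm": self.n_perm, "seed": self.seed,
        }


def _category_counts(p_loc: np.ndarray, p_dir: np.ndarray, alpha: float) -> np.ndarray:
    sig_l, sig_d = p_loc < alpha, p_dir < alpha
    return np.array([int((sig_l & ~sig_d).sum()), int((~sig_l & sig_d).sum()),
                     int((sig_l & sig_d).sum())])


def proportion_permutation_test(counts: CountMatrix, alpha: float = 0.05,
                                n_perm: int = 1000, seed: int = 0) -> ProportionSummary:
    """Permutation test on selectivity proportions.

    The trial-label order is permuted ``n_perm`` times and the ANOVA
    recomputed; the null proportion per category (location / direction /
    both) is the mean over permutations.  Observed category counts are then
    compared with the null expectation via a one-df chi-square goodness-of-fit
    per category.
    """
    if counts.n_units == 0:
        raise ValueError("no task-related units to test")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; null proportions will be noisy")
    rng = np.random.default_rng(seed)
    loc = counts.binary_labels("target_location")
    dr = counts.binary_labels("motion_direction")
    Y = counts.counts

    res = two_way_anova_2x2(Y, loc, dr)
    obs = _category_counts(res["p_location"], res["p_direction"], alpha)
    n = counts.n_units

    null_counts = np.zeros((n_perm, 3))
    for i in range(n_perm):
        perm = rng.permutation(counts.n_trials)
        r = two_way_anova_2x2(Y, loc[perm], dr[perm])
        null_counts[i] = _category_counts(r["p_location"], r["p_direction"], alpha)
    null_prop = null_counts.mean(axis=0) / n

    names = ("location", "direction", "both")
    chi2_p = {}
    for j, name in enumerate(names):
        expected = np.array([null_prop[j] * n, (1.0 - null_prop[j]) * n])
        if expected.min() <= 0:
            expected = np.clip(expected, 0.5, None)
            expected *= n / expected.sum()
        observed = np.array([obs[j], n - obs[j]])
        chi2_p[name] = float(stats.chisquare(observed, expected).pvalue)

    return ProportionSummary(
        n_units=n,
        observed_counts={k: int(obs[j]) for j, k in enumerate(names)},
        observed_proportions={k: obs[j] / n for j, k in enumerate(names)},
        halfwidth_wald={k: wald_halfwidth(int(obs[j]), n) for j, k in enumerate(names)},
        halfwidth_wilson={k: wilson_halfwidth(int(obs[j]), n) for j, k in enumerate(names)},
        null_proportions={k: float(null_prop[j]) for j, k in enumerate(names)},
        chi2_p=chi2_p, n_perm=n_perm, seed=seed,
    )
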