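"""Greedy ensemble-building curves and their controls.

Two ways of growing a decoding ensemble from simultaneously recorded units:

* BSU (best single units): rank units by individual cross-validated decoding
  accuracy and add them in that order.
* BE (best ensemble): start from the best single unit; at every step evaluate
  every remaining unit as an addition, under the same fold plan, and keep the
  one that maximizes ensemble accuracy.

Controls: chance curves rebuilt on fully label-shuffled surrogates, and
decorrelated curves in which each unit's trials are shuffled within condition
(destroying shared trial-by-trial variability while preserving marginals) and
the accuracy of the *fixed* raw-data memberships is recomputed.

All candidate evaluations within one build share a single fold plan so that
accuracy differences reflect ensemble composition, not resampling noise; this
also makes BE(2) >= BSU(2) and the size-N endpoint identity exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .decoder import (DecoderConfig, FoldPlan, build_fold_plan, cv_accuracy,
                      permutation_p)

logger = logging.getLogger(__name__)


@dataclass
class EnsembleCurve:
    """Ordered memberships and per-size CV accuracy for one building method."""

    method: str            # "BSU" | "BE"
    variant: str           # "raw" | "decorrelated" | "label_shuffled"
    membership_order: list
    accuracy_per_size: np.ndarray
    dispersion_per_size: np.ndarray
    label: str
    seed: int

    def to_dict(self) -> dict:
        return {"method": self.method, "variant": self.variant,
                "membership_order": [int(u) for u in self.membership_order],
                "accuracy_per_size": [float(a) for a in self.accuracy_per_size],
                "dispersion_per_size": [float(d) for d in self.dispersion_per_size],
                "label": self.label, "seed": self.seed}


@dataclass
class CurveSummary:
    """Maximum accuracy, the smallest size attaining it, and the smallest
    size attaining 90% of it (which may exceed the size at max)."""

    max_accuracy: float
    size_at_max: int
    size_at_90pct_of_max: int
    total_n: int

    def to_dict(self) -> dict:
        return {"max_accuracy": self.max_accuracy, "size_at_max": self.size_at_max,
                "size_at_90pct_of_max": self.size_at_90pct_of_max,
                "total_n": self.total_n}


def rank_units(X: np.ndarray, y: np.ndarray, config: DecoderConfig,
               condition_labels: np.ndarray, plan: FoldPlan,
               unit_ids: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Units ordered by single-unit CV accuracy (desc), ties by smaller id.

    Returns (ordering over column indices, single-unit accuracies in the
    original column order).
    """
    X = np.asarray(X, dtype=float)
    n_units = X.shape[1]
    if n_units < 1:
        raise ValueError("need at least one unit")
    if unit_ids is None:
        unit_ids = np.arange(n_units)
    accs = np.array([cv_accuracy(X[:, [u]], y, config, plan=plan).mean_accuracy
                     for u in range(n_units)])
    order = np.lexsort((np.asarray(unit_ids), -accs))
    return order, accs


def _curve_from_order(X, y, config, plan, order, max_size) -> tuple[np.ndarray, np.ndarray]:
    accs = np.empty(max_size)
    disp = np.empty(max_size)
    for k in range(1, max_size + 1):
        # columns sorted so accuracy is a function of the unit *set* only
        res = cv_accuracy(X[:, np.sort(order[:k])], y, config, plan=plan)
        accs[k - 1] = res.mean_accuracy
        disp[k - 1] = res.dispersion
    return accs, disp


def build_bsu_curve(X: np.ndarray, y: np.ndarray, config: DecoderConfig,
                    condition_labels: np.ndarray,
                    plan: FoldPlan | None = None,
                    unit_ids: np.ndarray | None = None,
                    max_size: int | None = None,
                    variant: str = "raw") -> EnsembleCurve:
    """Best-single-units curve: add units in order of individual accuracy."""
    X = np.asarray(X, dtype=float)
    if plan is None:
        plan = build_fold_plan(condition_labels, y, config)
    if unit_ids is None:
        unit_ids = np.arange(X.shape[1])
    order, _ = rank_units(X, y, config, condition_labels, plan, unit_ids)
    max_size = X.shape[1] if max_size is None else min(max_size, X.shape[1])
    accs, disp = _curve_from_order(X, y, config, plan, order, max_size)
    return EnsembleCurve("BSU", variant, [unit_ids[i] for i in order[:max_size]],
                         accs, disp, config.label, config.seed)


def build_be_curve(X: np.ndarray, y: np.ndarray, config: DecoderConfig,
                   condition_labels: np.ndarray,
                   plan: FoldPlan | None = None,
                   unit_ids: np.ndarray | None = None,
                   max_size: int | None = None,
                   variant: str = "raw") -> EnsembleCurve:
    """Best-ensemble curve: greedy forward selection from the best single unit.

    At each step every remaining unit is scored as an addition under the
    shared fold plan and the argmax is kept; ties go to the smaller unit id.
    """
    X = np.asarray(X, dtype=float)
    n_units = X.shape[1]
    if plan is None:
        plan = build_fold_plan(condition_labels, y, config)
    if unit_ids is None:
        unit_ids = np.arange(n_units)
    unit_ids = np.asarray(unit_ids)
    max_size = n_units if max_size is None else min(max_size, n_units)

    order, single_accs = rank_units(X, y, config, condition_labels, plan, unit_ids)
    members = [int(order[0])]
    accs = [float(single_accs[order[0]])]
    disp = [0.0]
    res0 = cv_accuracy(X[:, members], y, config, plan=plan)
    accs[0], disp[0] = res0.mean_accuracy, res0.dispersion
    remaining = [i for i in range(n_units) if i != members[0]]
    while len(members) < max_size:
        best_i, best_acc, best_disp = None, -1.0, 0.0
        # candidates scanned in unit-id order so that exact ties keep the
        # smaller id
        for i in sorted(remaining, key=lambda j: unit_ids[j]):
            res = cv_accuracy(X[:, sorted(members + [i])], y, config, plan=plan)
            if res.mean_accuracy > best_acc + 1e-12:
                best_i, best_acc, best_disp = i, res.mean_accuracy, res.dispersion
        members.append(best_i)
        remaining.remove(best_i)
        accs.append(best_acc)
        disp.append(best_disp)
    return EnsembleCurve("BE", variant, [unit_ids[i] for i in members],
                         np.asarray(accs), np.asarray(disp), config.label,
                         config.seed)


def decorrelate_within_condition(X: np.ndarray, condition_labels: np.ndarray,
                                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Shuffle each unit's trials independently within condition.

    Per-unit, per-condition marginal count distributions are exactly
    preserved; across-unit within-condition correlations are destroyed in
    expectation.  Conditions with a single trial are left as is.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    X = np.asarray(X)
    out = X.copy()
    condition_labels = np.asarray(condition_labels)
    for c in np.unique(condition_labels):
        idx = np.flatnonzero(condition_labels == c)
        if len(idx) < 2:
            logger.info("decorrelate: condition %r has one trial; left unpermuted", c)
            continue
        for u in range(X.shape[1]):
            out[idx, u] = X[rng.permutation(idx), u]
    return out


def summarize_curve(curve: EnsembleCurve) -> CurveSummary:
    """Max accuracy, smallest size attaining it, smallest size at >=90% of it."""
    accs = np.asarray(curve.accuracy_per_size)
    if accs.size == 0:
        raise ValueError("empty curve")
    max_acc = float(accs.max())
    size_at_max = int(np.argmax(accs)) + 1
    size_90 = int(np.flatnonzero(accs >= 0.9 * max_acc)[0]) + 1
    return CurveSummary(max_acc, size_at_max, size_90, int(accs.size))


def curve_with_controls(X: np.ndarray, y: np.ndarray, config: DecoderConfig,
                        condition_labels: np.ndarray,
                        n_decorr: int = 100, n_chance: int = 10,
                        unit_ids: np.ndarray | None = None,
                        max_size: int | None = None,
                        methods: tuple = ("BSU", "BE"),
                        seed: int | None = None) -> dict:
    """Raw BSU/BE curves with decorrelated and label-shuffled controls.

    * raw: built on the data under one shared fold plan.
    * decorrelated: raw membership kept FIXED; accuracy per size recomputed on
      ``n_decorr`` within-condition shuffles and averaged (per-shuffle values
      retained for paired tests).
    * label_shuffled: membership REBUILT on each of ``n_chance`` full label
      permutations; mean curve reported, per-surrogate accuracies retained as
      the per-size permutation null.

    Returns a dict with the curves, per-size permutation p-values versus
    chance, and per-size one-sample t-tests of the decorrelated accuracies
    against the raw value.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    condition_labels = np.asarray(condition_labels)
    if unit_ids is None:
        unit_ids = np.arange(X.shape[1])
    unit_ids = np.asarray(unit_ids)
    plan = build_fold_plan(condition_labels, y, config)
    builders = {"BSU": build_bsu_curve, "BE": build_be_curve}
    out: dict = {"curves": {}, "tests": {}}

    for method in methods:
        build = builders[method]
        raw = build(X, y, config, condition_labels, plan=plan,
                    unit_ids=unit_ids, max_size=max_size)
        out["curves"][(method, "raw")] = raw
        sizes = len(raw.accuracy_per_size)
        col_of = {u: i for i, u in enumerate(unit_ids)}
        member_cols = [col_of[u] for u in raw.membership_order]

        if n_decorr > 0:
            dec = np.empty((n_decorr, sizes))
            for s in range(n_decorr):
                Xs = decorrelate_within_condition(X, condition_labels, rng)
                for k in range(1, sizes + 1):
                    res = cv_accuracy(Xs[:, np.sort(member_cols[:k])], y, config,
                                      plan=plan)
                    dec[s, k - 1] = res.mean_accuracy
            out["curves"][(method, "decorrelated")] = EnsembleCurve(
                method, "decorrelated", list(raw.membership_order),
                dec.mean(axis=0), dec.std(axis=0, ddof=1) if n_decorr > 1
                else np.zeros(sizes), config.label, config.seed)
            tstats = []
            for k in range(sizes):
                vals = dec[:, k]
                if n_decorr > 1 and vals.std(ddof=1) > 0:
                    t, p = stats.ttest_1samp(vals, raw.accuracy_per_size[k])
                else:
                    t, p = 0.0, 1.0
                tstats.append({"size": k + 1, "t": float(t), "p": float(p),
                               "raw": float(raw.accuracy_per_size[k]),
                               "decorrelated_mean": float(vals.mean())})
            out["tests"][(method, "decorrelated")] = tstats
            out.setdefault("decorr_accuracies", {})[method] = dec

        if n_chance > 0:
            chance = np.empty((n_chance, sizes))
            for s in range(n_chance):
                perm = rng.permutation(len(y))
                cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
                surro = build(X, y[perm], cfg, condition_labels[perm],
                              unit_ids=unit_ids, max_size=max_size)
                chance[s] = surro.accuracy_per_size
            out["curves"][(method, "label_shuffled")] = EnsembleCurve(
                method, "label_shuffled", [], chance.mean(axis=0),
                chance.std(axis=0, ddof=1) if n_chance > 1 else np.zeros(sizes),
                config.label, config.seed)
            out["tests"][(method, "chance")] = [
                {"size": k + 1,
                 "p": permutation_p(float(raw.accuracy_per_size[k]), chance[:, k])}
                for k in range(sizes)]
            out.setdefault("chance_accuracies", {})[method] = chance

    return out


class GreedyEnsembleSelector(BaseEstimator):
    """Greedy unit selector over the ensemble-building curves.

    scikit-learn-style wrapper: ``fit(X, y, condition_labels=...)`` builds the
    BSU or BE curve and exposes ``membership_order_``, ``accuracy_per_size_``
    and ``best_size_``; ``transform`` keeps the columns of the best ensemble.
    """

    def __init__(self, method: str = "BE", config: DecoderConfig | None = None,
                 max_size: int | None = None):
        self.method = method
        self.config = config
        self.max_size = max_size

    def fit(self, X, y, condition_labels=None):
        if self.method not in ("BSU", "BE"):
            raise ValueError("method must be 'BSU' or 'BE'")
        config = self.config or DecoderConfig()
        X = np.asarray(X, dtype=float)
        cond = np.asarray(condition_labels) if condition_labels is not None \
            else np.asarray(y)
        build = build_be_curve if self.method == "BE" else build_bsu_curve
        curve = build(X, y, config, cond, max_size=self.max_size)
        self.curve_ = curve
        self.membership_order_ = list(curve.membership_order)
        self.accuracy_per_size_ = np.asarray(curve.accuracy_per_size)
        summary = summarize_curve(curve)
        self.best_size_ = summary.size_at_max
        self.summary_ = summary
        return self

    def transform(self, X):
        cols = self.membership_order_[: self.best_size_]
        return np.asarray(X, dtype=float)[:, cols]

    def get_support(self, indices: bool = False):
        cols = self.membership_order_[: self.best_size_]
        if indices:
            return np.asarray(cols)
        mask = np.zeros(len(self.membership_order_), dtype=bool)
        mask[np.asarray(cols)] = True
        return mask
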