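"""Balanced, cross-validated linear decoding of binary trial labels.

The decoding kernel: trials are balanced across the four location x direction
conditions by subsampling to the minimum condition count (repeated
``n_balance_repeats`` times), each balanced set is split into stratified
folds, and an L2-regularized linear SVM (liblinear) is trained on 90% and
tested on 10% of trials (10-fold CV by default).  The penalty parameter C is
chosen by a nested grid search inside the training folds only.  Fold plans
are first-class objects so that competing ensemble candidates can be scored
on identical subsamples and splits.

Chance level comes from full trial-label permutations; significance against
chance uses the tie-inclusive add-one permutation p-value, with a binomial
test on held-out counts available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)


@dataclass
class DecoderConfig:
    """Decoding hyperparameters.

    ``label`` names the decoded feature; ``c_grid`` is the penalty grid for
    the liblinear SVM (a single value skips the nested search);
    ``inner_folds`` is the nested CV depth used to pick C.
    """

    label: str = "target_location"
    c_grid: tuple = DEFAULT_C_GRID
    n_folds: int = 10
    n_balance_repeats: int = 10
    inner_folds: int = 5
    seed: int = 0

    def validate(self) -> "DecoderConfig":
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise ValueError("c_grid must be non-empty with positive values")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_balance_repeats < 1:
            raise ValueError("n_balance_repeats must be >= 1")
        return self


@dataclass
class FoldPlan:
    """Balanced subsamples and stratified fold assignments, reusable across
    candidate unit sets so comparisons reflect composition only."""

    repeats: list  # list of (indices, fold_id) pairs of equal-length arrays
    n_folds: int

    def to_dict(self) -> dict:
        return {"n_folds": self.n_folds,
                "repeats": [{"indices": idx.tolist(), "fold_id": fid.tolist()}
                            for idx, fid in self.repeats]}

    @classmethod
    def from_dict(cls, d: dict) -> "FoldPlan":
        return cls([(np.asarray(r["indices"]), np.asarray(r["fold_id"]))
                    for r in d["repeats"]], d["n_folds"])


@dataclass
class CVAccuracy:
    """Cross-validated accuracy of one decoder evaluation."""

    mean_accuracy: float
    fold_accuracies: np.ndarray
    n_per_class: dict
    chosen_C: list
    plan: FoldPlan

    @property
    def dispersion(self) -> float:
        return float(self.fold_accuracies.std(ddof=1)) \
            if len(self.fold_accuracies) > 1 else 0.0


def balanced_subsample(condition_labels: np.ndarray,
                       rng: np.random.Generator | int) -> np.ndarray:
    """Trial indices balanced across unique conditions.

    Every condition contributes exactly the minimum per-condition count,
    sampled without replacement.  Returns sorted indices.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    condition_labels = np.asarray(condition_labels)
    conds, counts = np.unique(condition_labels, return_counts=True)
    if counts.min() == 0 or len(conds) == 0:
        raise ValueError("a condition has no trials")
    m = int(counts.min())
    picked = []
    for c in conds:
        idx = np.flatnonzero(condition_labels == c)
        picked.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(picked))


def build_fold_plan(condition_labels: np.ndarray, y: np.ndarray,
                    config: DecoderConfig,
                    seed: int | None = None) -> FoldPlan:
    """Balanced subsamples plus stratified fold assignments for each repeat."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    y = np.asarray(y)
    repeats = []
    for _ in range(config.n_balance_repeats):
        idx = balanced_subsample(condition_labels, rng)
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        fold_id = np.empty(len(idx), dtype=int)
        for f, (_, test) in enumerate(skf.split(np.zeros(len(idx)), y[idx])):
            fold_id[test] = f
        repeats.append((idx, fold_id))
    return FoldPlan(repeats, config.n_folds)


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float) -> LinearSVC:
    clf = LinearSVC(C=C, penalty="l2", loss="squared_hinge", dual=False,
                    tol=1e-4, max_iter=5000)
    clf.fit(X, y)
    return clf


def _select_C(X: np.ndarray, y: np.ndarray, config: DecoderConfig,
              rng: np.random.Generator) -> float:
    """Inner stratified grid search over C on training data only."""
    if len(config.c_grid) == 1:
        return float(config.c_grid[0])
    n_inner = min(config.inner_folds, int(np.bincount(
        np.unique(y, return_inverse=True)[1]).min()))
    if n_inner < 2:
        return float(np.median(config.c_grid))
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True,
                          random_state=int(rng.integers(0, 2**31 - 1)))
    splits = list(skf.split(X, y))
    best_C, best_acc = None, -1.0
    for C in sorted(config.c_grid):
        correct = total = 0
        for tr, va in splits:
            clf = _fit_svc(X[tr], y[tr], C)
            correct += int((clf.predict(X[va]) == y[va]).sum())
            total += len(va)
        acc = correct / total
        if acc > best_acc + 1e-12:  # ties keep the smaller C
            best_acc, best_C = acc, C
    return float(best_C)


def cv_accuracy(X: np.ndarray, y: np.ndarray, config: DecoderConfig,
                condition_labels: np.ndarray | None = None,
                plan: FoldPlan | None = None) -> CVAccuracy:
    """Balanced, stratified, cross-validated accuracy of the linear SVM.

    When ``plan`` is given, its subsamples and fold assignments are reused
    exactly; otherwise a plan is built from ``condition_labels`` (falling
    back to the class labels) and the config seed.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels are degenerate (single class)")
    if plan is None:
        if condition_labels is None:
            condition_labels = y
        plan = build_fold_plan(condition_labels, y, config)

    rng = np.random.default_rng(config.seed + 1)
    fold_accs, chosen = [], []
    correct_total = tested_total = 0
    for idx, fold_id in plan.repeats:
        Xr, yr = X[idx], y[idx]
        for f in range(plan.n_folds):
            test = fold_id == f
            train = ~test
            if len(np.unique(yr[train])) < 2 or not test.any():
                continue
            C = _select_C(Xr[train], yr[train], config, rng)
            clf = _fit_svc(Xr[train], yr[train], C)
            pred = clf.predict(Xr[test])
            n_ok = int((pred == yr[test]).sum())
            fold_accs.append(n_ok / int(test.sum()))
            chosen.append(C)
            correct_total += n_ok
            tested_total += int(test.sum())
    if tested_total == 0:
        raise ValueError("no testable folds")
    n_per_class = {str(c): int((y == c).sum()) for c in classes}
    return CVAccuracy(correct_total / tested_total, np.asarray(fold_accs),
                      n_per_class, chosen, plan)


def shuffled_label_accuracy(X: np.ndarray, y: np.ndarray, config: DecoderConfig,
                            n_shuffles: int,
                            condition_labels: np.ndarray | None = None,
                            seed: int | None = None) -> list:
    """Null accuracies from full trial-order randomizations.

    Each shuffle permutes the label rows (class label together with its
    condition label) relative to the counts and re-runs the balanced CV with
    a fresh plan.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    y = np.asarray(y)
    if condition_labels is None:
        condition_labels = y
    condition_labels = np.asarray(condition_labels)
    out = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(y))
        cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        res = cv_accuracy(X, y[perm], cfg, condition_labels=condition_labels[perm])
        out.append(res.mean_accuracy)
    return out


def permutation_p(observed: float, null_values: Sequence[float]) -> float:
    """One-sided, tie-inclusive, add-one permutation p-value."""
    null_values = np.asarray(list(null_values), dtype=float)
    if null_values.size == 0:
        raise ValueError("null_values must be non-empty")
    return float((1 + int((null_values >= observed).sum())) / (1 + null_values.size))


def binomial_p(n_correct: int, n_total: int, chance: float = 0.5) -> float:
    """One-sided binomial test of held-out correct counts above chance."""
    return float(stats.binomtest(n_correct, n_total, chance,
                                 alternative="greater").pvalue)


class TunedLinearSVC(BaseEstimator, ClassifierMixin):
    """L2-regularized linear SVM with nested selection of the penalty C.

    A scikit-learn-compatible classifier: ``fit`` runs a stratified inner
    grid search over ``c_grid`` (skipped for a single value), refits on the
    full training data at the selected penalty, and exposes ``best_C_``,
    ``coef_`` and ``intercept_``.
    """

    def __init__(self, c_grid: tuple = DEFAULT_C_GRID, inner_folds: int = 5,
                 seed: int = 0):
        self.c_grid = c_grid
        self.inner_folds = inner_folds
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need two classes")
        cfg = DecoderConfig(c_grid=tuple(self.c_grid),
                            inner_folds=self.inner_folds, seed=self.seed)
        rng = np.random.default_rng(self.seed)
        self.best_C_ = _select_C(X, y, cfg, rng)
        self._clf = _fit_svc(X, y, self.best_C_)
        self.coef_ = self._clf.coef_
        self.intercept_ = self._clf.intercept_
        return self

    def predict(self, X):
        return self._clf.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        return self._clf.decision_function(np.asarray(X, dtype=float))
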