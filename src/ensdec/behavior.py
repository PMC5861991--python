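"""Outcome-conditioned decoding from the best ensemble.

Decoding accuracy is compared across behavioral outcome subsets: all
completed trials, hits only, errors (misses plus false alarms), and false
positives (false alarms) only.  The two large subsets are scored with
unbalanced 10-fold CV; the small error subsets are scored by training one
classifier on all hit trials and testing on the subset (the error pools are
too small to cross-validate or balance).  Scoring labels are always the
nominal trial condition, regardless of where the animal's attention actually
was, so a decoder tracking the internal attention state scores at or below
chance on error trials.  Chance is assessed with exact (permutation) tests
from 100 test-label shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import Session, POSTCUE_WINDOW, extract_counts
from .decoder import DecoderConfig, permutation_p, _select_C, _fit_svc

SUBSETS = ("all", "hits", "errors", "false_positives")
_SUBSET_OUTCOMES = {
    "all": {"hit", "miss", "false_alarm"},
    "hits": {"hit"},
    "errors": {"miss", "false_alarm"},
    "false_positives": {"false_alarm"},
}


@dataclass
class OutcomeDecodingResult:
    """Decoding accuracy and its permutation null for one outcome subset."""

    subset: str
    n_trials: int
    n_per_class: dict
    accuracy: float | None
    null_accuracies: list
    p: float | None
    testable: bool
    protocol: str  # "cv" | "train_hits_test_subset"

    def to_dict(self) -> dict:
        return {"subset": self.subset, "n_trials": self.n_trials,
                "n_per_class": self.n_per_class, "accuracy": self.accuracy,
                "null_accuracies": [float(a) for a in self.null_accuracies],
                "p": self.p, "testable": self.testable, "protocol": self.protocol}


def _unbalanced_cv_accuracy(X: np.ndarray, y: np.ndarray, config: DecoderConfig,
                            rng: np.random.Generator) -> float:
    """Stratified k-fold CV without trial balancing or subsample repeats."""
    n_folds = min(config.n_folds, int(np.unique(y, return_counts=True)[1].min()))
    if n_folds < 2:
        raise ValueError("too few trials per class to cross-validate")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(0, 2**31 - 1)))
    correct = total = 0
    for train, test in skf.split(X, y):
        C = _select_C(X[train], y[train], config, rng)
        clf = _fit_svc(X[train], y[train], C)
        correct += int((clf.predict(X[test]) == y[test]).sum())
        total += len(test)
    return correct / total


def outcome_conditioned_decoding(session: Session, best_be_membership,
                                 label: str, config: DecoderConfig,
                                 n_shuffles: int = 100, seed: int = 0,
                                 window=POSTCUE_WINDOW) -> list:
    """Decode ``label`` from the best-ensemble units within outcome subsets.

    ``all`` and ``hits`` are scored with (unbalanced) stratified CV, with
    chance from ``n_shuffles`` full label shuffles re-running the CV.
    ``errors`` and ``false_positives`` are scored by a classifier trained on
    all hit trials; chance there shuffles the test labels only (predictions
    are fixed).  With ``n_shuffles=0`` accuracies are reported without p.
    """
    rng = np.random.default_rng(seed)
    membership = list(best_be_membership)
    results = []

    cm_all = extract_counts(session, window,
                            include_outcomes={"hit", "miss", "false_alarm"})
    cm_all = cm_all.restrict_units(membership)
    outcomes = cm_all.labels["outcome"].to_numpy()
    X_full = cm_all.counts.astype(float)
    y_full = cm_all.binary_labels(label)

    hit_mask = outcomes == "hit"
    for subset in SUBSETS:
        mask = np.isin(outcomes, sorted(_SUBSET_OUTCOMES[subset]))
        Xs, ys = X_full[mask], y_full[mask]
        classes, counts = np.unique(ys, return_counts=True)
        n_per_class = {str(c): int(k) for c, k in zip(classes, counts)}
        if len(classes) < 2:
            results.append(OutcomeDecodingResult(
                subset, int(mask.sum()), n_per_class, None, [], None,
                testable=False,
                protocol="cv" if subset in ("all", "hits") else
                "train_hits_test_subset"))
            continue

        if subset in ("all", "hits"):
            acc = _unbalanced_cv_accuracy(Xs, ys, config, rng)
            null = []
            for _ in range(n_shuffles):
                perm = rng.permutation(len(ys))
                null.append(_unbalanced_cv_accuracy(Xs, ys[perm], config, rng))
            protocol = "cv"
        else:
            X_tr, y_tr = X_full[hit_mask], y_full[hit_mask]
            if len(np.unique(y_tr)) < 2:
                results.append(OutcomeDecodingResult(
                    subset, int(mask.sum()), n_per_class, None, [], None,
                    testable=False, protocol="train_hits_test_subset"))
                continue
            C = _select_C(X_tr, y_tr, config, rng)
            clf = _fit_svc(X_tr, y_tr, C)
            pred = clf.predict(Xs)
            acc = float((pred == ys).mean())
            null = []
            for _ in range(n_shuffles):
                perm = rng.permutation(len(ys))
                null.append(float((pred == ys[perm]).mean()))
            protocol = "train_hits_test_subset"

        p = permutation_p(acc, null) if null else None
        results.append(OutcomeDecodingResult(subset, int(mask.sum()),
                                             n_per_class, float(acc), null, p,
                                             testable=True, protocol=protocol))
    return results
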