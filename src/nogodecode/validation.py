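"""Generalization checks for the selected features.

The verification protocol holds out 30% of the subjects: features are
selected (t-filter + SFFS with k-fold SVM) on the 70% training set only,
an SVM trained on the training set is then scored once on the validation
set for each cumulative feature count, a label-permutation test (default
1000 reshuffles preserving group sizes) quantifies how often the real
labels are predicted better than random ones, and a feature-omission
ablation re-runs the whole selection on the remaining columns to check
that accuracy collapses to chance without the selected features.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureBank
from .selection import (SelectionConfig, SelectionResult, draw_folds,
                        make_svm, sffs, ttest_filter)


def split_train_validation(labels: np.ndarray, frac: float = 0.7,
                           seed: int = 0):
    """Stratified disjoint train/validation partition.

    The training set has floor(frac * N) subjects overall, allocated per
    group by largest-remainder rounding so both groups appear on both
    sides.  Returns (train_idx, val_idx), each sorted.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    labels = np.asarray(labels)
    n = len(labels)
    target = int(np.floor(frac * n))
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    quota = {}
    remainders = []
    total = 0
    for c in classes:
        exact = frac * np.sum(labels == c)
        quota[c] = int(np.floor(exact))
        total += quota[c]
        remainders.append((exact - quota[c], c))
    for _, c in sorted(remainders, reverse=True)[: target - total]:
        quota[c] += 1
    train = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if quota[c] < 1 or quota[c] >= len(idx):
            raise ValueError(f"group {c} would be absent from one side")
        train.extend(rng.permutation(idx)[: quota[c]])
    train = np.sort(np.asarray(train))
    val = np.setdiff1d(np.arange(n), train)
    assert len(train) + len(val) == n and not np.intersect1d(train, val).size
    return train, val


def validate_features(values: np.ndarray, labels: np.ndarray,
                      train_idx: np.ndarray, val_idx: np.ndarray,
                      ordered_features, cfg: SelectionConfig) -> list[float]:
    """Validation-set accuracy for each cumulative feature count.

    The SVM is fit on the training subjects only and scored once on the
    validation subjects, for features[:1], features[:2], ...
    """
    ordered = [int(c) for c in ordered_features]
    if not ordered:
        raise ValueError("no selected features to validate")
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and validation sets overlap")
    out = []
    for s in range(1, len(ordered) + 1):
        cols = ordered[:s]
        clf = make_svm(cfg).fit(values[np.ix_(train_idx, cols)],
                                labels[train_idx])
        acc = float(np.mean(clf.predict(values[np.ix_(val_idx, cols)])
                            == labels[val_idx]))
        out.append(acc)
    return out


def permutation_test(values: np.ndarray, labels: np.ndarray,
                     train_idx: np.ndarray, val_idx: np.ndarray,
                     feature_cols, real_accuracy: float,
                     n_perm: int = 1000, seed: int = 0,
                     cfg: SelectionConfig = SelectionConfig()) -> float:
    """Label-permutation null for the already-selected features.

    Each permutation reassigns the group labels over all subjects
    (preserving group sizes exactly), trains the SVM on the training
    subjects and scores it on the validation subjects.  Returns the
    percentage of permutations in which the real-label accuracy strictly
    exceeds the permuted-label accuracy (ties count as not-better).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cols = [int(c) for c in np.atleast_1d(feature_cols)]
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    x_tr = values[np.ix_(train_idx, cols)]
    x_va = values[np.ix_(val_idx, cols)]
    better = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        y = labels[perm]
        clf = make_svm(cfg).fit(x_tr, y[train_idx])
        acc = float(np.mean(clf.predict(x_va) == y[val_idx]))
        if real_accuracy > acc:
            better += 1
    return 100.0 * better / n_perm


def ablation(bank_values: np.ndarray, labels: np.ndarray,
             removed_cols, train_idx: np.ndarray, val_idx: np.ndarray,
             cfg: SelectionConfig, pvalue_floor_alpha: float | None = None,
             max_features: int = 1):
    """Accuracy without the given feature columns.

    The removed columns are dropped and the full protocol (t-filter +
    SFFS on the training set, SVM validation-set scoring) is re-run on
    the remainder.  Returns (validation accuracy of the best remaining
    feature set, SelectionResult or None if nothing survives the filter).
    """
    removed = np.unique(np.atleast_1d(removed_cols).astype(int))
    keep = np.setdiff1d(np.arange(bank_values.shape[1]), removed)
    if len(keep) == 0:
        raise ValueError("no features remain after ablation")
    values = bank_values[:, keep]
    labels = np.asarray(labels)
    cand, pvals = ttest_filter(values[train_idx], labels[train_idx],
                               pvalue_floor_alpha or cfg.filter_alpha,
                               cfg.equal_var)
    if len(cand) == 0:
        # nothing discriminative left: score the single least-null column
        cand = np.asarray([int(np.argmin(pvals))])
    folds = draw_folds(labels[train_idx], cfg)
    result = sffs(values[train_idx], labels[train_idx], cand, pvals, cfg,
                  folds=folds, max_features=max_features)
    acc = validate_features(values, labels, train_idx, val_idx,
                            result.ordered_features[:max_features], cfg)[-1]
    return acc, result


@dataclass
class ValidationReport:
    """Per cumulative feature count: training (k-fold CV) accuracy,
    validation accuracy, permutation exceedance % and ablation accuracy."""

    n_train: int
    n_validation: int
    seed: int
    mode: str
    feature_numbers: list[int]
    training_accuracy: list[float]
    validation_accuracy: list[float]
    permutation_better_pct: list[float]
    ablation_accuracy: list[float]
    selected_columns: list[int]
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_features": self.feature_numbers,
            "accuracy_training": self.training_accuracy,
            "accuracy_validation": self.validation_accuracy,
            "pct_better_than_random": self.permutation_better_pct,
            "accuracy_without_selected": self.ablation_accuracy,
        })

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls(**json.loads(text))


def run_validation(bank: FeatureBank, labels: np.ndarray,
                   cfg: SelectionConfig, frac: float = 0.7,
                   n_perm: int = 1000, max_features: int | None = None,
                   seed: int | None = None, do_ablation: bool = True,
                   mode: str = "paper") -> tuple[ValidationReport, SelectionResult]:
    """End-to-end verification on one feature bank.

    Selection (filter + SFFS, k-fold SVM) runs on the training subjects
    only; every reported accuracy is computed on the held-out validation
    subjects.  The ablation column removes all columns selected at any
    step and re-runs the protocol on the remainder.
    """
    seed = cfg.seed if seed is None else seed
    labels = np.asarray(labels)
    train_idx, val_idx = split_train_validation(labels, frac, seed)
    values = bank.values
    cand, pvals = ttest_filter(values[train_idx], labels[train_idx],
                               cfg.filter_alpha, cfg.equal_var)
    if len(cand) == 0:
        cand = np.asarray([int(np.argmin(pvals))])
    folds = draw_folds(labels[train_idx], cfg)
    sel = sffs(values[train_idx], labels[train_idx], cand, pvals, cfg,
               folds=folds, max_features=max_features)
    train_acc, val_acc, perm, abl = [], [], [], []
    for step in sel.steps:
        cols = list(step.subset)
        clf = make_svm(cfg).fit(values[np.ix_(train_idx, cols)],
                                labels[train_idx])
        acc = float(np.mean(clf.predict(values[np.ix_(val_idx, cols)])
                            == labels[val_idx]))
        train_acc.append(step.mean_accuracy)
        val_acc.append(acc)
        if n_perm >= 1:
            perm.append(permutation_test(values, labels, train_idx, val_idx,
                                         cols, acc, n_perm,
                                         seed + 1000 + step.size, cfg))
        else:
            perm.append(float("nan"))
        if do_ablation:
            acc_without, _ = ablation(values, labels, cols, train_idx,
                                      val_idx, cfg)
            abl.append(acc_without)
        else:
            abl.append(float("nan"))
    report = ValidationReport(
        n_train=len(train_idx), n_validation=len(val_idx), seed=seed,
        mode=mode, feature_numbers=[s.size for s in sel.steps],
        training_accuracy=train_acc, validation_accuracy=val_acc,
        permutation_better_pct=perm, ablation_accuracy=abl,
        selected_columns=[int(c) for c in sel.ordered_features])
    return report, sel
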