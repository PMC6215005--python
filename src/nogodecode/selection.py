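"""Hybrid filter-wrapper feature selection with an RBF-SVM evaluator.

A two-sample t-test screens every candidate column (keep p < 0.01); the
survivors enter sequential floating forward selection (SFFS) whose
subset evaluator is the stratified k-fold (k = 10) cross-validated
accuracy of a support vector machine with a radial basis function
kernel, K(x, y) = exp(-||x - y||^2 / (2 sigma^2)), sigma = 5.  Per-step
uncertainty is summarized by Student-t 99% confidence bounds over the k
fold accuracies; two steps (or two analyses) differ significantly when
those bounds do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    filter_alpha: float = 0.01
    k_folds: int = 10
    max_features: int = 20
    svm_sigma: float = 5.0
    svm_cost: float = 1.0
    ci_level: float = 0.99
    equal_var: bool = False     # Welch t-test by default
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.filter_alpha < 1:
            raise ValueError("filter_alpha must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.svm_sigma <= 0 or self.svm_cost <= 0:
            raise ValueError("svm_sigma and svm_cost must be positive")

    @property
    def gamma(self) -> float:
        """RBF gamma such that K = exp(-gamma ||x-y||^2) = exp(-||x-y||^2
        / (2 sigma^2))."""
        return 1.0 / (2.0 * self.svm_sigma**2)


def make_svm(cfg: SelectionConfig) -> SVC:
    return SVC(C=cfg.svm_cost, kernel="rbf", gamma=cfg.gamma)


def ttest_filter(values: np.ndarray, labels: np.ndarray,
                 alpha: float = 0.01, equal_var: bool = False):
    """Column-wise two-sample t-test between the groups; a column is a
    candidate iff p < alpha (strict).  Returns (candidate indices sorted
    by ascending p, p-values for all columns)."""
    labels = np.asarray(labels)
    g0, g1 = values[labels == 0], values[labels == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 subjects")
    res = stats.ttest_ind(g0, g1, axis=0, equal_var=equal_var)
    pvals = np.asarray(res.pvalue)
    candidates = np.flatnonzero(pvals < alpha)
    return candidates[np.argsort(pvals[candidates], kind="stable")], pvals


def draw_folds(labels: np.ndarray, cfg: SelectionConfig):
    """Stratified k-fold partition drawn once from the seed; every subject
    is tested exactly once.  Folds with a single class trigger a logged
    re-draw (cannot happen under stratification unless a class is tiny)."""
    labels = np.asarray(labels)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True,
                              random_state=(cfg.seed + attempt) % 2**31)
        folds = list(skf.split(np.zeros(len(labels)), labels))
        if all(len(np.unique(labels[tr])) == 2 for tr, _ in folds):
            if attempt:
                logger.warning("re-drew folds %d time(s)", attempt)
            return folds
    raise ValueError("cannot draw folds with both classes in every fold")


def svm_cv_accuracy(values: np.ndarray, labels: np.ndarray,
                    cfg: SelectionConfig, folds=None) -> dict:
    """k-fold cross-validated SVM accuracy on the given feature columns.

    Returns fold accuracies, their mean, and classwise accuracy pooled
    over test folds.
    """
    if values.ndim != 2 or values.shape[1] == 0:
        raise ValueError("need a non-empty 2-D feature subset")
    labels = np.asarray(labels)
    if folds is None:
        folds = draw_folds(labels, cfg)
    fold_acc = np.empty(len(folds))
    pred = np.empty(len(labels), dtype=int)
    for i, (tr, te) in enumerate(folds):
        clf = make_svm(cfg).fit(values[tr], labels[tr])
        p = clf.predict(values[te])
        pred[te] = p
        fold_acc[i] = float(np.mean(p == labels[te]))
    classwise = {int(c): float(np.mean(pred[labels == c] == c))
                 for c in np.unique(labels)}
    return {"fold_accuracies": fold_acc, "mean_accuracy": float(fold_acc.mean()),
            "classwise_accuracy": classwise}


def confidence_bounds(fold_accuracies, level: float = 0.99):
    """Student-t confidence interval for the mean of the k fold accuracies:
    mean ± t_{(1+level)/2, k-1} * sd / sqrt(k)."""
    acc = np.asarray(fold_accuracies, dtype=float)
    if len(acc) < 2:
        raise ValueError("need at least 2 fold accuracies")
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    if sd == 0.0:
        return (mean, mean)
    half = float(stats.t.ppf((1.0 + level) / 2.0, len(acc) - 1)
                 * sd / np.sqrt(len(acc)))
    return (mean - half, mean + half)


def bounds_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True (significant difference) iff the closed intervals are disjoint;
    intervals touching at an endpoint overlap and are not significant."""
    return a[1] < b[0] or b[1] < a[0]


@dataclass
class SelectionStep:
    size: int
    subset: tuple[int, ...]           # column indices, in addition order
    fold_accuracies: np.ndarray
    mean_accuracy: float
    ci: tuple[float, float]
    classwise_accuracy: dict
    added: int                        # column added (or swapped in) this size


@dataclass
class SelectionResult:
    steps: list[SelectionStep]
    ordered_features: list[int]       # first feature, second feature, ...
    pvalues: np.ndarray               # filter p-values of all columns
    n_candidates: int
    config: SelectionConfig
    n_evaluations: int = 0
    table: pd.DataFrame | None = field(default=None, repr=False)

    def best_of_size(self, size: int) -> SelectionStep:
        return self.steps[size - 1]


def _evaluate(cache, values, labels, cfg, folds, subset):
    key = frozenset(subset)
    if key not in cache:
        cache[key] = svm_cv_accuracy(values[:, list(subset)], labels, cfg,
                                     folds)
        cache["__n__"] = cache.get("__n__", 0) + 1
    return cache[key]


def _pick_best(scores, pvalues, columns):
    """Argmax mean accuracy; ties broken by smaller filter p-value, then
    by column order (determinism)."""
    order = sorted(range(len(columns)),
                   key=lambda i: (-scores[i], pvalues[columns[i]], columns[i]))
    return order[0]


def sffs(values: np.ndarray, labels: np.ndarray, candidates,
         pvalues: np.ndarray, cfg: SelectionConfig,
         folds=None, max_features: int | None = None) -> SelectionResult:
    """Sequential floating forward selection over the candidate columns.

    Forward steps add the candidate maximizing the cross-validated SVM
    accuracy; after each addition, backward (floating) steps remove any
    member whose exclusion strictly improves the best accuracy known for
    the smaller size.  The best subset per size is recorded up to
    ``max_features``.  Fold assignment is drawn once per run, so the
    procedure is deterministic given the seed.
    """
    candidates = [int(c) for c in np.asarray(candidates).ravel()]
    if len(candidates) == 0:
        raise ValueError("no candidate features")
    labels = np.asarray(labels)
    if folds is None:
        folds = draw_folds(labels, cfg)
    max_features = min(max_features or cfg.max_features, len(candidates))
    cache: dict = {}
    best: dict[int, tuple[tuple[int, ...], dict]] = {}

    def record(subset: tuple[int, ...], res: dict):
        size = len(subset)
        if size not in best or res["mean_accuracy"] > best[size][1]["mean_accuracy"]:
            best[size] = (subset, res)

    current: tuple[int, ...] = ()
    while len(current) < max_features:
        remaining = [c for c in candidates if c not in current]
        if not remaining:
            break
        results = [_evaluate(cache, values, labels, cfg, folds, current + (c,))
                   for c in remaining]
        scores = [r["mean_accuracy"] for r in results]
        i = _pick_best(scores, pvalues, remaining)
        current = current + (remaining[i],)
        record(current, results[i])
        # floating backward steps
        while len(current) > 2:
            subs = [tuple(x for x in current if x != r) for r in current]
            res_b = [_evaluate(cache, values, labels, cfg, folds, s)
                     for s in subs]
            sc = [r["mean_accuracy"] for r in res_b]
            j = int(np.argmax(sc))
            size_down = len(current) - 1
            if size_down in best and sc[j] > best[size_down][1]["mean_accuracy"]:
                current = subs[j]
                record(current, res_b[j])
            else:
                break

    steps = []
    prev: tuple[int, ...] = ()
    ordered: list[int] = []
    for size in sorted(best):
        subset, res = best[size]
        new = [c for c in subset if c not in prev]
        added = new[0] if new else subset[-1]
        for c in subset:
            if c not in ordered:
                ordered.append(c)
        steps.append(SelectionStep(
            size, subset, res["fold_accuracies"], res["mean_accuracy"],
            confidence_bounds(res["fold_accuracies"], cfg.ci_level),
            res["classwise_accuracy"], added))
        prev = subset
    return SelectionResult(steps, ordered, np.asarray(pvalues),
                           len(candidates), cfg,
                           n_evaluations=cache.get("__n__", 0))


def exhaustive_best_subsets(values, labels, candidates, cfg, folds=None,
                            max_size: int | None = None) -> dict[int, tuple]:
    """Independent oracle: evaluate every subset of the candidates and
    return the best (subset, mean accuracy) per size.  Exponential in the
    number of candidates — use only with a handful of columns."""
    from itertools import combinations

    candidates = [int(c) for c in np.asarray(candidates).ravel()]
    if len(candidates) > 12:
        raise ValueError("exhaustive search limited to <= 12 candidates")
    labels = np.asarray(labels)
    if folds is None:
        folds = draw_folds(labels, cfg)
    max_size = max_size or len(candidates)
    out = {}
    for size in range(1, max_size + 1):
        scored = []
        for subset in combinations(candidates, size):
            res = svm_cv_accuracy(values[:, list(subset)], labels, cfg, folds)
            scored.append((res["mean_accuracy"], subset))
        acc, subset = max(scored, key=lambda t: t[0])
        out[size] = (subset, acc)
    return out


def selection_table(result: SelectionResult, descriptors: pd.DataFrame) -> pd.DataFrame:
    """Summary table: feature number, electrode, [Hz,] time point (ms),
    mean predictability, p-value — one row per selected feature."""
    rows = []
    for step in result.steps:
        col = step.added
        d = descriptors.iloc[col]
        row = {"feature_number": step.size, "electrode": d["channel"]}
        if not pd.isna(d["freq_hz"]):
            row["freq_hz"] = float(d["freq_hz"])
        row["time_point_ms"] = float(d["time_ms"])
        row["mean_predictability"] = step.mean_accuracy
        row["p_value"] = float(result.pvalues[col])
        rows.append(row)
    return pd.DataFrame(rows)
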