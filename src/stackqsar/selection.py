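"""Two-step feature selection over probabilistic-feature columns.

Step one ranks PF columns by random-forest importance (Gini impurity
decrease by default; permutation importance available). Step two scores an
SVM on each top-m prefix of the ranking (m over an arithmetic grid) by
stratified k-fold cross-validated MCC — one shared fold plan across all m,
so differences reflect the feature sets and not fold luck — and keeps the
m with the highest MCC, breaking ties toward the smaller (more
parsimonious) subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .metrics import mcc


@dataclass(frozen=True)
class SelectionGrid:
    """Arithmetic grid of candidate subset sizes: m_start, m_start+s, … ≤ m_end."""

    m_start: int = 5
    m_end: int = 70
    s: int = 5

    def __post_init__(self) -> None:
        if self.m_start < 1 or self.s < 1 or self.m_end < self.m_start:
            raise ValueError(f"invalid selection grid {self}")

    @property
    def n(self) -> int:
        return (self.m_end - self.m_start) // self.s + 1


def candidate_sizes(grid: SelectionGrid, n_features: int | None = None) -> list[int]:
    """The m values of the grid, clipped (with a warning) to the feature count."""
    sizes = list(range(grid.m_start, grid.m_end + 1, grid.s))
    if n_features is not None and sizes and sizes[-1] > n_features:
        warnings.warn(
            f"selection grid m_end={grid.m_end} exceeds feature count {n_features}; clipping"
        )
        sizes = [m for m in sizes if m <= n_features]
        if not sizes:
            sizes = [n_features]
    return sizes


@dataclass
class SelectionResult:
    ranking: list[str]
    per_m_mcc: dict[int, float]
    chosen_m: int
    chosen_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chosen_columns:
            self.chosen_columns = self.ranking[: self.chosen_m]


def rank_importance(
    X,
    y,
    column_names: Sequence[str] | None = None,
    seed: int = 0,
    n_trees: int = 500,
    kind: Literal["impurity", "permutation"] = "impurity",
) -> list[str]:
    """Rank feature columns by random-forest importance, descending.

    Ties broken by column order (stable sort). Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    names = list(column_names) if column_names is not None else [str(i) for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("column_names length mismatch")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1).fit(X, y)
    if kind == "impurity":
        importances = rf.feature_importances_
    else:
        importances = permutation_importance(
            rf, X, y, n_repeats=10, random_state=seed, n_jobs=1
        ).importances_mean
    order = np.argsort(-importances, kind="stable")
    return [names[i] for i in order]


def _default_svm(n_features: int, seed: int) -> SVC:
    return SVC(C=1.0, gamma="scale", kernel="rbf", random_state=seed)


def select_opf(
    X,
    y,
    ranking: Sequence[str],
    column_names: Sequence[str],
    grid: SelectionGrid = SelectionGrid(),
    k: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Score each top-m prefix by shared-fold CV MCC of an SVM; keep argmax m.

    The chosen columns are always a prefix of the ranking.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    names = list(column_names)
    index = {name: i for i, name in enumerate(names)}
    missing = [r for r in ranking if r not in index]
    if missing:
        raise ValueError(f"ranking names not found in columns: {missing[:3]}")
    sizes = candidate_sizes(grid, n_features=len(ranking))
    skf = StratifiedKFold(n_splits=min(k, int(np.bincount(y).min())), shuffle=True,
                          random_state=seed)
    folds = list(skf.split(X, y))  # one shared plan across all m
    per_m: dict[int, float] = {}
    for m in sizes:
        cols = [index[name] for name in ranking[:m]]
        Xm = X[:, cols]
        y_pred = np.empty(len(y), dtype=int)
        for tr, te in folds:
            est = _default_svm(m, seed).fit(Xm[tr], y[tr])
            y_pred[te] = est.predict(Xm[te])
        per_m[m] = mcc(y, y_pred)
    chosen_m = max(sizes, key=lambda m: (per_m[m], -m))  # ties → smaller m
    return SelectionResult(ranking=list(ranking), per_m_mcc=per_m, chosen_m=chosen_m)


class PFSelector(BaseEstimator):
    """Sklearn-style transformer wrapping the two-step selection.

    ``fit(X, y)`` ranks columns and searches the m-grid; ``transform(X)``
    keeps the chosen columns. Fitted attributes: ``ranking_``,
    ``per_m_mcc_``, ``chosen_m_``, ``support_`` (boolean column mask),
    ``chosen_columns_``.
    """

    def __init__(self, grid: SelectionGrid = SelectionGrid(), k: int = 10,
                 seed: int = 0, column_names: Sequence[str] | None = None,
                 importance: Literal["impurity", "permutation"] = "impurity"):
        self.grid = grid
        self.k = k
        self.seed = seed
        self.column_names = column_names
        self.importance = importance

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        names = (
            list(self.column_names)
            if self.column_names is not None
            else [str(i) for i in range(X.shape[1])]
        )
        self.ranking_ = rank_importance(X, y, names, seed=self.seed, kind=self.importance)
        result = select_opf(X, y, self.ranking_, names, grid=self.grid, k=self.k, seed=self.seed)
        self.per_m_mcc_ = result.per_m_mcc
        self.chosen_m_ = result.chosen_m
        self.chosen_columns_ = result.chosen_columns
        self.support_ = np.array([name in set(result.chosen_columns) for name in names])
        self._names = names
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
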