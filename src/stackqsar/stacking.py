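"""Stacked generalization: out-of-fold probabilistic features + SVM meta-model.

The first layer trains one grid-tuned classifier per (algorithm,
fingerprint family) cell. Each cell contributes one probabilistic feature
(PF): the out-of-fold P(active) over a shared stratified 10-fold plan, so
no entry of the PF matrix was predicted by a model that saw that row's
label. All PF columns together form the aggregate probabilistic feature
matrix (APF; 72-dimensional at the full 8 algorithms × 9 families
configuration). A two-step random-forest-importance selection reduces the
APF to the optimal PF subset (OPF), on which an RBF-SVM meta-classifier is
grid-tuned and fitted.

For new samples the PFs come from base models refit on the entire training
split (standard stacked-generalization deployment); averaging the ten fold
models instead is available behind ``pf_mode``-style configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .base import (
    ALGORITHMS,
    BaseModelSpec,
    FittedBaseModel,
    enumerate_specs,
    grid_candidates,
    make_estimator,
    tune_and_fit,
)
from .descriptors import FingerprintBlock
from .metrics import MetricsReport, mcc, score_probabilities
from .selection import PFSelector, SelectionGrid

PFMode = Literal["concat", "average"]
PFTuning = Literal["shared", "per_fold"]


@dataclass(frozen=True)
class FoldPlan:
    """Stratified partition of the training rows into k near-equal folds."""

    k: int
    assignment: tuple[int, ...]  # row → fold index 0..k-1
    seed: int

    def indices(self, fold: int) -> np.ndarray:
        a = np.asarray(self.assignment)
        return np.flatnonzero(a == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        a = np.asarray(self.assignment)
        return np.flatnonzero(a != fold)


def make_fold_plan(y, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified fold plan; per-class fold sizes differ by at most one."""
    y = np.asarray(y).astype(int)
    if k > len(y):
        raise ValueError(f"k={k} exceeds n={len(y)}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, te) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[te] = fold
    return FoldPlan(k=k, assignment=tuple(int(a) for a in assignment), seed=seed)


@dataclass
class PFMatrix:
    """n × k_cols matrix of out-of-fold base-classifier probabilities."""

    matrix: np.ndarray
    column_names: list[str]
    fold_plan: FoldPlan

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.column_names):
            raise ValueError("PF matrix / column-name mismatch")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > 1):
            raise ValueError("PF entries must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        index = {n: i for i, n in enumerate(self.column_names)}
        return self.matrix[:, [index[n] for n in names]]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=self.column_names).to_csv(path, index=False)


def out_of_fold_pf(
    spec: BaseModelSpec,
    X,
    y,
    plan: FoldPlan,
    tuned_params: Mapping | None = None,
    mode: PFMode = "concat",
    tuning: PFTuning = "shared",
    return_models: bool = False,
):
    """One PF column: out-of-fold P(active) from the spec's base classifier.

    ``concat`` (default): each row is predicted exactly once, by the fold
    model whose training part excluded it; the ten disjoint fold outputs
    are assembled into one full-length column. ``average``: every fold
    model predicts all rows and the ten outputs are averaged pointwise
    (leaks labels into 9/10 of each row's predictors; kept only for
    comparison with that alternative reading).

    With ``tuning="shared"`` the hyperparameters are tuned once on the full
    training rows and reused across folds; ``per_fold`` re-tunes on each
    fold's own training part.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(X) != len(y) or len(y) != len(plan.assignment):
        raise ValueError("X, y and fold plan are not aligned")
    if tuning == "shared" and tuned_params is None:
        tuned_params = tune_and_fit(spec, X, y, k=plan.k).tuned_params
    pf = np.zeros(len(y), dtype=float)
    acc = np.zeros(len(y), dtype=float) if mode == "average" else None
    models = []
    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.indices(fold)
        if len(np.unique(y[tr])) < 2:  # stratification repair
            warnings.warn(f"fold {fold}: single-class training part; borrowing one row")
            other = np.flatnonzero(y != y[tr[0]])
            tr = np.append(tr, other[0])
        if tuning == "per_fold":
            fbm = tune_and_fit(spec, X[tr], y[tr], k=min(plan.k, 5))
            est = fbm.full_fit
        else:
            est = make_estimator(
                spec.algorithm, dict(tuned_params), X.shape[1], len(tr), spec.seed
            ).fit(X[tr], y[tr])
        if mode == "average":
            acc += np.asarray(est.predict_proba(X))[:, 1]
        else:
            pf[te] = np.asarray(est.predict_proba(X[te]))[:, 1]
        if return_models:
            models.append((fold, tr, est))
    if mode == "average":
        pf = acc / plan.k
    return (pf, models) if return_models else pf


def assemble_apf(columns: Mapping[str, np.ndarray], fold_plan: FoldPlan,
                 order: Sequence[str] | None = None) -> PFMatrix:
    """Stack PF columns into the aggregate PF matrix, fixed column order."""
    names = list(order) if order is not None else list(columns)
    lengths = {len(columns[n]) for n in names}
    if len(lengths) > 1:
        raise ValueError(f"PF columns differ in length: {lengths}")
    (n,) = lengths or {0}
    if n != len(fold_plan.assignment):
        raise ValueError("PF columns do not match the fold plan length")
    matrix = np.column_stack([columns[n_] for n_ in names]) if names else np.empty((n, 0))
    return PFMatrix(matrix=matrix, column_names=names, fold_plan=fold_plan)


DEFAULT_META_GRID: Mapping[str, Sequence[float]] = {
    "C": [0.1, 1.0, 10.0, 100.0],
    "gamma_mult": [1.0, 10.0],  # × 1/k_cols
}


def fit_meta(
    pf: PFMatrix,
    y,
    selected: Sequence[str],
    svm_grid: Mapping[str, Sequence[float]] | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[SVC, dict, float]:
    """Grid-tune the RBF-SVM meta-classifier by CV MCC on the selected PFs.

    Returns (fitted probability-calibrated SVC, tuned params, tuning CV MCC).
    """
    if not list(selected):
        raise ValueError("selected PF column set must be non-empty")
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Xs = pf.columns(list(selected))
    p = Xs.shape[1]
    grid = svm_grid if svm_grid is not None else DEFAULT_META_GRID
    skf = StratifiedKFold(n_splits=min(k, int(np.bincount(y).min())), shuffle=True,
                          random_state=seed)
    folds = list(skf.split(Xs, y))
    best_params, best_score = None, -np.inf
    for cand in grid_candidates(grid):
        gamma = float(cand.get("gamma_mult", 1.0)) / p
        C = float(cand.get("C", 1.0))
        y_pred = np.empty(len(y), dtype=int)
        for tr, te in folds:
            est = SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed).fit(Xs[tr], y[tr])
            y_pred[te] = est.predict(Xs[te])
        score = mcc(y, y_pred)
        if score > best_score:
            best_params, best_score = cand, score
    gamma = float(best_params.get("gamma_mult", 1.0)) / p
    meta = CalibratedClassifierCV(
        SVC(C=float(best_params.get("C", 1.0)), gamma=gamma, kernel="rbf",
            random_state=seed),
        method="sigmoid", cv=5, ensemble=False,
    ).fit(Xs, y)
    return meta, dict(best_params), float(best_score)


def _block_matrix(block) -> np.ndarray:
    if isinstance(block, FingerprintBlock):
        return np.asarray(block.matrix, dtype=float)
    return np.asarray(block, dtype=float)


class StackedEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Two-layer stacked ensemble over fingerprint blocks.

    ``fit`` takes a mapping ``{family name: FingerprintBlock or 2D array}``
    plus binary labels (1 = active); every enabled (algorithm, family) cell
    is grid-tuned, out-of-fold PFs are generated over one shared stratified
    k-fold plan, the PF subset is selected by the two-step procedure, and
    the RBF-SVM meta-classifier is tuned and fitted on the selected
    columns.

    Parameters
    ----------
    algorithms : subset of :data:`stackqsar.base.ALGORITHMS`.
    descriptors : fingerprint family names; default = the keys of the
        blocks passed to ``fit`` (registry order preserved by the caller).
    grids : optional per-algorithm hyperparameter grid overrides.
    k : folds for PF generation, tuning and selection (default 10).
    selection_grid : subset-size grid for the two-step selection.
    meta_grid : C / gamma grid for the meta-SVM.
    pf_mode : "concat" (each row predicted once, out of fold; default) or
        "average" (pointwise mean of all fold models — leaky, comparison
        only).
    pf_tuning : "shared" (tune each cell once on the training split) or
        "per_fold" (re-tune inside every fold).
    random_state : master seed for fold plans and learners.

    Fitted attributes: ``base_models_`` (name → FittedBaseModel),
    ``pf_matrix_`` (the APF), ``selected_columns_`` (the OPF names, ranking
    order), ``selection_`` (fitted PFSelector), ``meta_``,
    ``meta_params_``, ``meta_cv_mcc_``, ``base_cv_reports_``,
    ``fold_plan_``.
    """

    def __init__(
        self,
        algorithms: Sequence[str] = ALGORITHMS,
        descriptors: Sequence[str] | None = None,
        grids: Mapping[str, Mapping[str, Sequence]] | None = None,
        k: int = 10,
        selection_grid: SelectionGrid = SelectionGrid(),
        meta_grid: Mapping[str, Sequence[float]] | None = None,
        pf_mode: PFMode = "concat",
        pf_tuning: PFTuning = "shared",
        random_state: int = 0,
    ):
        self.algorithms = algorithms
        self.descriptors = descriptors
        self.grids = grids
        self.k = k
        self.selection_grid = selection_grid
        self.meta_grid = meta_grid
        self.pf_mode = pf_mode
        self.pf_tuning = pf_tuning
        self.random_state = random_state

    def _resolve_descriptors(self, blocks: Mapping[str, object]) -> list[str]:
        descriptors = list(self.descriptors) if self.descriptors is not None else list(blocks)
        missing = [d for d in descriptors if d not in blocks]
        if missing:
            raise KeyError(f"missing fingerprint blocks for: {missing}")
        return descriptors

    def fit(self, blocks: Mapping[str, object], y):
        y = np.asarray(y).astype(int)
        if y.size == 0:
            raise ValueError("empty training data")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present in y")
        descriptors = self._resolve_descriptors(blocks)
        mats = {d: _block_matrix(blocks[d]) for d in descriptors}
        for d, m in mats.items():
            if m.shape[0] != len(y):
                raise ValueError(f"block {d!r} has {m.shape[0]} rows, y has {len(y)}")
        specs = enumerate_specs(self.algorithms, descriptors, self.grids, seed=self.random_state)
        self.fold_plan_ = make_fold_plan(y, k=self.k, seed=self.random_state)

        self.base_models_: dict[str, FittedBaseModel] = {}
        pf_columns: dict[str, np.ndarray] = {}
        for spec in specs:
            X = mats[spec.descriptor]
            fitted = tune_and_fit(spec, X, y, k=self.k)
            pf_columns[spec.name] = out_of_fold_pf(
                spec, X, y, self.fold_plan_,
                tuned_params=fitted.tuned_params,
                mode=self.pf_mode, tuning=self.pf_tuning,
            )
            fitted.cv_metrics = score_probabilities(y, pf_columns[spec.name])
            self.base_models_[spec.name] = fitted

        self.pf_matrix_ = assemble_apf(
            pf_columns, self.fold_plan_, order=[s.name for s in specs]
        )
        self.base_cv_reports_ = {
            name: m.cv_metrics for name, m in self.base_models_.items()
        }

        self.selection_ = PFSelector(
            grid=self.selection_grid, k=self.k, seed=self.random_state,
            column_names=self.pf_matrix_.column_names,
        ).fit(self.pf_matrix_.matrix, y)
        self.selected_columns_ = list(self.selection_.chosen_columns_)

        self.meta_, self.meta_params_, self.meta_cv_mcc_ = fit_meta(
            self.pf_matrix_, y, self.selected_columns_,
            svm_grid=self.meta_grid, k=self.k, seed=self.random_state,
        )
        self.classes_ = np.array([0, 1])
        return self

    def _new_sample_pfs(self, blocks: Mapping[str, object]) -> np.ndarray:
        """PF columns for new samples from the full-training base models."""
        cols = []
        for name in self.selected_columns_:
            fbm = self.base_models_[name]
            d = fbm.spec.descriptor
            if d not in blocks:
                raise KeyError(f"missing fingerprint block {d!r} required by PF {name}")
            X = _block_matrix(blocks[d])
            cols.append(fbm.full_fit.predict_proba(X)[:, 1])
        return np.column_stack(cols)

    def predict_proba(self, blocks: Mapping[str, object]) -> np.ndarray:
        check_is_fitted(self, "meta_")
        pfs = self._new_sample_pfs(blocks)
        return self.meta_.predict_proba(pfs)

    def predict(self, blocks: Mapping[str, object]) -> np.ndarray:
        return (self.predict_proba(blocks)[:, 1] >= 0.5).astype(int)

    def cv_report(self, y) -> MetricsReport:
        """Cross-validation report of the stacked model: the meta-SVM scored
        on the selected out-of-fold PF columns over a fresh fold plan."""
        check_is_fitted(self, "meta_")
        y = np.asarray(y).astype(int)
        Xs = self.pf_matrix_.columns(self.selected_columns_)
        skf = StratifiedKFold(
            n_splits=min(self.k, int(np.bincount(y).min())), shuffle=True,
            random_state=self.random_state + 1,
        )
        gamma = float(self.meta_params_.get("gamma_mult", 1.0)) / Xs.shape[1]
        oof = np.empty(len(y), dtype=float)
        for tr, te in skf.split(Xs, y):
            est = CalibratedClassifierCV(
                SVC(C=float(self.meta_params_.get("C", 1.0)), gamma=gamma,
                    kernel="rbf", random_state=self.random_state),
                method="sigmoid", cv=5, ensemble=False,
            ).fit(Xs[tr], y[tr])
            oof[te] = est.predict_proba(Xs[te])[:, 1]
        return score_probabilities(y, oof, context="cross_validation")


def fit_stacker(dataset, blocks: Mapping[str, object], config=None, **kwargs) -> StackedEnsembleClassifier:
    """Fit a stacked ensemble on a curated training dataset.

    ``dataset`` is a :class:`~stackqsar.curation.LabeledDataset` whose
    records are the training split; ``blocks`` maps family names to
    row-aligned fingerprint blocks. ``config`` (a mapping) or keyword
    arguments set the estimator parameters.
    """
    params = dict(config or {})
    params.update(kwargs)
    model = StackedEnsembleClassifier(**params)
    model.fit(blocks, dataset.y)
    model.train_ids_ = [r.id for r in dataset.records]
    return model
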