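"""First-layer base classifiers: eight algorithms, grid-tuned per block.

Each base classifier is one learning algorithm trained on one fingerprint
block. Hyperparameters are chosen from a small declared grid by k-fold
cross-validated MCC on the training rows. Wrapped as a scikit-learn
estimator (:class:`BaseBlockClassifier`) so base models compose with
sklearn model selection; the :func:`tune_and_fit` function is a thin
wrapper over it.

Algorithm naming follows the conventions of the R caret ecosystem this
family of QSAR models grew up in: GLM is a binomial logistic regression,
CART ("rpart") a single decision tree, PLS a PLS-DA classifier with
probabilities via a softmax over class scores.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y
from xgboost import XGBClassifier

from .metrics import MetricsReport, mcc, score_probabilities

#: Fixed enumeration order of the eight algorithms (outer order of the APF).
ALGORITHMS = ("RF", "GLM", "SVM", "XGB", "KNN", "PLS", "CART", "MLP")

#: Default hyperparameter grids. Multiplier-style entries are resolved
#: against the block width p at fit time: ``max_features_mult`` scales √p
#: (RF), ``gamma_mult`` scales 1/p (SVM). All overridable via config.
DEFAULT_GRIDS: Mapping[str, dict[str, list]] = {
    "RF": {"max_features_mult": [0.5, 1.0, 2.0]},
    "GLM": {"l2": [0.0, 0.01, 1.0]},
    "SVM": {"C": [0.1, 1.0, 10.0], "gamma_mult": [1.0, 10.0]},
    "XGB": {"max_depth": [3, 6], "learning_rate": [0.1, 0.3]},
    "KNN": {"n_neighbors": [3, 5, 7, 9]},
    "PLS": {"n_components": [2, 4, 8]},
    "CART": {"ccp_alpha": [0.001, 0.01, 0.1]},
    "MLP": {"hidden_size": [5, 10, 20]},
}

#: Fixed (non-gridded) settings.
DEFAULTS: Mapping[str, dict[str, Any]] = {
    "RF": {"n_estimators": 500},
    "XGB": {"n_estimators": 200},
    "MLP": {"max_iter": 400},
}


def default_grid(algorithm: str) -> dict[str, list]:
    """The default hyperparameter grid for one of the eight algorithms."""
    try:
        return {k: list(v) for k, v in DEFAULT_GRIDS[algorithm].items()}
    except KeyError:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; known: {list(ALGORITHMS)}"
        ) from None


def grid_candidates(grid: Mapping[str, Sequence]) -> list[dict]:
    """Cartesian product of a grid in declared key order (ties in tuning
    are broken toward the first candidate in this enumeration)."""
    if not grid:
        raise ValueError("grid must be non-empty")
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


class _ZeroVarianceMasked(BaseEstimator, ClassifierMixin):
    """Drop constant columns before fitting a distance-based learner.

    Degenerate all-constant input keeps the first column and warns rather
    than erroring, so pipelines survive pathological folds.
    """

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        mask = X.std(axis=0) > 0
        if not mask.any():
            warnings.warn("all feature columns are constant; keeping column 0")
            mask[0] = True
        self.mask_ = mask
        self.estimator_ = clone(self.estimator).fit(X[:, mask], y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(np.asarray(X, dtype=float)[:, self.mask_])

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS-DA: PLS regression on one-hot class indicators, probabilities
    via a softmax over the predicted class scores."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("PLS-DA needs two classes")
        Y = np.column_stack([(y == c).astype(float) for c in self.classes_])
        n_comp = max(1, min(self.n_components, X.shape[1], X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=n_comp, scale=False).fit(X, Y)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "pls_")
        scores = self.pls_.predict(np.asarray(X, dtype=float))
        z = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_estimator(
    algorithm: str,
    params: Mapping[str, Any],
    n_features: int,
    n_samples: int,
    random_state: int = 0,
):
    """Instantiate one of the eight learners with grid params resolved
    against the block shape."""
    p = max(1, n_features)
    params = dict(params)
    if algorithm == "RF":
        mult = float(params.pop("max_features_mult", 1.0))
        max_features = int(min(p, max(1, round(mult * math.sqrt(p)))))
        return RandomForestClassifier(
            n_estimators=int(params.pop("n_estimators", DEFAULTS["RF"]["n_estimators"])),
            max_features=max_features,
            random_state=random_state,
            n_jobs=1,
            **params,
        )
    if algorithm == "GLM":
        l2 = float(params.pop("l2", 0.0))
        if l2 > 0:
            return LogisticRegression(C=1.0 / l2, max_iter=2000, **params)
        return LogisticRegression(penalty=None, max_iter=2000, **params)
    if algorithm == "SVM":
        gamma = float(params.pop("gamma_mult", 1.0)) / p
        svc = SVC(
            C=float(params.pop("C", 1.0)),
            gamma=gamma,
            kernel="rbf",
            random_state=random_state,
            **params,
        )
        # Platt-style sigmoid calibration fitted on internal training folds
        return CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    if algorithm == "XGB":
        return XGBClassifier(
            n_estimators=int(params.pop("n_estimators", DEFAULTS["XGB"]["n_estimators"])),
            max_depth=int(params.pop("max_depth", 6)),
            learning_rate=float(params.pop("learning_rate", 0.3)),
            random_state=random_state,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
            **params,
        )
    if algorithm == "KNN":
        k = int(params.pop("n_neighbors", 5))
        k = max(1, min(k, n_samples - 1)) if n_samples > 1 else 1
        return _ZeroVarianceMasked(KNeighborsClassifier(n_neighbors=k, **params))
    if algorithm == "PLS":
        return _ZeroVarianceMasked(
            PLSDAClassifier(n_components=int(params.pop("n_components", 2)))
        )
    if algorithm == "CART":
        return DecisionTreeClassifier(
            ccp_alpha=float(params.pop("ccp_alpha", 0.0)),
            random_state=random_state,
            **params,
        )
    if algorithm == "MLP":
        h = int(params.pop("hidden_size", 10))
        return MLPClassifier(
            hidden_layer_sizes=(h,),
            max_iter=int(params.pop("max_iter", DEFAULTS["MLP"]["max_iter"])),
            random_state=random_state,
            **params,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; known: {list(ALGORITHMS)}")


class BaseBlockClassifier(BaseEstimator, ClassifierMixin):
    """One algorithm on one fingerprint block, grid-tuned by CV MCC.

    Parameters
    ----------
    algorithm : one of :data:`ALGORITHMS`.
    grid : hyperparameter grid (defaults to :func:`default_grid`).
    cv : folds for the tuning cross-validation.
    random_state : seeds the fold plan and every stochastic learner.

    After ``fit``: ``best_params_`` (the tuned grid point), ``cv_mcc_``
    (tuning-CV MCC of the winner; None for a singleton grid, which needs
    no search), ``cv_results_`` (per-candidate MCC), ``estimator_``
    (refit on all rows).
    """

    def __init__(self, algorithm: str = "RF", grid: Mapping[str, Sequence] | None = None,
                 cv: int = 10, random_state: int = 0):
        self.algorithm = algorithm
        self.grid = grid
        self.cv = cv
        self.random_state = random_state

    def _candidate_oof_mcc(self, params, X, y) -> float:
        n_splits = min(self.cv, int(np.bincount(y).min()))
        n_splits = max(2, n_splits)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.random_state)
        oof = np.empty(len(y), dtype=float)
        for tr, te in skf.split(X, y):
            est = make_estimator(self.algorithm, params, X.shape[1], len(tr), self.random_state)
            est.fit(X[tr], y[tr])
            oof[te] = est.predict_proba(X[te])[:, 1]
        return mcc(y, (oof >= 0.5).astype(int))

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = y.astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("both classes must be present in y")
        grid = self.grid if self.grid is not None else default_grid(self.algorithm)
        candidates = grid_candidates(grid)
        if X.std(axis=0).max() == 0:
            warnings.warn("all feature columns constant; fit proceeds but is degenerate")
        if len(candidates) == 1:
            self.best_params_ = candidates[0]
            self.cv_results_ = None
            self.cv_mcc_ = None
        else:
            scores = [self._candidate_oof_mcc(c, X, y) for c in candidates]
            best = int(np.argmax(scores))  # first argmax wins ties
            self.best_params_ = candidates[best]
            self.cv_results_ = list(zip(candidates, scores))
            self.cv_mcc_ = scores[best]
        self.estimator_ = make_estimator(
            self.algorithm, self.best_params_, X.shape[1], X.shape[0], self.random_state
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width mismatch: model expects {self.n_features_in_}, "
                f"got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        if X.shape[0] == 0:
            return np.empty((0, 2))
        return np.asarray(self.estimator_.predict_proba(X))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def cv_report(self, X, y, k: int = 10, seed: int | None = None) -> MetricsReport:
        """Full six-metric CV report for this (tuned) base model."""
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        rs = self.random_state if seed is None else seed
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        oof = np.empty(len(y), dtype=float)
        for tr, te in skf.split(X, y):
            est = make_estimator(self.algorithm, self.best_params_, X.shape[1], len(tr), rs)
            est.fit(X[tr], y[tr])
            oof[te] = est.predict_proba(X[te])[:, 1]
        return score_probabilities(y, oof, context="cross_validation")


@dataclass(frozen=True)
class BaseModelSpec:
    """One (algorithm, descriptor) cell of the base-classifier matrix."""

    algorithm: str
    descriptor: str
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    seed: int = 0

    def resolved_grid(self) -> dict[str, list]:
        return {k: list(v) for k, v in self.grid.items()} if self.grid else default_grid(self.algorithm)

    @property
    def name(self) -> str:
        return f"{self.algorithm}__{self.descriptor}"


@dataclass
class FittedBaseModel:
    spec: BaseModelSpec
    tuned_params: dict
    full_fit: BaseBlockClassifier
    cv_metrics: MetricsReport | None = None


def enumerate_specs(
    algorithms: Sequence[str],
    descriptors: Sequence[str],
    grids: Mapping[str, Mapping[str, Sequence]] | None = None,
    seed: int = 0,
) -> list[BaseModelSpec]:
    """All algorithm × descriptor cells, algorithm-outer, descriptor-inner."""
    grids = grids or {}
    for a in algorithms:
        if a not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {a!r}")
    return [
        BaseModelSpec(algorithm=a, descriptor=d, grid=grids.get(a, {}), seed=seed)
        for a in algorithms
        for d in descriptors
    ]


def tune_and_fit(spec: BaseModelSpec, X, y, k: int = 10, seed: int | None = None) -> FittedBaseModel:
    """Grid-tune one base classifier by k-fold CV MCC and refit on all rows."""
    clf = BaseBlockClassifier(
        algorithm=spec.algorithm,
        grid=spec.resolved_grid(),
        cv=k,
        random_state=spec.seed if seed is None else seed,
    ).fit(np.asarray(X, dtype=float), y)
    return FittedBaseModel(spec=spec, tuned_params=clf.best_params_, full_fit=clf)


def predict_proba(model: FittedBaseModel, X) -> np.ndarray:
    """P(active) per row from a fitted base model."""
    return model.full_fit.predict_proba(np.asarray(X, dtype=float))[:, 1]
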