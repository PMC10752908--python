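"""Binary-classification performance metrics and evaluation harnesses.

Six metrics are reported throughout: accuracy (ACC), balanced accuracy
(BACC), sensitivity (Sn), specificity (Sp), the Matthews correlation
coefficient (MCC) and the area under the ROC curve (AUC, computed as the
rank-based probability that a random active outscores a random inactive,
ties counting one half). The active class is the positive class, and the
classification threshold is fixed at 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    ACC: float
    BACC: float
    Sn: float
    Sp: float
    MCC: float
    AUC: float | None
    counts: ConfusionCounts
    context: Literal["cross_validation", "independent_test"] = "cross_validation"

    def as_dict(self) -> dict[str, float | None]:
        return {
            "ACC": self.ACC,
            "BACC": self.BACC,
            "Sn": self.Sn,
            "Sp": self.Sp,
            "MCC": self.MCC,
            "AUC": self.AUC,
        }


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if y.size and not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1 (1 = active)")
    return y


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard 2×2 confusion counts; active (1) is the positive class."""
    y_true, y_pred = _as_binary(y_true), _as_binary(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Closed-form MCC; 0 by convention when any marginal is empty."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def auc_rank(scores, y_true) -> float:
    """AUC as the normalized Mann–Whitney U statistic (ties count 1/2).

    Invariant under strictly monotone transformations of the scores.
    """
    y_true = _as_binary(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def compute_metrics(
    counts: ConfusionCounts,
    scores=None,
    y_true=None,
    context: Literal["cross_validation", "independent_test"] = "cross_validation",
) -> MetricsReport:
    """Assemble the six-metric report from confusion counts (+ scores for AUC).

    Ratio metrics with an empty denominator are reported as 0; AUC is None
    when scores are not supplied.
    """
    n = counts.n
    acc = (counts.TP + counts.TN) / n if n else 0.0
    sn = counts.TP / (counts.TP + counts.FN) if (counts.TP + counts.FN) else 0.0
    sp = counts.TN / (counts.TN + counts.FP) if (counts.TN + counts.FP) else 0.0
    auc = auc_rank(scores, y_true) if scores is not None else None
    return MetricsReport(
        ACC=acc,
        BACC=(sn + sp) / 2,
        Sn=sn,
        Sp=sp,
        MCC=mcc_from_counts(counts),
        AUC=auc,
        counts=counts,
        context=context,
    )


def score_probabilities(
    y_true, proba, threshold: float = 0.5,
    context: Literal["cross_validation", "independent_test"] = "cross_validation",
) -> MetricsReport:
    """Six-metric report from P(active) scores at a fixed threshold."""
    proba = np.asarray(proba, dtype=float)
    y_pred = (proba >= threshold).astype(int)
    return compute_metrics(confusion(y_true, y_pred), scores=proba, y_true=y_true,
                           context=context)


def mcc(y_true, y_pred) -> float:
    return mcc_from_counts(confusion(y_true, y_pred))


def cross_validate(
    model_builder: Callable[[], "object"],
    X: np.ndarray,
    y,
    k: int = 10,
    seed: int = 0,
    scoring: Literal["pooled", "macro"] = "pooled",
) -> MetricsReport:
    """k-fold cross-validation of a probabilistic classifier.

    ``model_builder`` returns a fresh unfitted estimator exposing
    ``fit(X, y)`` and ``predict_proba(X)`` (two-column, P(active) second).
    Out-of-fold probabilities are pooled over one stratified fold plan and
    scored once (micro-averaging, the default) or scored per fold and
    averaged (``macro``). Deterministic given the seed.
    """
    X = np.asarray(X)
    y = _as_binary(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=float)
    fold_reports = []
    for train_idx, test_idx in skf.split(X, y):
        model = model_builder()
        model.fit(X[train_idx], y[train_idx])
        proba = np.asarray(model.predict_proba(X[test_idx]))[:, 1]
        oof[test_idx] = proba
        if scoring == "macro":
            fold_reports.append(score_probabilities(y[test_idx], proba))
    if scoring == "macro":
        counts = ConfusionCounts(
            TP=sum(r.counts.TP for r in fold_reports),
            TN=sum(r.counts.TN for r in fold_reports),
            FP=sum(r.counts.FP for r in fold_reports),
            FN=sum(r.counts.FN for r in fold_reports),
        )
        return MetricsReport(
            ACC=float(np.mean([r.ACC for r in fold_reports])),
            BACC=float(np.mean([r.BACC for r in fold_reports])),
            Sn=float(np.mean([r.Sn for r in fold_reports])),
            Sp=float(np.mean([r.Sp for r in fold_reports])),
            MCC=float(np.mean([r.MCC for r in fold_reports])),
            AUC=float(np.mean([r.AUC for r in fold_reports])),
            counts=counts,
        )
    return score_probabilities(y, oof, context="cross_validation")


class LeakageError(ValueError):
    """Test records overlap the model's training records."""


def evaluate_independent(model, test_dataset, blocks) -> MetricsReport:
    """Single-pass scoring of a fitted stacked model on a held-out split.

    ``model`` must expose ``predict_proba(blocks)``; if it carries
    ``train_ids_``, disjointness of the test ids is asserted first.
    """
    records = test_dataset.records
    if not records:
        raise ValueError("empty test dataset")
    test_ids = {r.id for r in records}
    train_ids = set(getattr(model, "train_ids_", ()))
    overlap = train_ids & test_ids
    if overlap:
        raise LeakageError(f"test ids overlap training ids: {sorted(overlap)[:5]}")
    proba = np.asarray(model.predict_proba(blocks))[:, 1]
    return score_probabilities(test_dataset.y, proba, context="independent_test")
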