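"""Validation module: 5-classifier cross-validated AUC and MCC reporting.

Selected feature sets are judged by five classifiers that are deliberately
disjoint from the selection ensemble — AdaBoost, Extra Trees, KNeighbors,
a multilayer perceptron, and LassoCV — each evaluated under stratified
10-fold cross-validation. Per classifier the module reports the mean
held-out ROC AUC (fold ROC curves vertically averaged on a common
false-positive-rate grid) and the Matthews correlation coefficient of the
pooled out-of-fold predictions; the headline numbers are the arithmetic
means of the five per-classifier values. The whole evaluation is repeated
``n_runs`` times with distinct seeds and averaged, to damp the
stochasticity of the ensemble members and of the fold partitions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, ExtraTreesClassifier
from sklearn.linear_model import LassoCV
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .data_model import AbundanceDataset, DatasetError, FeatureSignature

__all__ = [
    "ClassifierPerformance",
    "ValidationReport",
    "VALIDATION_CLASSIFIERS",
    "build_validation_roster",
    "compute_mcc",
    "compute_roc_auc",
    "validate_features",
]

logger = logging.getLogger(__name__)

#: Fixed false-positive-rate grid for vertical ROC averaging.
FPR_GRID = np.linspace(0.0, 1.0, 101)

VALIDATION_CLASSIFIERS = ("AdaBoost", "ExtraTrees", "KNeighbors", "MLP", "LassoCV")


def build_validation_roster(seed: int) -> list[tuple[str, object]]:
    """The five validation classifiers with fixed, documented defaults."""
    return [
        ("AdaBoost", AdaBoostClassifier(n_estimators=15, random_state=seed)),
        ("ExtraTrees", ExtraTreesClassifier(n_estimators=25, random_state=seed)),
        ("KNeighbors", KNeighborsClassifier()),
        (
            "MLP",
            MLPClassifier(
                hidden_layer_sizes=(30,), max_iter=150, tol=1e-3, random_state=seed
            ),
        ),
        ("LassoCV", LassoCV(cv=4, alphas=20, random_state=seed)),
    ]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def compute_mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from a 2x2 confusion table.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)), defined as
    0 whenever a denominator factor vanishes. Equals the Pearson
    correlation between the binary prediction and truth vectors.
    """
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise DatasetError("confusion-table entries must be non-negative")
    if tp + tn + fp + fn == 0:
        raise DatasetError("empty confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def compute_roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC by the trapezoidal rule, plus the ROC curve points.

    Equivalent to the Mann-Whitney U statistic over all (case, control)
    score pairs divided by ``n_pos * n_neg``, ties counting 1/2.

    Returns ``(auc, fpr, tpr)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise DatasetError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise DatasetError("both classes must be present to compute a ROC")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


def _interp_roc(fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    """Fold ROC interpolated onto the common FPR grid, anchored at (0,0)."""
    tpr_grid = np.interp(FPR_GRID, fpr, tpr)
    tpr_grid[0] = 0.0
    tpr_grid[-1] = 1.0
    return tpr_grid


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------


@dataclass
class ClassifierPerformance:
    name: str
    mean_auc: float
    auc_std: float
    mcc: float
    mean_tpr: np.ndarray | None = None
    tpr_std: np.ndarray | None = None


@dataclass
class ValidationReport:
    """Per-classifier and averaged AUC / MCC for one feature set."""

    per_classifier: list[ClassifierPerformance]
    average_auc: float
    average_mcc: float
    n_features_used: int
    n_runs: int
    seed: int
    dataset_name: str = ""
    matched_count: int | None = None
    signature_size: int | None = None

    def best_classifier(self) -> ClassifierPerformance:
        return max(self.per_classifier, key=lambda c: c.mean_auc)


# ---------------------------------------------------------------------------
# continuous scores / hard labels per classifier
# ---------------------------------------------------------------------------


def _scores_and_labels(name: str, model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Held-out continuous score (class-1 tendency) and hard prediction.

    LassoCV is a continuous regressor on the {0,1} labels: its prediction
    is the score and the hard label is score > 0.5. Other members use the
    class-1 probability where available, else the decision-function value.
    """
    if name == "LassoCV":
        score = np.asarray(model.predict(X), dtype=float)
        return score, (score > 0.5).astype(int)
    if hasattr(model, "predict_proba"):
        # class-1 probability; > 0.5 coincides with predict for binary tasks
        score = np.asarray(model.predict_proba(X))[:, 1]
        return score, (score > 0.5).astype(int)
    score = np.asarray(model.decision_function(X), dtype=float)
    return score, (score > 0).astype(int)


def _resolve_feature_indices(
    dataset: AbundanceDataset, features: FeatureSignature | str
) -> list[int]:
    if isinstance(features, str):
        if features != "all":
            raise DatasetError(f"unknown feature selector {features!r}")
        return list(range(dataset.n_features))
    index = dataset.feature_index()
    missing = [s for s in features.sequences if s not in index]
    if missing:
        raise DatasetError(
            f"{len(missing)} signature sequences absent from {dataset.name}: "
            f"{[m[:20] + '...' for m in missing[:3]]}"
        )
    return [index[s] for s in features.sequences]


def validate_features(
    dataset: AbundanceDataset,
    features: FeatureSignature | str = "all",
    n_runs: int = 10,
    seed: int = 0,
    n_folds: int = 10,
) -> ValidationReport:
    """Evaluate a feature set with the 5-classifier validation roster.

    Per classifier and run: stratified ``n_folds``-fold CV; fold ROC
    curves are averaged vertically on a 101-point FPR grid; the AUC is the
    mean of per-fold AUCs; the MCC comes from the pooled out-of-fold hard
    predictions of the run. Per-classifier values are then averaged over
    the ``n_runs`` runs (seeds ``seed+0 .. seed+n_runs-1``), and the
    report's headline values average the five classifiers.
    """
    cols = _resolve_feature_indices(dataset, features)
    if not cols:
        raise DatasetError("no features to validate")
    dataset.check_group_sizes(min_per_group=n_folds)
    X_all = dataset.counts[:, cols].astype(float)
    y = dataset.labels

    per_classifier: list[ClassifierPerformance] = []
    for name, proto in build_validation_roster(seed):
        run_aucs: list[float] = []
        run_auc_stds: list[float] = []
        run_mccs: list[float] = []
        tprs: list[np.ndarray] = []
        for r in range(n_runs):
            run_seed = seed + r
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=run_seed)
            fold_aucs: list[float] = []
            pooled_pred = np.empty_like(y)
            for train_idx, test_idx in skf.split(X_all, y):
                scaler = StandardScaler().fit(X_all[train_idx])
                X_tr = scaler.transform(X_all[train_idx])
                X_te = scaler.transform(X_all[test_idx])
                model = clone(proto)
                if hasattr(model, "random_state"):
                    model.random_state = run_seed
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model.fit(X_tr, y[train_idx])
                except Exception as exc:  # noqa: BLE001
                    logger.warning("%s failed on a fold: %s", name, exc)
                    pooled_pred[test_idx] = 0
                    continue
                score, hard = _scores_and_labels(name, model, X_te)
                pooled_pred[test_idx] = hard
                if len(np.unique(y[test_idx])) == 2:
                    auc, fpr, tpr = compute_roc_auc(score, y[test_idx])
                    fold_aucs.append(auc)
                    tprs.append(_interp_roc(fpr, tpr))
            tp = int(np.sum((pooled_pred == 1) & (y == 1)))
            tn = int(np.sum((pooled_pred == 0) & (y == 0)))
            fp = int(np.sum((pooled_pred == 1) & (y == 0)))
            fn = int(np.sum((pooled_pred == 0) & (y == 1)))
            run_mccs.append(compute_mcc(tp, tn, fp, fn))
            if fold_aucs:
                run_aucs.append(float(np.mean(fold_aucs)))
                run_auc_stds.append(float(np.std(fold_aucs)))
        per_classifier.append(
            ClassifierPerformance(
                name=name,
                mean_auc=float(np.mean(run_aucs)),
                auc_std=float(np.mean(run_auc_stds)),
                mcc=float(np.mean(run_mccs)),
                mean_tpr=np.mean(tprs, axis=0),
                tpr_std=np.std(tprs, axis=0),
            )
        )

    return ValidationReport(
        per_classifier=per_classifier,
        average_auc=float(np.mean([c.mean_auc for c in per_classifier])),
        average_mcc=float(np.mean([c.mcc for c in per_classifier])),
        n_features_used=len(cols),
        n_runs=n_runs,
        seed=seed,
        dataset_name=dataset.name,
    )
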