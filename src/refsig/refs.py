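"""Recursive Ensemble Feature Selection (REFS).

REFS searches for the smallest feature set that attains the highest
cross-validated classification accuracy. Features are scored by an
ensemble of eight heterogeneous scikit-learn classifiers: per-feature
importances (absolute coefficients for linear members, impurity
importances for tree members) are L1-normalised per classifier and summed,
and the lowest-scoring fraction of features is discarded at each step.

The elimination is nested inside stratified 10-fold cross-validation so
that the reported accuracy curve is never contaminated by feature
selection: within each fold an independent elimination path runs on the
training portion only, and the accuracy recorded at every feature count
comes from that fold's untouched held-out samples. The trajectory is the
fold-averaged accuracy-vs-feature-count curve. The reported signature is
the feature set of a parallel elimination path run on the complete
dataset, cut at the trajectory point with maximal accuracy (ties resolved
toward fewer features) — the usual way a recursive-elimination selector
turns an unbiased CV curve into one concrete feature set.

To compensate for the stochasticity of ensemble members the whole
procedure is repeated ``n_runs`` times with distinct seeds; the reported
signature is the best-accuracy run's set, with per-feature agreement
across runs as a stability diagnostic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import (
    LogisticRegression,
    RidgeClassifier,
    SGDClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .data_model import AbundanceDataset, DatasetError, FeatureSignature

__all__ = [
    "RefsConfig",
    "RefsResult",
    "build_ensemble_roster",
    "elimination_schedule",
    "ensemble_feature_scores",
    "refs_select",
]

logger = logging.getLogger(__name__)


def build_ensemble_roster(seed: int) -> list[tuple[str, object]]:
    """The eight-member ensemble used for feature scoring.

    Linear members (SGD, linear-kernel SVC, logistic regression,
    passive-aggressive, ridge) contribute |coefficient| importances; tree
    members (gradient boosting, random forest, bagged decision trees)
    contribute impurity importances. Ensemble sizes of the tree members
    are kept moderate — feature ranking stabilises well before the
    default ensemble sizes on tables with tens of samples, and the roster
    is refit at every fold of every elimination step.
    """
    return [
        ("SGD", SGDClassifier(random_state=seed)),
        ("LinearSVC", LinearSVC(dual="auto", random_state=seed)),
        (
            "GradientBoosting",
            GradientBoostingClassifier(
                n_estimators=25, max_depth=2, max_features="sqrt", random_state=seed
            ),
        ),
        ("RandomForest", RandomForestClassifier(n_estimators=25, random_state=seed)),
        (
            "LogisticRegression",
            LogisticRegression(solver="liblinear", max_iter=1000, random_state=seed),
        ),
        (
            # the passive-aggressive update rule, via its SGD formulation
            "PassiveAggressive",
            SGDClassifier(
                loss="hinge", penalty=None, learning_rate="pa1", eta0=1.0,
                random_state=seed,
            ),
        ),
        ("Ridge", RidgeClassifier(random_state=seed)),
        (
            "Bagging",
            BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=seed),
                n_estimators=10,
                random_state=seed,
            ),
        ),
    ]


@dataclass
class RefsConfig:
    """Tunable parameters of the REFS procedure."""

    n_folds: int = 10
    reduction_keep_fraction: float = 0.8
    min_features: int = 1
    n_runs: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.reduction_keep_fraction < 1:
            raise DatasetError("reduction_keep_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise DatasetError("n_folds must be >= 2")
        if self.min_features < 1:
            raise DatasetError("min_features must be >= 1")
        if self.n_runs < 1:
            raise DatasetError("n_runs must be >= 1")


@dataclass
class TrajectoryStep:
    n_features: int
    mean_accuracy: float
    accuracy_std: float


@dataclass
class RefsResult:
    """Outcome of :func:`refs_select`.

    ``trajectory`` is the accuracy-vs-feature-count curve of the reported
    (best) run; ``selected`` the minimal feature set at maximal accuracy;
    ``per_run_selected`` the per-run signatures; ``run_agreement`` the
    fraction of runs whose selected set contains each reported sequence.
    """

    trajectory: list[TrajectoryStep]
    selected: FeatureSignature
    per_run_selected: list[FeatureSignature]
    run_agreement: dict[str, float]
    best_run: int = 0
    per_run_trajectories: list[list[TrajectoryStep]] = field(default_factory=list)


def elimination_schedule(
    n_features: int, keep_fraction: float = 0.8, min_features: int = 1
) -> list[int]:
    """Feature counts visited by the elimination loop.

    ``|F_{k+1}| = ceil(keep_fraction * |F_k|)``, forced to shrink by at
    least one feature per step (the ceiling stalls below five features at
    keep fraction 0.8), stopping at ``min_features``.
    """
    if n_features < min_features:
        raise DatasetError("n_features below min_features")
    sizes = [n_features]
    while sizes[-1] > min_features:
        nxt = math.ceil(keep_fraction * sizes[-1])
        if nxt >= sizes[-1]:
            nxt = sizes[-1] - 1
        if nxt < min_features:
            break
        sizes.append(nxt)
    return sizes


def _extract_importances(name: str, model, n_features: int) -> np.ndarray:
    if hasattr(model, "feature_importances_"):
        imp = np.asarray(model.feature_importances_, dtype=float)
    elif hasattr(model, "coef_"):
        imp = np.abs(np.asarray(model.coef_, dtype=float)).ravel()
    elif hasattr(model, "estimators_"):  # bagging of trees
        imp = np.mean(
            [est.feature_importances_ for est in model.estimators_], axis=0
        )
    else:  # pragma: no cover - roster guarantees one of the above
        raise AttributeError(f"no importance source for {name}")
    if imp.shape[0] != n_features:
        raise ValueError(f"{name}: importance length {imp.shape[0]} != {n_features}")
    return imp


def ensemble_feature_scores(
    dataset: AbundanceDataset,
    feature_subset: list[int] | np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Aggregate held-out importances and accuracy for a feature subset.

    For every stratified fold and roster classifier: standardise counts
    with training-fold statistics, fit, record held-out accuracy and the
    L1-normalised per-feature importance. Importances are summed over
    classifiers and folds into the score vector; accuracy is the mean over
    all fold x classifier evaluations. A classifier whose fit fails
    contributes zero importances and is excluded from the accuracy mean.

    Returns ``(scores, mean_accuracy, accuracy_std)``.
    """
    subset = np.asarray(feature_subset, dtype=int)
    if subset.size == 0:
        raise DatasetError("empty feature subset")
    X = dataset.counts[:, subset].astype(float)
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise DatasetError("both classes must be present")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(subset.size)
    accuracies: list[float] = []

    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2:  # pragma: no cover - stratified
            raise DatasetError("a training fold is missing a class")
        scaler = StandardScaler().fit(X[train_idx])
        fold_scores, fold_accs = _fit_ensemble_split(
            scaler.transform(X[train_idx]),
            y[train_idx],
            scaler.transform(X[test_idx]),
            y[test_idx],
            seed,
        )
        scores += fold_scores
        accuracies.extend(fold_accs)

    if not accuracies:
        raise DatasetError("every roster classifier failed to fit")
    return scores, float(np.mean(accuracies)), float(np.std(accuracies))


def _fit_ensemble_split(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray | None,
    y_te: np.ndarray | None,
    seed: int,
) -> tuple[np.ndarray, list[float]]:
    """Fit the roster on one (already standardised) training matrix.

    Returns the summed L1-normalised importance vector and the held-out
    accuracy of each successfully fitted classifier (empty when no test
    split is given). A classifier whose fit fails contributes zero
    importances and no accuracy.
    """
    scores = np.zeros(X_tr.shape[1])
    accuracies: list[float] = []
    for name, proto in build_ensemble_roster(seed):
        model = clone(proto)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_tr, y_tr)
        except Exception as exc:  # noqa: BLE001 - degrade gracefully
            logger.warning("classifier %s failed to fit: %s", name, exc)
            continue
        if X_te is not None:
            accuracies.append(float(model.score(X_te, y_te)))
        imp = _extract_importances(name, model, X_tr.shape[1])
        total = imp.sum()
        if total > 0:
            scores += imp / total
    return scores, accuracies


def _elimination_path(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray | None,
    y_te: np.ndarray | None,
    target_sizes: list[int],
    step_seeds: list[int],
) -> tuple[list[np.ndarray], list[list[float]]]:
    """One recursive-elimination path over the given (standardised) split.

    Returns the feature-index set at every schedule size and, when a test
    split is supplied, the per-step held-out accuracies of the roster.
    """
    current = np.arange(X_tr.shape[1])
    sets: list[np.ndarray] = []
    accs: list[list[float]] = []
    for k, size in enumerate(target_sizes):
        scores, fold_accs = _fit_ensemble_split(
            X_tr[:, current],
            y_tr,
            None if X_te is None else X_te[:, current],
            y_te,
            step_seeds[k],
        )
        sets.append(current.copy())
        accs.append(fold_accs)
        if k + 1 == len(target_sizes):
            break
        keep = target_sizes[k + 1]
        # highest scores kept; ties broken by original feature order
        order = sorted(range(current.size), key=lambda i: (-scores[i], current[i]))
        current = np.array(sorted(current[order[:keep]]))
    return sets, accs


def _single_run(
    dataset: AbundanceDataset, config: RefsConfig, run_seed: int
) -> tuple[list[TrajectoryStep], list[np.ndarray]]:
    """One nested REFS run.

    Per CV fold an elimination path on the training portion yields
    held-out accuracies at every schedule size; the trajectory averages
    those over folds and classifiers. A full-data elimination path
    provides the candidate feature set at every size.
    """
    rng = np.random.default_rng(run_seed)
    X = dataset.counts.astype(float)
    y = dataset.labels
    target_sizes = elimination_schedule(
        dataset.n_features, config.reduction_keep_fraction, config.min_features
    )
    # one classifier seed per run, shared by every step: common random
    # numbers, so accuracy differences along the trajectory reflect the
    # feature sets rather than resampled classifier noise
    step_seeds = [int(rng.integers(0, 2**31 - 1))] * len(target_sizes)

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=run_seed)
    step_accs: list[list[float]] = [[] for _ in target_sizes]
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2:  # pragma: no cover - stratified
            raise DatasetError("a training fold is missing a class")
        scaler = StandardScaler().fit(X[train_idx])
        X_tr = scaler.transform(X[train_idx])
        X_te = scaler.transform(X[test_idx])
        _, accs = _elimination_path(
            X_tr, y[train_idx], X_te, y[test_idx], target_sizes, step_seeds
        )
        for k, fold_accs in enumerate(accs):
            step_accs[k].extend(fold_accs)

    X_full = StandardScaler().fit_transform(X)
    step_sets, _ = _elimination_path(X_full, y, None, None, target_sizes, step_seeds)

    trajectory = []
    for size, accs_k in zip(target_sizes, step_accs):
        if not accs_k:
            raise DatasetError("every roster classifier failed to fit")
        trajectory.append(
            TrajectoryStep(size, float(np.mean(accs_k)), float(np.std(accs_k)))
        )
    return trajectory, step_sets


def refs_select(dataset: AbundanceDataset, config: RefsConfig | None = None) -> RefsResult:
    """Run REFS on a discovery dataset.

    Each of ``config.n_runs`` runs (seeds ``seed+0 .. seed+n_runs-1``)
    performs the full elimination pass and selects the trajectory step
    with maximal mean accuracy (ties toward fewer features). The reported
    signature comes from the run with the highest selected-step accuracy
    (ties: fewer features, then lower run index).
    """
    config = config or RefsConfig()
    config.validate()
    dataset.check_group_sizes()
    if len(np.unique(dataset.labels)) < 2:
        raise DatasetError("labels are constant")
    minority = min(np.sum(dataset.labels == 0), np.sum(dataset.labels == 1))
    if config.n_folds > minority:
        raise DatasetError(
            f"n_folds={config.n_folds} exceeds minority class size {minority}"
        )
    if dataset.n_features < config.min_features:
        raise DatasetError("dataset has fewer features than min_features")

    per_run_selected: list[FeatureSignature] = []
    per_run_sets: list[np.ndarray] = []
    per_run_best: list[tuple[float, int]] = []  # (accuracy, n_features)
    trajectories: list[list[TrajectoryStep]] = []

    for r in range(config.n_runs):
        run_seed = config.seed + r
        trajectory, step_sets = _single_run(dataset, config, run_seed)
        # max accuracy, tie-broken toward fewest features (= latest step)
        best = max(
            range(len(trajectory)),
            key=lambda i: (trajectory[i].mean_accuracy, -trajectory[i].n_features),
        )
        chosen = step_sets[best]
        per_run_sets.append(chosen)
        per_run_selected.append(
            FeatureSignature(
                source_dataset=dataset.name,
                sequences=[dataset.features[i] for i in chosen],
            )
        )
        per_run_best.append(
            (trajectory[best].mean_accuracy, trajectory[best].n_features)
        )
        trajectories.append(trajectory)
        logger.info(
            "REFS run %d/%d: %d features at accuracy %.3f",
            r + 1,
            config.n_runs,
            trajectory[best].n_features,
            trajectory[best].mean_accuracy,
        )

    best_run = min(
        range(config.n_runs),
        key=lambda r: (-per_run_best[r][0], per_run_best[r][1], r),
    )
    selected = per_run_selected[best_run]
    run_agreement = {
        seq: sum(seq in sig.sequences for sig in per_run_selected) / config.n_runs
        for seq in selected.sequences
    }
    return RefsResult(
        trajectory=trajectories[best_run],
        selected=selected,
        per_run_selected=per_run_selected,
        run_agreement=run_agreement,
        best_run=best_run,
        per_run_trajectories=trajectories,
    )
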