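"""Comparison feature-selection baselines: K-Best with F-score and
10-time random selection.

K-Best ranks features on the discovery dataset by the one-way ANOVA F
statistic between the two groups and keeps the k best, with k set to the
size of the REFS signature. The random baseline repeatedly draws m
features uniformly without replacement from a testing dataset — m equal
to the number of REFS signature features actually found there — and
validates each draw, reporting per-run and averaged AUC / MCC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import f_classif

from .data_model import AbundanceDataset, DatasetError, FeatureSignature
from .validation import ValidationReport, validate_features

__all__ = ["BaselineResult", "kbest_select", "random_select"]


@dataclass
class BaselineResult:
    method: str
    signatures: list[FeatureSignature]
    reports: list[ValidationReport]
    average_auc: float
    average_mcc: float


def anova_f_scores(dataset: AbundanceDataset) -> np.ndarray:
    """Per-feature one-way ANOVA F statistic between the two groups.

    F = MS_between / MS_within with (1, n-2) degrees of freedom, computed
    on raw counts. A feature with zero within-group variance in both
    groups is assigned F = 0 (it carries no usable contrast).
    """
    if len(np.unique(dataset.labels)) < 2:
        raise DatasetError("both classes must be present")
    F, _ = f_classif(dataset.counts.astype(float), dataset.labels)
    return np.nan_to_num(F, nan=0.0, posinf=0.0)


def kbest_select(dataset: AbundanceDataset, k: int) -> FeatureSignature:
    """The k features with the largest F scores, ties by feature order."""
    if not 1 <= k <= dataset.n_features:
        raise DatasetError(f"k={k} outside [1, {dataset.n_features}]")
    F = anova_f_scores(dataset)
    order = sorted(range(dataset.n_features), key=lambda i: (-F[i], i))
    chosen = sorted(order[:k])
    return FeatureSignature(
        source_dataset=dataset.name,
        sequences=[dataset.features[i] for i in chosen],
    )


def random_select(
    testing: AbundanceDataset,
    m: int,
    n_runs: int = 10,
    seed: int = 0,
    validation_runs: int = 1,
    n_folds: int = 10,
) -> BaselineResult:
    """Validate ``n_runs`` uniform random m-feature draws from a dataset.

    Draw r uses seed ``seed + r``; each draw is validated with the
    5-classifier module. The averaged AUC / MCC over draws is the random
    baseline against which selected signatures are compared.
    """
    if not 1 <= m <= testing.n_features:
        raise DatasetError(f"m={m} outside [1, {testing.n_features}]")
    signatures: list[FeatureSignature] = []
    reports: list[ValidationReport] = []
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        cols = np.sort(rng.choice(testing.n_features, size=m, replace=False))
        sig = FeatureSignature(
            source_dataset=testing.name,
            sequences=[testing.features[i] for i in cols],
        )
        report = validate_features(
            testing.subset_features(list(cols)),
            "all",
            n_runs=validation_runs,
            seed=seed + r,
            n_folds=n_folds,
        )
        signatures.append(sig)
        reports.append(report)
    return BaselineResult(
        method="random",
        signatures=signatures,
        reports=reports,
        average_auc=float(np.mean([rep.average_auc for rep in reports])),
        average_mcc=float(np.mean([rep.average_mcc for rep in reports])),
    )
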