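"""Synthetic families of linked ASV datasets with a planted signature.

The generator emulates the structure of a multi-study 16S experiment:
one *discovery* dataset whose ASVs were trimmed to the shortest read
length, and two or more *testing* datasets with longer ASVs. A small set
of planted "signal" sequences discriminates case from control samples; in
each testing dataset every surviving planted sequence is embedded as a
contiguous substring of one (or, for a configurable number of sequences,
two) longer testing features, mirroring how an exact ASV recurs inside
sequences trimmed at a different length. Counts follow a negative binomial
model; testing datasets can carry a multiplicative batch shift.

Everything is deterministic given the spec seed, so the generated truth is
a self-contained oracle for the downstream matching and selection stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import AbundanceDataset, DatasetError, FeatureSignature

__all__ = ["SyntheticSpec", "TruthReport", "generate_dataset_family", "plant_truth_report"]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Generative parameters for a linked dataset family.

    Parameters
    ----------
    n_control, n_case:
        Samples per group in every dataset (each must be >= 10, matching
        the eligibility rule for real studies).
    n_features:
        Total ASV features per dataset.
    n_signal:
        Number of planted discriminative features.
    log2_fold_change:
        Case-group mean of a signal feature is ``base_mean * 2**log2_fold_change``.
    dispersion:
        Negative-binomial dispersion ``alpha`` (variance = mu + alpha*mu^2).
    base_mean:
        Expected count of a background feature.
    trim_lengths:
        Per-dataset ASV length; the unique minimum marks the discovery
        dataset, the rest are testing datasets.
    n_duplicated_matches:
        How many planted sequences are embedded in exactly two distinct
        testing features (per testing dataset).
    dropout_signal:
        How many planted sequences have no containing feature in each
        testing dataset.
    batch_log_shift:
        Log-scale multiplicative offset applied to all feature means of
        each testing dataset (scalar, or one value per testing dataset).
    seed:
        Base RNG seed; the family is fully reproducible from it.
    """

    n_control: int = 50
    n_case: int = 50
    n_features: int = 500
    n_signal: int = 10
    log2_fold_change: float = 2.0
    dispersion: float = 0.5
    base_mean: float = 50.0
    trim_lengths: tuple[int, ...] = (100, 150, 150)
    n_duplicated_matches: int = 2
    dropout_signal: int = 2
    batch_log_shift: float | tuple[float, ...] = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 10 or self.n_case < 10:
            raise DatasetError("each group needs >= 10 samples")
        if not 0 < self.n_signal < self.n_features:
            raise DatasetError("need 0 < n_signal < n_features")
        if len(self.trim_lengths) < 3:
            raise DatasetError("need >= 3 trim lengths (1 discovery + >= 2 testing)")
        lmin = min(self.trim_lengths)
        if list(self.trim_lengths).count(lmin) != 1:
            raise DatasetError("trim_lengths must have a unique minimum")
        if any(l < lmin + 2 for l in self.trim_lengths if l != lmin):
            raise DatasetError(
                "testing trim lengths must exceed the discovery length by >= 2 "
                "so planted sequences can be embedded with flanks"
            )
        if not 0 <= self.dropout_signal < self.n_signal:
            raise DatasetError("need 0 <= dropout_signal < n_signal")
        if self.n_duplicated_matches + self.dropout_signal > self.n_signal:
            raise DatasetError("duplicated + dropped sequences exceed n_signal")
        if self.dispersion <= 0 or self.base_mean <= 0:
            raise DatasetError("dispersion and base_mean must be positive")

    def batch_shifts(self) -> list[float]:
        """One log-shift per testing dataset, in family order."""
        n_testing = len(self.trim_lengths) - 1
        if np.isscalar(self.batch_log_shift):
            return [float(self.batch_log_shift)] * n_testing
        shifts = list(self.batch_log_shift)  # type: ignore[arg-type]
        if len(shifts) != n_testing:
            raise DatasetError(
                f"batch_log_shift needs {n_testing} entries, got {len(shifts)}"
            )
        return [float(s) for s in shifts]


@dataclass
class TruthReport:
    """Exhaustive containment scan of the planted truth in one dataset.

    ``rows`` has one entry per truth sequence: the matched feature column
    indices and the occurrence count. ``summed_counts`` maps each truth
    sequence with >= 1 match to the per-sample sum over its matching
    columns — the expected aggregated abundance column.
    """

    dataset_name: str
    rows: pd.DataFrame
    summed_counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def matched_count(self) -> int:
        return int((self.rows["n_occurrences"] > 0).sum())


# ---------------------------------------------------------------------------
# sequence machinery
# ---------------------------------------------------------------------------


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct uniform DNA strings of the given length."""
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        block = rng.integers(0, 4, size=(n - len(seqs), length))
        for row in block:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    return seqs


def _embed(rng: np.random.Generator, core: str, length: int) -> str:
    """core embedded at a random offset inside a random string of `length`."""
    slack = length - len(core)
    off = int(rng.integers(0, slack + 1))
    left = "".join(_BASES[rng.integers(0, 4, size=off)])
    right = "".join(_BASES[rng.integers(0, 4, size=slack - off)])
    return left + core + right


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, n_samples: int
) -> np.ndarray:
    """Negative binomial draws, shape (n_samples, len(mean)).

    Parameterised by mean mu and dispersion alpha with
    variance = mu + alpha * mu^2 (gamma-Poisson mixture).
    """
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=(n_samples, mean.size)).astype(np.int64)


# ---------------------------------------------------------------------------
# family generation
# ---------------------------------------------------------------------------


def generate_dataset_family(
    spec: SyntheticSpec,
) -> tuple[list[AbundanceDataset], FeatureSignature]:
    """Generate one discovery dataset plus testing datasets and the truth.

    The returned list follows ``spec.trim_lengths`` order; the dataset at
    the position of the minimum trim length is the discovery dataset and
    contains the truth sequences verbatim as its first ``n_signal``
    planted feature columns (feature order is shuffled afterwards so the
    planted columns are not positionally obvious). The returned
    :class:`FeatureSignature` holds the ground-truth planted sequences.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lmin = min(spec.trim_lengths)
    disc_idx = list(spec.trim_lengths).index(lmin)
    n_samples = spec.n_control + spec.n_case
    labels = np.array([0] * spec.n_control + [1] * spec.n_case)
    shifts = spec.batch_shifts()

    truth_seqs = _random_seqs(rng, spec.n_signal, lmin)

    datasets: list[AbundanceDataset] = []
    testing_pos = 0
    for d, length in enumerate(spec.trim_lengths):
        name = f"synthetic_d{d}"
        if d == disc_idx:
            seqs = list(truth_seqs)
            seqs += _background_without_truth(
                rng, spec.n_features - spec.n_signal, length, truth_seqs
            )
            # signal column j carries truth sequence j
            signal_cols: dict[int, list[int]] = {j: [j] for j in range(spec.n_signal)}
            shift = 0.0
        else:
            # per-testing-dataset plan: which truths drop out, which duplicate
            order = rng.permutation(spec.n_signal)
            dropped = set(order[: spec.dropout_signal].tolist())
            duplicated = set(
                order[spec.dropout_signal : spec.dropout_signal + spec.n_duplicated_matches].tolist()
            )
            seqs = []
            signal_cols = {}
            for j, core in enumerate(truth_seqs):
                if j in dropped:
                    continue
                n_copies = 2 if j in duplicated else 1
                signal_cols[j] = []
                for _ in range(n_copies):
                    signal_cols[j].append(len(seqs))
                    seqs.append(_embed(rng, core, length))
            n_background = spec.n_features - len(seqs)
            background = _background_without_truth(rng, n_background, length, truth_seqs)
            seqs += background
            shift = shifts[testing_pos]
            testing_pos += 1

        # means per (group, feature)
        mu_control = np.full(spec.n_features, spec.base_mean)
        mu_case = np.full(spec.n_features, spec.base_mean)
        planted = [c for cols in signal_cols.values() for c in cols]
        mu_case[planted] *= 2.0 ** spec.log2_fold_change
        factor = float(np.exp(shift))
        mu_control *= factor
        mu_case *= factor

        counts = np.empty((n_samples, spec.n_features), dtype=np.int64)
        counts[labels == 0] = _nb_counts(rng, mu_control, spec.dispersion, spec.n_control)
        counts[labels == 1] = _nb_counts(rng, mu_case, spec.dispersion, spec.n_case)

        # shuffle feature order so planted columns are not the first ones
        perm = rng.permutation(spec.n_features)
        seqs = [seqs[i] for i in perm]
        counts = counts[:, perm]

        datasets.append(
            AbundanceDataset(
                name=name,
                features=seqs,
                counts=counts,
                labels=labels.copy(),
                sample_ids=[f"{name}_s{i}" for i in range(n_samples)],
            )
        )

    truth = FeatureSignature(source_dataset=datasets[disc_idx].name, sequences=truth_seqs)
    return datasets, truth


def _background_without_truth(
    rng: np.random.Generator, n: int, length: int, truth_seqs: list[str]
) -> list[str]:
    """Random sequences guaranteed not to contain any truth sequence.

    Accidental containment of a >=50 nt exact sequence in uniform DNA has
    probability ~4**-50 per position; the rejection loop exists for
    correctness at the short lengths used in unit tests.
    """
    out: list[str] = []
    while len(out) < n:
        for s in _random_seqs(rng, n - len(out), length):
            if not any(t in s for t in truth_seqs):
                out.append(s)
    return out


# ---------------------------------------------------------------------------
# ground-truth report (independent matching oracle)
# ---------------------------------------------------------------------------


def plant_truth_report(
    family: list[AbundanceDataset], truth: FeatureSignature
) -> list[TruthReport]:
    """Brute-force containment scan of every truth sequence in every dataset.

    One report per dataset, scanning all sequence pairs exhaustively: truth
    sequence ``s`` matches feature ``t`` iff ``s`` is a contiguous
    substring of ``t``. Used as the independent oracle for the signature
    matching stage.
    """
    reports = []
    for ds in family:
        recs = []
        summed: dict[str, np.ndarray] = {}
        for s in truth.sequences:
            hits = [j for j, t in enumerate(ds.features) if s in t]
            recs.append(
                {"truth_sequence": s, "matched_features": hits, "n_occurrences": len(hits)}
            )
            if hits:
                summed[s] = ds.counts[:, hits].sum(axis=1)
        reports.append(
            TruthReport(dataset_name=ds.name, rows=pd.DataFrame(recs), summed_counts=summed)
        )
    return reports
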