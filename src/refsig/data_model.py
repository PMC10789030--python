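"""Core data types and I/O for ASV abundance studies.

An analysis works on triples of files per dataset:

* a counts table (TSV/CSV): first column sample id, one column per ASV
  feature id, non-negative integer counts;
* a FASTA file of ASV sequences, one record per feature, record id equal
  to the corresponding counts column;
* a labels table (TSV/CSV): sample id and group, where the group vocabulary
  maps onto the binary {0 = control, 1 = case} encoding.

The feature *identity* is the ASV sequence string itself (uppercased
A/C/G/T text): exact denoised sequences are comparable across independent
studies, which is what makes cross-dataset signature testing possible.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AbundanceDataset",
    "FeatureSignature",
    "DatasetError",
    "DEFAULT_LABEL_MAP",
    "MIN_GROUP_SIZE",
    "load_abundance_dataset",
    "write_abundance_dataset",
    "write_signature",
    "read_signature",
    "select_discovery_dataset",
]

#: Minimum per-group sample count for a dataset to be usable in feature
#: selection or validation.
MIN_GROUP_SIZE = 10

#: Default vocabulary mapping label-file text onto the binary encoding.
DEFAULT_LABEL_MAP = {
    "control": 0,
    "case": 1,
    "0": 0,
    "1": 1,
}


class DatasetError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class AbundanceDataset:
    """A samples x ASV-features count matrix with binary group labels.

    Attributes
    ----------
    name:
        Human-readable dataset label.
    features:
        Ordered ASV sequences (uppercase DNA strings); the sequence is the
        feature identity and must be unique within the dataset.
    counts:
        Integer matrix of shape ``(n_samples, n_features)``.
    labels:
        Per-sample binary class, 0 = control, 1 = case.
    sample_ids:
        Ordered unique sample identifiers.
    """

    name: str
    features: list[str]
    counts: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.features = [str(s).upper() for s in self.features]
        self.counts = np.asarray(self.counts)
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n, p = self.counts.shape
        if n != len(self.labels) or n != len(self.sample_ids):
            raise DatasetError(
                f"{self.name}: counts has {n} rows but "
                f"{len(self.labels)} labels / {len(self.sample_ids)} sample ids"
            )
        if p != len(self.features):
            raise DatasetError(
                f"{self.name}: counts has {p} columns but {len(self.features)} features"
            )
        if not np.issubdtype(self.counts.dtype, np.number):
            raise DatasetError(f"{self.name}: counts are not numeric")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise DatasetError(
                f"{self.name}: negative count at sample {self.sample_ids[i]!r}, "
                f"feature column {j}"
            )
        dupes = _duplicates(self.features)
        if dupes:
            raise DatasetError(f"{self.name}: duplicate feature sequences: {dupes[:5]}")
        if len(set(self.sample_ids)) != n:
            raise DatasetError(f"{self.name}: sample ids are not unique")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise DatasetError(f"{self.name}: labels must be 0/1")

    def check_group_sizes(self, min_per_group: int = MIN_GROUP_SIZE) -> None:
        """Enforce the eligibility rule for selection/validation use."""
        n_control = int(np.sum(self.labels == 0))
        n_case = int(np.sum(self.labels == 1))
        if n_control < min_per_group or n_case < min_per_group:
            raise DatasetError(
                f"{self.name}: needs >= {min_per_group} samples per group, "
                f"got control={n_control}, case={n_case}"
            )

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def feature_index(self) -> dict[str, int]:
        return {seq: i for i, seq in enumerate(self.features)}

    def subset_features(self, indices: list[int], name: str | None = None) -> "AbundanceDataset":
        """A copy restricted to the given feature columns (order preserved)."""
        return AbundanceDataset(
            name=name or self.name,
            features=[self.features[i] for i in indices],
            counts=self.counts[:, indices].copy(),
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class FeatureSignature:
    """An ordered set of ASV sequences selected as candidate biomarkers."""

    source_dataset: str
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequences = [str(s).upper() for s in self.sequences]
        if len(set(self.sequences)) != len(self.sequences):
            raise DatasetError(
                f"signature from {self.source_dataset}: duplicate sequences"
            )

    @property
    def size(self) -> int:
        return len(self.sequences)


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=delimiter, dtype={0: str})


def load_abundance_dataset(
    counts_path: str | Path,
    fasta_path: str | Path,
    labels_path: str | Path,
    *,
    name: str | None = None,
    delimiter: str | None = None,
    label_map: dict[str, int] | None = None,
) -> AbundanceDataset:
    """Load and validate a dataset triple (counts, FASTA, labels).

    Feature order follows the FASTA file; counts columns are aligned to it
    by feature id. Every sample in the counts table must have a label.

    Raises
    ------
    DatasetError
        On any mismatch between the three files: counts columns absent from
        the FASTA (and vice versa), non-numeric or negative counts,
        duplicate sequences, unknown label words, or unlabeled samples.
    """
    label_map = {k.lower(): v for k, v in (label_map or DEFAULT_LABEL_MAP).items()}
    name = name or Path(counts_path).stem

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise DatasetError(f"{name}: FASTA {fasta_path} contains no records")
    feature_ids = [r.id for r in records]
    sequences = [str(r.seq).upper() for r in records]

    table = _read_table(counts_path, delimiter)
    sample_col = table.columns[0]
    count_cols = list(table.columns[1:])

    fasta_set, counts_set = set(feature_ids), set(count_cols)
    missing_in_fasta = [c for c in count_cols if c not in fasta_set]
    if missing_in_fasta:
        raise DatasetError(
            f"{name}: counts column {missing_in_fasta[0]!r} has no FASTA record"
        )
    missing_in_counts = [f for f in feature_ids if f not in counts_set]
    if missing_in_counts:
        raise DatasetError(
            f"{name}: FASTA record {missing_in_counts[0]!r} has no counts column"
        )

    sample_ids = [str(s) for s in table[sample_col]]
    raw = table[feature_ids]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        j = int(np.argwhere(numeric.isna().to_numpy())[0][1])
        i = int(np.argwhere(numeric.isna().to_numpy())[0][0])
        raise DatasetError(
            f"{name}: non-numeric count at sample {sample_ids[i]!r}, "
            f"feature {feature_ids[j]!r}"
        )
    counts = numeric.to_numpy()
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise DatasetError(
            f"{name}: negative count at sample {sample_ids[i]!r}, "
            f"feature {feature_ids[j]!r}"
        )
    counts = counts.astype(np.int64)

    lab_table = _read_table(labels_path, delimiter)
    lab_table.iloc[:, 0] = lab_table.iloc[:, 0].astype(str)
    group_of = dict(zip(lab_table.iloc[:, 0], lab_table.iloc[:, 1]))
    labels = []
    for s in sample_ids:
        if s not in group_of:
            raise DatasetError(f"{name}: sample {s!r} has no label")
        word = str(group_of[s]).strip().lower()
        if word not in label_map:
            raise DatasetError(
                f"{name}: unknown label {group_of[s]!r} for sample {s!r} "
                f"(known: {sorted(label_map)})"
            )
        labels.append(label_map[word])

    return AbundanceDataset(
        name=name,
        features=sequences,
        counts=counts,
        labels=np.array(labels),
        sample_ids=sample_ids,
    )


def write_abundance_dataset(
    dataset: AbundanceDataset,
    counts_path: str | Path,
    fasta_path: str | Path,
    labels_path: str | Path,
    *,
    delimiter: str = "\t",
) -> None:
    """Write the standard triple so that :func:`load_abundance_dataset`
    round-trips counts, labels and sequences exactly."""
    feature_ids = [f"{dataset.name}|f{i}" for i in range(dataset.n_features)]
    table = pd.DataFrame(dataset.counts, columns=feature_ids)
    table.insert(0, "sample_id", dataset.sample_ids)
    table.to_csv(counts_path, sep=delimiter, index=False)

    records = [
        SeqRecord(Seq(seq), id=fid, description="")
        for fid, seq in zip(feature_ids, dataset.features)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    lab = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "group": ["case" if y else "control" for y in dataset.labels],
        }
    )
    lab.to_csv(labels_path, sep=delimiter, index=False)


def write_signature(signature: FeatureSignature, path: str | Path) -> None:
    """Write a signature as FASTA, one record per sequence.

    Record ids are ``<source_dataset>|f<i>`` so the file round-trips
    through :func:`read_signature`.
    """
    if signature.size == 0:
        raise DatasetError("cannot write an empty signature")
    records = [
        SeqRecord(Seq(seq), id=f"{signature.source_dataset}|f{i}", description="")
        for i, seq in enumerate(signature.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_signature(path: str | Path, source_dataset: str | None = None) -> FeatureSignature:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DatasetError(f"signature FASTA {path} is empty")
    if source_dataset is None:
        source_dataset = records[0].id.rsplit("|", 1)[0]
    return FeatureSignature(
        source_dataset=source_dataset,
        sequences=[str(r.seq).upper() for r in records],
    )


# ---------------------------------------------------------------------------
# discovery-dataset eligibility
# ---------------------------------------------------------------------------


def select_discovery_dataset(
    datasets: list[AbundanceDataset],
    *,
    allow_fewer: bool = False,
    check_groups: bool = True,
) -> int:
    """Index of the dataset eligible for discovery.

    The discovery dataset is the one with the shortest ASV sequences —
    summarised as the smallest *median* feature length, tie-broken by the
    smallest mean length, then by input order — so that its features can be
    found by containment inside the longer sequences of the testing
    datasets. At least three datasets (one discovery + two testing) are
    required unless ``allow_fewer`` is set.
    """
    if len(datasets) < 3 and not allow_fewer:
        raise DatasetError(
            "cross-dataset testing needs at least three datasets "
            "(one discovery, two testing); pass allow_fewer=True to override"
        )
    if not datasets:
        raise DatasetError("no datasets given")
    if check_groups:
        for ds in datasets:
            ds.check_group_sizes()

    keys = []
    for i, ds in enumerate(datasets):
        lengths = [len(s) for s in ds.features]
        keys.append((statistics.median(lengths), statistics.fmean(lengths), i))
    return min(keys)[2]
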