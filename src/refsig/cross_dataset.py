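"""Testing phase: signature containment matching across datasets.

A discovery signature is carried to an independent testing dataset by
exact sequence containment: a discovery ASV matches a testing ASV when it
is a contiguous substring of it (the discovery dataset is the one with the
shortest trim, so its sequences can sit inside longer testing sequences).
When a discovery sequence occurs inside *n* testing features, the
abundances of those n occurrences are summed per sample into a single
aggregated column. The matched sub-table is then re-validated with the
5-classifier validation module on the testing dataset's own labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AbundanceDataset, DatasetError, FeatureSignature
from .validation import ValidationReport, validate_features

__all__ = ["SignatureMatch", "match_signature", "test_signature"]

MATCH_MODES = ("forward", "bidirectional")


@dataclass
class SignatureMatch:
    """Containment matches of a discovery signature in one testing dataset.

    ``per_feature`` has one row per signature sequence (matched testing
    column indices and occurrence count); ``matched_table`` holds only the
    sequences with >= 1 occurrence, its counts being per-sample sums over
    the matching testing columns.
    """

    signature: FeatureSignature
    testing_name: str
    per_feature: pd.DataFrame
    matched_table: AbundanceDataset

    @property
    def matched_count(self) -> int:
        return self.matched_table.n_features

    def report_frame(self) -> pd.DataFrame:
        out = self.per_feature.copy()
        out["matched_features"] = out["matched_features"].apply(
            lambda idx: ",".join(map(str, idx))
        )
        return out


def match_signature(
    signature: FeatureSignature,
    testing: AbundanceDataset,
    mode: str = "forward",
) -> SignatureMatch:
    """Locate each signature sequence in the testing dataset by containment.

    ``mode="forward"``: signature sequence s matches testing feature t iff
    s is a contiguous substring of t (exact characters, uppercase; IUPAC
    ambiguity codes only match themselves). ``mode="bidirectional"``
    additionally accepts t being a substring of s. A testing feature may
    match several signature sequences and then contributes its counts to
    each of their aggregated columns.
    """
    if mode not in MATCH_MODES:
        raise DatasetError(f"unknown match mode {mode!r}; use one of {MATCH_MODES}")
    if signature.size == 0:
        raise DatasetError("empty signature")

    rows = []
    matched_seqs: list[str] = []
    matched_cols: list[np.ndarray] = []
    for s in signature.sequences:
        if mode == "forward":
            hits = [j for j, t in enumerate(testing.features) if s in t]
        else:
            hits = [j for j, t in enumerate(testing.features) if s in t or t in s]
        rows.append(
            {"sequence": s, "matched_features": hits, "n_occurrences": len(hits)}
        )
        if hits:
            matched_seqs.append(s)
            matched_cols.append(testing.counts[:, hits].sum(axis=1))

    if matched_seqs:
        counts = np.column_stack(matched_cols)
    else:
        counts = np.zeros((testing.n_samples, 0), dtype=testing.counts.dtype)
    matched_table = AbundanceDataset(
        name=f"{testing.name}|{signature.source_dataset}-matched",
        features=matched_seqs,
        counts=counts,
        labels=testing.labels.copy(),
        sample_ids=list(testing.sample_ids),
    )
    return SignatureMatch(
        signature=signature,
        testing_name=testing.name,
        per_feature=pd.DataFrame(rows),
        matched_table=matched_table,
    )


def test_signature(
    signature: FeatureSignature,
    testing: AbundanceDataset,
    n_runs: int = 10,
    seed: int = 0,
    mode: str = "forward",
    n_folds: int = 10,
) -> tuple[SignatureMatch, ValidationReport]:
    """Match a signature in a testing dataset, then validate the found part.

    The validation module runs on the aggregated matched table with the
    testing dataset's labels; the report is annotated with how many of the
    signature's sequences were found.
    """
    match = match_signature(signature, testing, mode=mode)
    if match.matched_count == 0:
        raise DatasetError(
            f"no sequence of the {signature.size}-feature signature from "
            f"{signature.source_dataset!r} is contained in {testing.name!r}; "
            "the datasets may be incompatible (check trim lengths and regions)"
        )
    report = validate_features(
        match.matched_table, "all", n_runs=n_runs, seed=seed, n_folds=n_folds
    )
    report.dataset_name = testing.name
    report.matched_count = match.matched_count
    report.signature_size = signature.size
    return match, report
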