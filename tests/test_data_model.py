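"""Dataset loading, round-trips, and the discovery-eligibility rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refsig import (
    AbundanceDataset,
    DatasetError,
    FeatureSignature,
    load_abundance_dataset,
    read_signature,
    select_discovery_dataset,
    write_abundance_dataset,
    write_signature,
)


def toy_dataset() -> AbundanceDataset:
    return AbundanceDataset(
        name="toy",
        features=["ACGTACGT", "TTTTAAAA", "GGGGCCCC", "ACACACAC"],
        counts=np.array([[1, 0, 3, 2], [4, 5, 0, 1], [0, 2, 2, 9]]),
        labels=np.array([0, 0, 1]),
        sample_ids=["s1", "s2", "s3"],
    )


def write_triple(ds, tmp_path, tag="d"):
    paths = (
        tmp_path / f"{tag}_counts.tsv",
        tmp_path / f"{tag}.fasta",
        tmp_path / f"{tag}_labels.tsv",
    )
    write_abundance_dataset(ds, *paths)
    return paths


class TestLoadRoundTrip:
    def test_toy_round_trip(self, tmp_path):
        ds = toy_dataset()
        loaded = load_abundance_dataset(*write_triple(ds, tmp_path), name="toy")
        assert loaded.counts.shape == (3, 4)
        assert loaded.features == ds.features
        assert np.array_equal(loaded.counts, ds.counts)
        assert np.array_equal(loaded.labels, [0, 0, 1])
        assert loaded.sample_ids == ds.sample_ids

    def test_generated_family_round_trips(self, small_family, tmp_path):
        ds = small_family[0][0]
        loaded = load_abundance_dataset(*write_triple(ds, tmp_path), name=ds.name)
        assert loaded.features == ds.features
        assert np.array_equal(loaded.counts, ds.counts)
        assert np.array_equal(loaded.labels, ds.labels)

    def test_lowercase_fasta_is_uppercased(self, tmp_path):
        ds = toy_dataset()
        counts, fasta, labels = write_triple(ds, tmp_path)
        fasta.write_text(">toy|f0\nacgt\n>toy|f1\ntttt\n>toy|f2\ngggg\n>toy|f3\nacac\n")
        loaded = load_abundance_dataset(counts, fasta, labels)
        assert loaded.features[0] == "ACGT"

    def test_counts_column_missing_from_fasta(self, tmp_path):
        ds = toy_dataset()
        counts, fasta, labels = write_triple(ds, tmp_path)
        fasta.write_text(">toy|f0\nACGT\n>toy|f1\nTTTT\n>toy|f2\nGGGG\n")
        with pytest.raises(DatasetError, match="toy\\|f3"):
            load_abundance_dataset(counts, fasta, labels)

    def test_negative_and_non_numeric_counts(self, tmp_path):
        ds = toy_dataset()
        counts, fasta, labels = write_triple(ds, tmp_path)
        text = counts.read_text().replace("\t3\t", "\t-3\t")
        counts.write_text(text)
        with pytest.raises(DatasetError, match="negative"):
            load_abundance_dataset(counts, fasta, labels)
        counts.write_text(text.replace("-3", "oops"))
        with pytest.raises(DatasetError, match="non-numeric"):
            load_abundance_dataset(counts, fasta, labels)

    def test_duplicate_sequences_rejected(self, tmp_path):
        ds = toy_dataset()
        counts, fasta, labels = write_triple(ds, tmp_path)
        fasta.write_text(">toy|f0\nACGT\n>toy|f1\nACGT\n>toy|f2\nGGGG\n>toy|f3\nACAC\n")
        with pytest.raises(DatasetError, match="duplicate"):
            load_abundance_dataset(counts, fasta, labels)

    def test_unknown_and_missing_labels_rejected(self, tmp_path):
        ds = toy_dataset()
        counts, fasta, labels = write_triple(ds, tmp_path)
        labels.write_text("sample_id\tgroup\ns1\tcontrol\ns2\tweird\ns3\tcase\n")
        with pytest.raises(DatasetError, match="weird"):
            load_abundance_dataset(counts, fasta, labels)
        labels.write_text("sample_id\tgroup\ns1\tcontrol\ns3\tcase\n")
        with pytest.raises(DatasetError, match="s2"):
            load_abundance_dataset(counts, fasta, labels)

    def test_label_synonyms_configurable(self, tmp_path):
        ds = toy_dataset()
        counts, fasta, labels = write_triple(ds, tmp_path)
        labels.write_text("sample_id\tgroup\ns1\thealthy\ns2\thealthy\ns3\tsick\n")
        loaded = load_abundance_dataset(
            counts, fasta, labels, label_map={"healthy": 0, "sick": 1}
        )
        assert np.array_equal(loaded.labels, [0, 0, 1])


class TestSignatureIO:
    def test_round_trip(self, tmp_path):
        sig = FeatureSignature("disc", ["ACGTAC", "TTTTGG"])
        path = tmp_path / "sig.fasta"
        write_signature(sig, path)
        again = read_signature(path)
        assert again.sequences == sig.sequences
        assert again.source_dataset == "disc"

    def test_record_count_matches_size(self, tmp_path):
        seqs = ["".join(np.random.default_rng(i).choice(list("ACGT"), 30)) for i in range(26)]
        sig = FeatureSignature("disc", seqs)
        path = tmp_path / "sig26.fasta"
        write_signature(sig, path)
        assert path.read_text().count(">") == 26

    def test_empty_signature_errors(self, tmp_path):
        with pytest.raises(DatasetError):
            write_signature(FeatureSignature("disc", []), tmp_path / "x.fasta")


def _ds_with_lengths(name, lengths, n=20):
    rng = np.random.default_rng(hash(name) % 2**31)
    feats = []
    for i, L in enumerate(lengths):
        feats.append("".join(rng.choice(list("ACGT"), L)))
    return AbundanceDataset(
        name=name,
        features=feats,
        counts=rng.integers(0, 10, size=(n, len(feats))),
        labels=np.array([0] * (n // 2) + [1] * (n - n // 2)),
        sample_ids=[f"{name}{i}" for i in range(n)],
    )


class TestDiscoverySelection:
    def test_smallest_median_wins(self):
        dss = [
            _ds_with_lengths("a", [250] * 5),
            _ds_with_lengths("b", [230] * 5),
            _ds_with_lengths("c", [290] * 5),
        ]
        assert select_discovery_dataset(dss) == 1

    def test_tie_broken_by_mean(self):
        # both medians 230; means 231 vs 229
        a = _ds_with_lengths("a", [229, 230, 234])
        b = _ds_with_lengths("b", [227, 230, 230])
        c = _ds_with_lengths("c", [290] * 3)
        assert select_discovery_dataset([a, b, c]) == 1

    def test_fewer_than_three_requires_override(self):
        dss = [_ds_with_lengths("a", [100] * 3), _ds_with_lengths("b", [200] * 3)]
        with pytest.raises(DatasetError, match="three"):
            select_discovery_dataset(dss)
        assert select_discovery_dataset(dss, allow_fewer=True) == 0

    def test_group_size_rule_enforced(self):
        bad = _ds_with_lengths("a", [100] * 3, n=12)  # 6 per group < 10
        ok1 = _ds_with_lengths("b", [200] * 3)
        ok2 = _ds_with_lengths("c", [300] * 3)
        with pytest.raises(DatasetError, match=">= 10"):
            select_discovery_dataset([bad, ok1, ok2])

    def test_generated_family_shortest_trim_selected(self, small_family, small_spec):
        family, _ = small_family
        chosen = select_discovery_dataset(family)
        # independent brute-force scan over the generated sequences
        med = [np.median([len(s) for s in ds.features]) for ds in family]
        assert chosen == int(np.argmin(med))
        assert chosen == list(small_spec.trim_lengths).index(min(small_spec.trim_lengths))

    @given(perm=st.permutations(range(3)))
    def test_permutation_consistency(self, perm):
        dss = [
            _ds_with_lengths("a", [250] * 4),
            _ds_with_lengths("b", [230] * 4),
            _ds_with_lengths("c", [290] * 4),
        ]
        base = select_discovery_dataset(dss)
        shuffled = [dss[i] for i in perm]
        assert shuffled[select_discovery_dataset(shuffled)] is dss[base]
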