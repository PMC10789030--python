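"""REFS: elimination schedule, ensemble scoring, and selection behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refsig import (
    AbundanceDataset,
    DatasetError,
    RefsConfig,
    elimination_schedule,
    ensemble_feature_scores,
    refs_select,
)


def _schedule_oracle(n, keep=0.8, floor=1):
    # independent recursion: shrink by ceil(keep*F), at least one per step
    import math

    sizes = [n]
    while sizes[-1] > floor:
        nxt = min(math.ceil(keep * sizes[-1]), sizes[-1] - 1)
        if nxt < floor:
            break
        sizes.append(nxt)
    return sizes


class TestSchedule:
    def test_matches_recursion_from_2040(self):
        assert elimination_schedule(2040) == _schedule_oracle(2040)

    def test_26_is_a_visited_size_from_2040(self):
        assert 26 in elimination_schedule(2040)

    @given(
        n=st.integers(1, 3000),
        keep=st.floats(0.5, 0.95),
        floor=st.integers(1, 5),
    )
    def test_strictly_decreasing_and_bounded(self, n, keep, floor):
        if n < floor:
            return
        sizes = elimination_schedule(n, keep, floor)
        assert sizes[0] == n
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] >= floor


def _make_dataset(X, y, name="mk"):
    rng = np.random.default_rng(0)
    feats = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(X.shape[1])]
    return AbundanceDataset(
        name=name,
        features=feats,
        counts=np.asarray(X, dtype=int),
        labels=np.asarray(y),
        sample_ids=[f"s{i}" for i in range(len(y))],
    )


def _separating_dataset(rng, n_per_group=12, n_noise=9):
    """One feature cleanly splits the groups; the rest are i.i.d. noise."""
    n = 2 * n_per_group
    y = np.array([0] * n_per_group + [1] * n_per_group)
    X = rng.poisson(20, size=(n, n_noise + 1))
    X[:, 0] = np.where(y == 0, rng.poisson(5, n), rng.poisson(200, n))
    return _make_dataset(X, y)


class TestEnsembleScores:
    def test_perfect_feature_gets_top_score(self):
        hits = 0
        for seed in range(10):
            ds = _separating_dataset(np.random.default_rng(100 + seed))
            scores, acc, _ = ensemble_feature_scores(ds, np.arange(10), n_folds=5, seed=seed)
            if np.argmax(scores) == 0:
                hits += 1
        assert hits >= 9

    def test_duplicated_informative_columns_share_score(self):
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            ds = _separating_dataset(rng)
            X = np.column_stack([ds.counts, ds.counts[:, 0]])  # exact copy of col 0
            dup = _make_dataset(X, ds.labels)
            scores, _, _ = ensemble_feature_scores(dup, np.arange(11), n_folds=5, seed=seed)
            ratios.append(scores[10] / scores[0])
        assert abs(np.mean(ratios) - 1.0) < 0.10

    def test_permuted_labels_yield_chance_accuracy(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            X = rng.poisson(20, size=(40, 12))
            y = rng.permutation([0] * 20 + [1] * 20)
            ds = _make_dataset(X, y)
            _, acc, _ = ensemble_feature_scores(ds, np.arange(12), n_folds=5, seed=seed)
            accs.append(acc)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_empty_subset_rejected(self):
        ds = _separating_dataset(np.random.default_rng(1))
        with pytest.raises(DatasetError):
            ensemble_feature_scores(ds, [], n_folds=5)


@pytest.fixture(scope="module")
def small_discovery(small_family):
    family, truth = small_family
    disc = min(family, key=lambda d: len(d.features[0]))
    return disc, truth


@pytest.fixture(scope="module")
def refs_run(small_discovery):
    disc, _ = small_discovery
    return refs_select(disc, RefsConfig(n_runs=2, seed=0, n_folds=5))


class TestRefsSelect:
    def test_trajectory_follows_schedule(self, refs_run, small_discovery):
        disc, _ = small_discovery
        sizes = [s.n_features for s in refs_run.trajectory]
        assert sizes == elimination_schedule(disc.n_features, 0.8, 1)

    def test_selected_is_subset_with_size_on_trajectory(self, refs_run, small_discovery):
        disc, _ = small_discovery
        assert set(refs_run.selected.sequences) <= set(disc.features)
        assert refs_run.selected.size in [s.n_features for s in refs_run.trajectory]
        assert all(0.0 <= s.mean_accuracy <= 1.0 for s in refs_run.trajectory)

    def test_selected_step_has_max_accuracy_fewest_features(self, refs_run):
        traj = refs_run.per_run_trajectories[refs_run.best_run]
        best_acc = max(s.mean_accuracy for s in traj)
        candidates = [s.n_features for s in traj if s.mean_accuracy == best_acc]
        assert refs_run.selected.size == min(candidates)

    def test_selected_features_are_planted(self, refs_run, small_discovery):
        # strong planted signal: the signature is drawn almost entirely
        # from the truth set (at most one noise feature slips in)
        _, truth = small_discovery
        recovered = set(refs_run.selected.sequences) & set(truth.sequences)
        assert len(recovered) >= refs_run.selected.size - 1
        assert len(recovered) >= 3

    def test_run_agreement_range_and_best_run_membership(self, refs_run):
        assert set(refs_run.run_agreement) == set(refs_run.selected.sequences)
        assert all(0 < v <= 1 for v in refs_run.run_agreement.values())
        assert refs_run.per_run_selected[refs_run.best_run].sequences == refs_run.selected.sequences

    def test_deterministic(self, small_discovery):
        disc, _ = small_discovery
        cfg = RefsConfig(n_runs=1, seed=3, n_folds=5)
        r1 = refs_select(disc, cfg)
        r2 = refs_select(disc, cfg)
        assert r1.selected.sequences == r2.selected.sequences
        assert [s.mean_accuracy for s in r1.trajectory] == [
            s.mean_accuracy for s in r2.trajectory
        ]

    def test_min_features_equal_to_n_features_degenerate(self):
        ds = _separating_dataset(np.random.default_rng(4), n_noise=4)
        res = refs_select(ds, RefsConfig(n_runs=1, min_features=5, n_folds=5, seed=0))
        assert len(res.trajectory) == 1
        assert res.selected.size == 5
        assert set(res.selected.sequences) == set(ds.features)

    def test_constant_labels_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(10, size=(24, 5))
        ds = _make_dataset(X, np.zeros(24, dtype=int))
        with pytest.raises(DatasetError):
            refs_select(ds, RefsConfig(n_runs=1, n_folds=5))

    def test_too_many_folds_rejected(self):
        ds = _separating_dataset(np.random.default_rng(5))
        with pytest.raises(DatasetError, match="n_folds"):
            refs_select(ds, RefsConfig(n_runs=1, n_folds=13))
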