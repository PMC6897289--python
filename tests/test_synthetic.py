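import itertools
from collections import Counter

import numpy as np
import pytest

from oracle_helpers import rand_index_pairs
from rnastructclust import (
    SynthFamilySpec,
    adjusted_rand_index,
    mean_pairwise_identity,
    sample_family,
    shuffle_background,
    simulate_reactivities,
)
from rnastructclust.refine import Partition
from rnastructclust.synthetic import PAIR_TYPES, partition_labels

_CANONICAL = set(PAIR_TYPES)


class TestSampleFamily:
    def test_identity_one_gives_identical_members(self):
        recs, _ = sample_family(SynthFamilySpec(n_sequences=5, target_identity=1.0, seed=1))
        assert len({r.sequence for r in recs}) == 1

    def test_every_member_compatible_with_structure(self):
        recs, struct = sample_family(SynthFamilySpec(n_sequences=10, seed=2))
        for rec in recs:
            for i, j in struct.pairs:
                assert rec.sequence[i] + rec.sequence[j] in _CANONICAL

    def test_structure_satisfies_density_and_min_loop(self):
        spec = SynthFamilySpec(seed=3)
        _, struct = sample_family(spec)
        paired = 2 * len(struct.pairs) / struct.length
        assert paired >= 0.3
        for i, j in struct.pairs:
            assert j - i - 1 >= spec.min_loop

    def test_mean_pairwise_identity_near_target(self):
        recs, _ = sample_family(
            SynthFamilySpec(n_sequences=20, target_identity=0.7, seed=4)
        )
        mpi = mean_pairwise_identity([r.sequence for r in recs], max_pairs=100)
        assert mpi == pytest.approx(0.7, abs=0.05)

    def test_reproducible_given_seed(self):
        a, sa = sample_family(SynthFamilySpec(seed=5))
        b, sb = sample_family(SynthFamilySpec(seed=5))
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert sa.pairs == sb.pairs

    def test_infeasible_identity_rejected(self):
        with pytest.raises(ValueError):
            SynthFamilySpec(target_identity=0.2)


class TestSimulateReactivities:
    def test_unpaired_more_reactive_than_paired(self):
        _, struct = sample_family(SynthFamilySpec(structure_length=120, seed=6))
        prof = simulate_reactivities(struct, seed=1)
        paired = {i for p in struct.pairs for i in p}
        vp = [v for i, v in enumerate(prof.values) if i in paired]
        vu = [v for i, v in enumerate(prof.values) if i not in paired]
        assert np.mean(vu) > np.mean(vp)

    def test_same_seed_same_profile(self):
        _, struct = sample_family(SynthFamilySpec(seed=7))
        assert (
            simulate_reactivities(struct, seed=9).values
            == simulate_reactivities(struct, seed=9).values
        )

    def test_reactivity_ranks_separate_pairing_states(self):
        """Sorting positions by reactivity separates paired from unpaired."""
        rng = np.random.default_rng(8)
        paired_vals, unpaired_vals = [], []
        total = 0
        seed = 0
        while total < 1000:
            _, struct = sample_family(SynthFamilySpec(structure_length=100, seed=800 + seed))
            prof = simulate_reactivities(struct, seed=seed)
            paired = {i for p in struct.pairs for i in p}
            for i, v in enumerate(prof.values):
                (paired_vals if i in paired else unpaired_vals).append(v)
            total += struct.length
            seed += 1
        # empirical AUC via rank statistics
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(unpaired_vals, paired_vals, alternative="greater").statistic
        auc = u / (len(paired_vals) * len(unpaired_vals))
        assert auc >= 0.8


class TestShuffleBackground:
    def test_order1_preserves_base_composition(self, small_family):
        recs, _ = small_family
        decoys = shuffle_background(recs, 4, order=1, seed=3)
        for d, src in zip(decoys, recs):
            assert Counter(d.sequence) == Counter(src.sequence)

    def test_order2_preserves_dinucleotide_counts(self, small_family):
        recs, _ = small_family
        decoys = shuffle_background(recs, 8, order=2, seed=3)
        changed = 0
        for d, src in zip(decoys, itertools.cycle(recs)):
            dinucs = lambda s: Counter(s[i : i + 2] for i in range(len(s) - 1))
            assert dinucs(d.sequence) == dinucs(src.sequence)
            changed += d.sequence != src.sequence
        assert changed >= 6  # shuffles actually shuffle

    def test_zero_decoys(self, small_family):
        recs, _ = small_family
        assert shuffle_background(recs, 0, order=1, seed=1) == []

    def test_bad_order_rejected(self, small_family):
        recs, _ = small_family
        with pytest.raises(ValueError):
            shuffle_background(recs, 1, order=3, seed=1)


class TestAdjustedRandIndex:
    def test_identical_partitions_score_one(self):
        labels = {f"e{i}": i % 3 for i in range(12)}
        assert adjusted_rand_index(labels, dict(labels)).ari == pytest.approx(1.0)

    def test_all_in_one_vs_singletons_scores_zero(self):
        pred = {f"e{i}": 0 for i in range(8)}
        ref = {f"e{i}": i for i in range(8)}
        assert adjusted_rand_index(pred, ref).ari == pytest.approx(0.0)

    def test_rand_index_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 13))
            pred = {f"e{i}": int(rng.integers(1, 4)) for i in range(n)}
            ref = {f"e{i}": int(rng.integers(1, 4)) for i in range(n)}
            cmp = adjusted_rand_index(pred, ref)
            assert cmp.rand_index == pytest.approx(rand_index_pairs(pred, ref))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import adjusted_rand_score

        for _ in range(20):
            n = int(rng.integers(3, 30))
            ids = [f"e{i}" for i in range(n)]
            pred = {e: int(rng.integers(1, 5)) for e in ids}
            ref = {e: int(rng.integers(1, 5)) for e in ids}
            want = adjusted_rand_score(
                [ref[e] for e in ids], [pred[e] for e in ids]
            )
            assert adjusted_rand_index(pred, ref).ari == pytest.approx(want)

    def test_invariant_under_relabeling(self, rng):
        n = 20
        pred = {f"e{i}": int(rng.integers(0, 4)) for i in range(n)}
        ref = {f"e{i}": int(rng.integers(0, 4)) for i in range(n)}
        remap = {0: "w", 1: "x", 2: "y", 3: "z"}
        pred2 = {k: remap[v] for k, v in pred.items()}
        assert adjusted_rand_index(pred, ref).ari == pytest.approx(
            adjusted_rand_index(pred2, ref).ari
        )

    def test_element_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index({"a": 1, "b": 1}, {"a": 1, "c": 1})

    def test_unclustered_become_singletons(self):
        part = Partition(mode="hard", assignments={"a": {1}, "b": {1}}, unclustered={"c", "d"})
        labels = partition_labels(part, ["a", "b", "c", "d"])
        assert labels["a"] == labels["b"] == 1
        assert labels["c"] != labels["d"]

    def test_drop_policy_removes_unclustered(self):
        part = Partition(mode="hard", assignments={"a": {1}}, unclustered={"c"})
        labels = partition_labels(part, ["a", "c"], unclustered_policy="drop")
        assert set(labels) == {"a"}
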