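import itertools

import numpy as np
import pytest

from oracle_helpers import best_alignment_score_enum, best_subtree_leaves
from rnastructclust import (
    FoldParams,
    fold,
    parse_dotbracket,
)
from rnastructclust.kernel import SparseFeatureVector
from rnastructclust.refine import (
    GAP,
    MATCH,
    MISMATCH,
    STATE_BONUS,
    Cluster,
    _column_score,
    align_pair,
    centroid_vector,
    consensus_and_metrics,
    extend_cluster,
    pair_score,
    progressive_align,
    prune_cluster,
    report_partition,
    score_to_distance,
    self_score,
    upgma,
)


def win(seq, db):
    return (seq, parse_dotbracket(db))


class TestPairScore:
    def test_self_score_closed_form(self):
        x = win("GGGAAACCC", "(((...)))")
        assert pair_score(x, x) == 3.0 * 9

    def test_symmetry(self, rng):
        for _ in range(5):
            a_seq = "".join(rng.choice(list("ACGU"), size=12))
            b_seq = "".join(rng.choice(list("ACGU"), size=10))
            a, b = win(a_seq, "." * 12), win(b_seq, "." * 10)
            assert pair_score(a, b) == pair_score(b, a)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(8):
            na, nb = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            a_seq = "".join(rng.choice(list("ACGU"), size=na))
            b_seq = "".join(rng.choice(list("ACGU"), size=nb))
            a, b = (a_seq, fold(a_seq)), (b_seq, fold(b_seq))
            sa, sb = a[1].pair_state(), b[1].pair_state()

            def col(i, j):
                return _column_score(a_seq[i], sa[i], b_seq[j], sb[j])

            want = best_alignment_score_enum(a_seq, b_seq, col, GAP)
            assert pair_score(a, b) == pytest.approx(want)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair(("", parse_dotbracket("")), win("A", "."))


class TestUpgma:
    def test_two_leaves_root_at_half_distance(self):
        tree = upgma(["a", "b"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        assert tree.height == pytest.approx(2.0)
        assert tree.leaves == ("a", "b")

    def test_three_leaves_hand_executed(self):
        D = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
        tree = upgma(["A", "B", "C"], D)
        assert tree.height == pytest.approx(4.0)
        (first,) = [c for c in tree.children if not c.is_leaf]
        assert first.leaves == ("A", "B")
        assert first.height == pytest.approx(1.0)

    def test_ultrametric_on_random_matrices(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 9))
            M = rng.random((n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = upgma([f"l{i}" for i in range(n)], D)

            def leaf_depths(node, acc=0.0):
                # depth from root down to each leaf along merge heights
                if node.is_leaf:
                    return [acc + node.height]
                return [d for c in node.children for d in leaf_depths(c, 0.0)]

            # root height is max; every leaf-to-root path spans root.height
            def check(node):
                if node.is_leaf:
                    return
                for c in node.children:
                    assert c.height <= node.height + 1e-9
                    check(c)

            check(tree)

    def test_invalid_distances_rejected(self):
        with pytest.raises(ValueError):
            upgma(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            upgma(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]))

    def test_agrees_with_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        for _ in range(5):
            n = int(rng.integers(4, 10))
            M = rng.random((n, n)) + 0.01
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = upgma([f"l{i}" for i in range(n)], D)
            Z = average(squareform(D, checks=False))
            assert tree.height == pytest.approx(Z[-1, 2] / 2.0)


class TestPrune:
    def block_scores(self, ids, high, low, block):
        scores = {}
        for a, b in itertools.combinations(ids, 2):
            val = high if a in block and b in block else low
            scores[frozenset((a, b))] = val
        return scores

    def test_planted_block_recovered(self):
        ids = ["a", "b", "c", "d", "e"]
        scores = self.block_scores(ids, 0.9, 0.1, {"a", "b", "c"})
        D = np.zeros((5, 5))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i != j:
                    D[i, j] = 1.0 - scores[frozenset((x, y))]
        tree = upgma(ids, D)
        assert prune_cluster(tree, scores, 3) == ("a", "b", "c")

    def test_uniform_scores_keep_everything(self):
        ids = ["a", "b", "c", "d"]
        scores = {frozenset(p): 0.5 for p in itertools.combinations(ids, 2)}
        D = np.ones((4, 4)) * 0.5
        np.fill_diagonal(D, 0.0)
        tree = upgma(ids, D)
        assert prune_cluster(tree, scores, 2) == ("a", "b", "c", "d")

    def test_unsatisfiable_min_size_gives_empty(self):
        ids = ["a", "b"]
        scores = {frozenset(("a", "b")): 1.0}
        tree = upgma(ids, np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert prune_cluster(tree, scores, 3) == ()

    def test_matches_exhaustive_subtree_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 11))
            ids = [f"l{i}" for i in range(n)]
            M = rng.random((n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = upgma(ids, D)
            scores = {
                frozenset((ids[i], ids[j])): float(1.0 - D[i, j])
                for i in range(n)
                for j in range(i + 1, n)
            }
            min_size = int(rng.integers(2, 5))
            assert prune_cluster(tree, scores, min_size) == best_subtree_leaves(
                tree, scores, min_size
            )


class TestProgressiveAlign:
    def align(self, items):
        ids = sorted(items)
        n = len(ids)
        D = np.zeros((n, n))
        for i, a in enumerate(ids):
            for j in range(i + 1, n):
                b = ids[j]
                s = pair_score(items[a], items[b])
                D[i, j] = D[j, i] = score_to_distance(
                    s, self_score(items[a]), self_score(items[b])
                )
        return progressive_align(items, upgma(ids, D))

    def test_identical_sequences_align_without_gaps(self):
        items = {"a": win("GGGAAACCC", "(((...)))"), "b": win("GGGAAACCC", "(((...)))")}
        aln = self.align(items)
        assert aln.rows["a"] == "GGGAAACCC"
        assert aln.rows["b"] == "GGGAAACCC"

    def test_rows_reconstruct_members(self, small_family):
        recs, struct = small_family
        items = {r.id: (r.sequence, fold(r.sequence)) for r in recs[:4]}
        aln = self.align(items)
        assert len(aln.ids) == 4
        for rid, (seq, _) in items.items():
            assert aln.rows[rid].replace("-", "") == seq

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({"a": win("ACGU", "....")}, None)


class TestConsensusAndMetrics:
    def test_identical_rows_reproduce_structure(self):
        seq = "GGGAAACCC"
        struct = fold(seq)
        items = {f"m{i}": (seq, struct) for i in range(3)}
        aln = TestProgressiveAlign().align(items)
        consensus, sci, cov = consensus_and_metrics(
            aln, {k: struct for k in items}, FoldParams()
        )
        assert consensus.pairs == struct.pairs
        assert sci == pytest.approx(1.0)
        assert cov == 0

    def test_compensatory_pair_counted(self):
        # two rows G-C, two rows A-U at the single consensus pair
        items = {}
        for i, (l, r) in enumerate([("G", "C"), ("G", "C"), ("A", "U"), ("A", "U")]):
            seq = l + "AAA" + r
            items[f"m{i}"] = (seq, parse_dotbracket("(...)"))
        aln = TestProgressiveAlign().align(items)
        consensus, sci, cov = consensus_and_metrics(
            aln, {k: v[1] for k, v in items.items()}, FoldParams()
        )
        assert (0, 4) in consensus.pairs
        assert cov >= 1

    def test_low_sci_detectable(self):
        # unrelated unstructured rows: consensus scores ~0 and sci 0
        items = {
            "a": ("AAAAAAAA", parse_dotbracket("........")),
            "b": ("AAAAAAAA", parse_dotbracket("........")),
        }
        aln = TestProgressiveAlign().align(items)
        consensus, sci, cov = consensus_and_metrics(
            aln, {k: v[1] for k, v in items.items()}, FoldParams()
        )
        assert sci == 0.0


class TestExtension:
    def unit_vec(self, support):
        n = len(support) ** 0.5
        return SparseFeatureVector(entries={k: 1.0 / n for k in support}, bits=20)

    def test_identical_window_recruited(self):
        vectors = {
            "m1": self.unit_vec(range(10)),
            "m2": self.unit_vec(range(10)),
            "new": self.unit_vec(range(10)),
        }
        added, centroid, sims = extend_cluster(["m1", "m2"], vectors, ["new"], 0.5)
        assert added == ["new"]
        assert sims["new"] == pytest.approx(1.0)

    def test_threshold_above_one_blocks_everything(self):
        vectors = {
            "m1": self.unit_vec(range(10)),
            "new": self.unit_vec(range(10)),
        }
        added, _, _ = extend_cluster(["m1"], vectors, ["new"], 1.01)
        assert added == []


class TestPartition:
    def make_cluster(self, cid, members, sims):
        return Cluster(
            cluster_id=cid,
            members=members,
            sources={m: "initial" for m in members},
            alignment=None,
            consensus_structure=None,
            metrics={},
            member_similarities=sims,
        )

    def test_hard_mode_disjoint(self):
        c1 = self.make_cluster(1, ["a", "b", "x"], {"a": 0.9, "b": 0.9, "x": 0.7})
        c2 = self.make_cluster(2, ["c", "x"], {"c": 0.9, "x": 0.8})
        part = report_partition([c1, c2], "hard")
        assert part.assignments["x"] == {2}
        ms = [set(part.assignments[m]) for m in ("a", "b", "c")]
        assert all(len(s) == 1 for s in ms)

    def test_soft_mode_keeps_overlap(self):
        c1 = self.make_cluster(1, ["a", "x"], {"a": 0.9, "x": 0.7})
        c2 = self.make_cluster(2, ["b", "x"], {"b": 0.9, "x": 0.8})
        part = report_partition([c1, c2], "soft")
        assert part.assignments["x"] == {1, 2}

    def test_equal_claim_goes_to_lower_cluster_id(self):
        c2 = self.make_cluster(2, ["x", "a", "b"], {"x": 0.5, "a": 1.0, "b": 1.0})
        c5 = self.make_cluster(5, ["x", "c", "d"], {"x": 0.5, "c": 1.0, "d": 1.0})
        part = report_partition([c5, c2], "hard")
        assert part.assignments["x"] == {2}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            report_partition([], "fuzzy")
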