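"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming / hashing code
paths: structures are enumerated explicitly, kernels are counted on raw
feature keys, alignments are enumerated recursively, and partition agreement
is counted pair by pair.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

_CANONICAL = {"GC": 3.0, "CG": 3.0, "AU": 2.0, "UA": 2.0, "GU": 1.0, "UG": 1.0}


def enumerate_nested_structures(n: int, min_loop: int = 3) -> list[frozenset]:
    """All nested pair sets over n positions (every pair respects min_loop)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[frozenset, ...]:
        # structures over the half-open interval [i, j), decomposed by the
        # status of position j-1 (unpaired, or paired with some k)
        if j - i < min_loop + 2:
            return (frozenset(),)
        out = list(rec(i, j - 1))
        for k in range(i, j - 1 - min_loop):
            for left in rec(i, k):
                for inner in rec(k + 1, j - 1):
                    out.append(left | inner | {(k, j - 1)})
        return tuple(out)

    return list(rec(0, n))


def best_fold_score_enum(
    sequence: str,
    pair_scores: dict[str, float] | None = None,
    pseudo: list[float] | None = None,
    lam: float = 1.0,
    min_loop: int = 3,
) -> float:
    """Maximum fold objective by exhaustive enumeration (sequences <= ~14)."""
    table = pair_scores or _CANONICAL
    best = 0.0
    for struct in enumerate_nested_structures(len(sequence), min_loop):
        total = 0.0
        ok = True
        for i, j in struct:
            w = table.get(sequence[i] + sequence[j])
            if w is None:
                ok = False
                break
            total += w
            if pseudo is not None:
                total -= lam * (pseudo[i] + pseudo[j])
        if ok and total > best:
            best = total
    return best


def unhashed_kernel_similarity(graph_a, graph_b, params) -> float:
    """Kernel value from raw (r, d, label, label) keys, no hash folding."""
    from rnastructclust.kernel import block_normalize, iter_feature_keys

    def vec(graph):
        counts: dict[tuple, float] = {}
        for key in iter_feature_keys(graph, params):
            counts[key] = counts.get(key, 0.0) + 1.0
        return block_normalize(counts)

    va, vb = vec(graph_a), vec(graph_b)
    return sum(w * vb.get(k, 0.0) for k, w in va.items())


def best_alignment_score_enum(a, b, column_score, gap: float) -> float:
    """Optimal global alignment score by recursion (tiny inputs only)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return 0.0
        best = float("-inf")
        if i > 0 and j > 0:
            best = max(best, rec(i - 1, j - 1) + column_score(i - 1, j - 1))
        if i > 0:
            best = max(best, rec(i - 1, j) + gap)
        if j > 0:
            best = max(best, rec(i, j - 1) + gap)
        return best

    return rec(len(a), len(b))


def best_subtree_leaves(tree, scores, min_size):
    """Independent exhaustive subtree scan (recursive walk, own tie rule)."""
    best_key, best_leaves = None, ()

    def walk(node):
        nonlocal best_key, best_leaves
        leaves = node.leaves
        if len(leaves) >= min_size:
            pairs = list(itertools.combinations(leaves, 2))
            mean = sum(scores[frozenset(p)] for p in pairs) / len(pairs)
            key = (-mean, -len(leaves), leaves)
            if best_key is None or key < best_key:
                best_key, best_leaves = key, leaves
        for child in node.children:
            walk(child)

    walk(tree)
    return best_leaves


def rand_index_pairs(labels_a: dict, labels_b: dict) -> float:
    """Rand index by explicit pair counting."""
    ids = sorted(labels_a)
    agree = total = 0
    for x, y in itertools.combinations(ids, 2):
        same_a = labels_a[x] == labels_a[y]
        same_b = labels_b[x] == labels_b[y]
        agree += same_a == same_b
        total += 1
    return agree / total
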