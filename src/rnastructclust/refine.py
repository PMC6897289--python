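"""Cluster refinement: UPGMA pruning, progressive alignment, consensus
structure and conservation metrics, centroid extension, and partitions.

Each dense-neighborhood candidate is refined by (1) scoring all member pairs
with a sequence-structure alignment, (2) building a UPGMA tree from the
score-derived distances and keeping the subtree with the highest average
pairwise alignment score, (3) progressively aligning the surviving members
along the tree, (4) predicting a consensus structure over alignment columns
and annotating it with a structure conservation index (SCI) and a
compensatory-double-substitution count, and (5) scanning the unclustered
windows against the cluster's feature-space centroid to pull in homologs the
hashing stage missed.  The stage boundaries mirror a pipeline in which
heavier domain tools (a simultaneous-alignment aligner, covariance-model
search) can be slotted in behind the same interfaces.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .folding import (
    FoldParams,
    SecondaryStructure,
    fold,
    fold_objective,
    maximize_nested_pairing,
)
from .kernel import SparseFeatureVector, similarity

# alignment scoring: match/mismatch on residues, bonus for agreeing pairing
# state (opening / closing / unpaired), linear gap penalty
MATCH = 2.0
MISMATCH = -1.0
STATE_BONUS = 1.0
GAP = -2.0

_PAIRABLE = frozenset({"GC", "CG", "AU", "UA", "GU", "UG"})


# ---------------------------------------------------------------------------
# pairwise sequence-structure alignment
# ---------------------------------------------------------------------------

def _column_score(ca: str, sa: str, cb: str, sb: str) -> float:
    s = MATCH if ca == cb else MISMATCH
    if sa == sb:
        s += STATE_BONUS
    return s


def align_pair(
    a: tuple[str, SecondaryStructure], b: tuple[str, SecondaryStructure]
) -> tuple[float, str, str]:
    """Global sequence-structure alignment of two windows.

    Returns ``(score, gapped_a, gapped_b)``.  Traceback prefers diagonal,
    then the gap in the second sequence, for determinism.
    """
    seq_a, st_a = a[0], a[1].pair_state()
    seq_b, st_b = b[0], b[1].pair_state()
    n, m = len(seq_a), len(seq_b)
    if n == 0 or m == 0:
        raise ValueError("cannot align an empty sequence")
    M = np.empty((n + 1, m + 1))
    M[0, :] = GAP * np.arange(m + 1)
    M[:, 0] = GAP * np.arange(n + 1)
    for i in range(1, n + 1):
        row_p, row = M[i - 1], M[i]
        ca, sa = seq_a[i - 1], st_a[i - 1]
        for j in range(1, m + 1):
            diag = row_p[j - 1] + _column_score(ca, sa, seq_b[j - 1], st_b[j - 1])
            up = row_p[j] + GAP
            left = row[j - 1] + GAP
            row[j] = diag if diag >= up and diag >= left else (up if up >= left else left)
    ga, gb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and math.isclose(
            M[i, j],
            M[i - 1, j - 1]
            + _column_score(seq_a[i - 1], st_a[i - 1], seq_b[j - 1], st_b[j - 1]),
        ):
            ga.append(seq_a[i - 1]); gb.append(seq_b[j - 1]); i -= 1; j -= 1
        elif i > 0 and math.isclose(M[i, j], M[i - 1, j] + GAP):
            ga.append(seq_a[i - 1]); gb.append("-"); i -= 1
        else:
            ga.append("-"); gb.append(seq_b[j - 1]); j -= 1
    return float(M[n, m]), "".join(reversed(ga)), "".join(reversed(gb))


def pair_score(
    a: tuple[str, SecondaryStructure], b: tuple[str, SecondaryStructure]
) -> float:
    """Optimal global alignment score of two (sequence, structure) windows."""
    return align_pair(a, b)[0]


def self_score(a: tuple[str, SecondaryStructure]) -> float:
    # every self-alignment column scores MATCH + STATE_BONUS
    return (MATCH + STATE_BONUS) * len(a[0])


def score_to_distance(score: float, self_a: float, self_b: float) -> float:
    """Map an alignment score to [0, 1]: 0 = as similar as a self-alignment."""
    denom = max(self_a, self_b)
    if denom <= 0:
        return 1.0
    return min(1.0, max(0.0, 1.0 - score / denom))


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UpgmaNode:
    """Node of an ultrametric average-linkage tree (binary; leaves height 0)."""

    leaves: tuple[str, ...]  # sorted leaf ids under this node
    height: float
    children: tuple["UpgmaNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def subtrees(self) -> list["UpgmaNode"]:
        out = [self]
        for c in self.children:
            out.extend(c.subtrees())
        return out


def upgma(ids: Sequence[str], distances: np.ndarray) -> UpgmaNode:
    """Average-linkage agglomeration with a deterministic tie-break.

    ``distances`` is a symmetric matrix with zero diagonal, indexed like
    ``ids``.  At equal merge distances the lexicographically smallest pair of
    (sorted) member-id tuples is merged first.  Node height is half the
    average-linkage distance at the merge, so the tree is ultrametric.
    """
    n = len(ids)
    if distances.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if np.any(~np.isfinite(distances)) or np.any(distances < 0):
        raise ValueError("distances must be finite and non-negative")
    if not np.allclose(distances, distances.T) or np.any(np.diag(distances) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes: list[UpgmaNode] = [UpgmaNode(leaves=(i,), height=0.0) for i in ids]
    D = {frozenset((i, j)): float(distances[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    store: dict[int, UpgmaNode] = {i: nodes[i] for i in active}
    size: dict[int, int] = {i: 1 for i in active}
    next_id = n
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            d = D[frozenset((a, b))]
            key = (d, store[a].leaves, store[b].leaves)
            if best is None or key < best[0]:
                best = (key, a, b)
        a, b = best[1], best[2]
        d_ab = D[frozenset((a, b))]
        merged = UpgmaNode(
            leaves=tuple(sorted(store[a].leaves + store[b].leaves)),
            height=d_ab / 2.0,
            children=(store[a], store[b]),
        )
        for c in active:
            if c in (a, b):
                continue
            d_new = (size[a] * D[frozenset((a, c))] + size[b] * D[frozenset((b, c))]) / (
                size[a] + size[b]
            )
            D[frozenset((next_id, c))] = d_new
        store[next_id] = merged
        size[next_id] = size[a] + size[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return store[active[0]]


def prune_cluster(
    tree: UpgmaNode, scores: dict[frozenset, float], min_size: int
) -> tuple[str, ...]:
    """Leaf set of the subtree with the highest mean pairwise alignment score.

    Considers every subtree with at least ``min_size`` leaves; ties go to the
    larger subtree, then to the lexicographically smallest leaf set.  Returns
    an empty tuple when no subtree is large enough (candidate rejected).
    """
    best: Optional[tuple] = None
    for node in tree.subtrees():
        leaves = node.leaves
        if len(leaves) < min_size:
            continue
        pairs = list(itertools.combinations(leaves, 2))
        mean = sum(scores[frozenset(p)] for p in pairs) / len(pairs)
        key = (-mean, -len(leaves), leaves)
        if best is None or key < best[0]:
            best = (key, leaves)
    return best[1] if best is not None else ()


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A gapped multiple alignment with per-row pairing-state strings."""

    ids: list[str]
    rows: dict[str, str]  # id -> gapped sequence over {A,C,G,U,N,-}
    states: dict[str, str]  # id -> gapped '(' ')' '.' string ('-' at gaps)

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    def column(self, c: int) -> list[tuple[str, str]]:
        return [(self.rows[i][c], self.states[i][c]) for i in self.ids]

    def mean_pairwise_identity(self) -> float:
        total, count = 0.0, 0
        for a, b in itertools.combinations(self.ids, 2):
            ra, rb = self.rows[a], self.rows[b]
            both = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
            if both:
                total += sum(x == y for x, y in both) / len(both)
                count += 1
        return total / count if count else 0.0


def _profile_column_score(ca: list[tuple[str, str]], cb: list[tuple[str, str]]) -> float:
    total = 0.0
    for (xa, sa) in ca:
        for (xb, sb) in cb:
            if xa == "-" and xb == "-":
                continue
            if xa == "-" or xb == "-":
                total += GAP
            else:
                total += _column_score(xa, sa, xb, sb)
    return total / (len(ca) * len(cb))


def _gap_column_score(col: list[tuple[str, str]]) -> float:
    return GAP * sum(1 for x, _ in col if x != "-") / len(col)


def _merge_profiles(A: Alignment, B: Alignment) -> Alignment:
    na, nb = A.n_cols, B.n_cols
    cols_a = [A.column(c) for c in range(na)]
    cols_b = [B.column(c) for c in range(nb)]
    gap_a = [_gap_column_score(c) for c in cols_a]
    gap_b = [_gap_column_score(c) for c in cols_b]
    M = np.empty((na + 1, nb + 1))
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        M[i, 0] = M[i - 1, 0] + gap_a[i - 1]
    for j in range(1, nb + 1):
        M[0, j] = M[0, j - 1] + gap_b[j - 1]
    S = np.empty((na, nb))
    for i in range(na):
        for j in range(nb):
            S[i, j] = _profile_column_score(cols_a[i], cols_b[j])
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            M[i, j] = max(
                M[i - 1, j - 1] + S[i - 1, j - 1],
                M[i - 1, j] + gap_a[i - 1],
                M[i, j - 1] + gap_b[j - 1],
            )
    # traceback: diagonal preferred, then consuming from A
    path: list[tuple[str, int]] = []
    i, j = na, nb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and math.isclose(M[i, j], M[i - 1, j - 1] + S[i - 1, j - 1]):
            path.append(("d", i - 1)); i -= 1; j -= 1
        elif i > 0 and math.isclose(M[i, j], M[i - 1, j] + gap_a[i - 1]):
            path.append(("a", i - 1)); i -= 1
        else:
            path.append(("b", j - 1)); j -= 1
    path.reverse()
    rows: dict[str, list[str]] = {i_: [] for i_ in A.ids + B.ids}
    states: dict[str, list[str]] = {i_: [] for i_ in A.ids + B.ids}
    ai = bi = 0
    for kind, _ in path:
        if kind in ("d", "a"):
            for rid in A.ids:
                rows[rid].append(A.rows[rid][ai]); states[rid].append(A.states[rid][ai])
        else:
            for rid in A.ids:
                rows[rid].append("-"); states[rid].append("-")
        if kind in ("d", "b"):
            for rid in B.ids:
                rows[rid].append(B.rows[rid][bi]); states[rid].append(B.states[rid][bi])
        else:
            for rid in B.ids:
                rows[rid].append("-"); states[rid].append("-")
        if kind in ("d", "a"):
            ai += 1
        if kind in ("d", "b"):
            bi += 1
    return Alignment(
        ids=A.ids + B.ids,
        rows={k: "".join(v) for k, v in rows.items()},
        states={k: "".join(v) for k, v in states.items()},
    )


def progressive_align(
    members: dict[str, tuple[str, SecondaryStructure]], tree: UpgmaNode
) -> Alignment:
    """Profile-profile alignment along the guide tree's merge order."""
    if len(members) < 2:
        raise ValueError("progressive alignment needs at least 2 members")

    def build(node: UpgmaNode) -> Alignment:
        if node.is_leaf:
            rid = node.leaves[0]
            seq, struct = members[rid]
            return Alignment(ids=[rid], rows={rid: seq}, states={rid: struct.pair_state()})
        left, right = node.children
        return _merge_profiles(build(left), build(right))

    # restrict the tree to the member set (tree may cover pruned-away leaves)
    def restrict(node: UpgmaNode) -> Optional[UpgmaNode]:
        if node.is_leaf:
            return node if node.leaves[0] in members else None
        kept = [r for r in (restrict(c) for c in node.children) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return UpgmaNode(
            leaves=tuple(sorted(l for k in kept for l in k.leaves)),
            height=node.height,
            children=tuple(kept),
        )

    sub = restrict(tree)
    assert sub is not None and set(sub.leaves) == set(members)
    return build(sub)


# ---------------------------------------------------------------------------
# consensus structure and conservation metrics
# ---------------------------------------------------------------------------

def consensus_and_metrics(
    alignment: Alignment,
    member_structures: dict[str, SecondaryStructure],
    fold_params: FoldParams = FoldParams(),
    min_pair_support: float = 0.5,
) -> tuple[SecondaryStructure, float, int]:
    """Consensus structure over alignment columns, SCI, and covariation count.

    The consensus is the maximum-score nested pairing of columns where a
    column pair scores ``(fraction of rows pairable) * (mean pair weight over
    pairable rows)`` and is admissible only when at least ``min_pair_support``
    of the rows can form a canonical pair.  SCI divides the consensus score
    by the mean of the members' individual fold objectives (0 when that mean
    is 0).  A consensus pair counts as covarying when >= 2 rows differ from
    the majority residue pair at both positions while remaining pairable.
    """
    if len(alignment.ids) < 2:
        raise ValueError("need >= 2 rows")
    ncols = alignment.n_cols
    nrows = len(alignment.ids)
    table = fold_params.score_table
    rows = [alignment.rows[i] for i in alignment.ids]
    S = np.full((ncols, ncols), -np.inf)
    for c1 in range(ncols):
        for c2 in range(c1 + fold_params.min_loop + 1, ncols):
            weights = [
                table[r[c1] + r[c2]]
                for r in rows
                if r[c1] != "-" and r[c2] != "-" and (r[c1] + r[c2]) in table
            ]
            if not weights:
                continue
            frac = len(weights) / nrows
            if frac < min_pair_support:
                continue
            S[c1, c2] = frac * (sum(weights) / len(weights))
    consensus_score, pairs = maximize_nested_pairing(S, fold_params.min_loop)
    consensus = SecondaryStructure(length=ncols, pairs=pairs)

    member_scores = []
    for rid in alignment.ids:
        seq = alignment.rows[rid].replace("-", "")
        member_scores.append(fold_objective(member_structures[rid], seq, fold_params))
    mean_member = sum(member_scores) / len(member_scores)
    sci = consensus_score / mean_member if mean_member > 0 else 0.0

    covarying = 0
    for c1, c2 in sorted(pairs):
        duos = [
            r[c1] + r[c2]
            for r in rows
            if r[c1] != "-" and r[c2] != "-" and (r[c1] + r[c2]) in table
        ]
        if not duos:
            continue
        counts: dict[str, int] = {}
        for d in duos:
            counts[d] = counts.get(d, 0) + 1
        majority = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        n_cov = sum(
            1 for d in duos if d[0] != majority[0] and d[1] != majority[1]
        )
        if n_cov >= 2:
            covarying += 1
    return consensus, float(sci), covarying


# ---------------------------------------------------------------------------
# clusters, extension, partitions
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    cluster_id: int
    members: list[str]
    sources: dict[str, str]  # member -> "initial" | "extended"
    alignment: Optional[Alignment]
    consensus_structure: Optional[SecondaryStructure]
    metrics: dict
    centroid: Optional[SparseFeatureVector] = None
    member_similarities: dict[str, float] = field(default_factory=dict)


@dataclass
class Partition:
    mode: str  # "hard" | "soft"
    assignments: dict[str, set[int]]
    unclustered: set[str]


def centroid_vector(vectors: Sequence[SparseFeatureVector]) -> SparseFeatureVector:
    """L2-normalized mean of a set of normalized sparse vectors."""
    acc: dict[int, float] = {}
    bits = vectors[0].bits
    for v in vectors:
        if v.bits != bits:
            raise ValueError("mixed feature spaces")
        for k, w in v.entries.items():
            acc[k] = acc.get(k, 0.0) + w
    n = len(vectors)
    acc = {k: w / n for k, w in acc.items()}
    norm = sum(w * w for w in acc.values()) ** 0.5
    if norm > 0:
        acc = {k: w / norm for k, w in acc.items()}
    return SparseFeatureVector(entries=acc, bits=bits)


def extend_cluster(
    cluster_members: Sequence[str],
    vectors: dict[str, SparseFeatureVector],
    candidate_ids: Sequence[str],
    extension_threshold: float = 0.5,
) -> tuple[list[str], SparseFeatureVector, dict[str, float]]:
    """Centroid-similarity scan standing in for a profile-model search.

    Returns ``(new_member_ids, centroid, similarity of every member and
    recruit to the centroid)``.  Deterministic: candidates are scanned in
    sorted order.
    """
    centroid = centroid_vector([vectors[m] for m in cluster_members])
    sims = {m: similarity(centroid, vectors[m]) for m in cluster_members}
    added: list[str] = []
    for wid in sorted(candidate_ids):
        if wid in sims:
            continue
        s = similarity(centroid, vectors[wid])
        if s >= extension_threshold:
            added.append(wid)
            sims[wid] = s
    return added, centroid, sims


def report_partition(clusters: Sequence[Cluster], mode: str = "hard") -> Partition:
    """Final assignment of members to clusters.

    Soft mode keeps overlaps; hard mode gives every multiply-claimed member
    to the cluster where its similarity to the centroid is highest (ties to
    the lower cluster id), guaranteeing pairwise-disjoint member sets.
    """
    if mode not in ("hard", "soft"):
        raise ValueError(f"unknown partition mode {mode!r}")
    assignments: dict[str, set[int]] = {}
    for cl in clusters:
        for m in cl.members:
            assignments.setdefault(m, set()).add(cl.cluster_id)
    if mode == "hard":
        by_id = {cl.cluster_id: cl for cl in clusters}
        for m, cids in assignments.items():
            if len(cids) <= 1:
                continue
            best = sorted(
                cids, key=lambda cid: (-by_id[cid].member_similarities.get(m, 0.0), cid)
            )[0]
            assignments[m] = {best}
    return Partition(mode=mode, assignments=assignments, unclustered=set())
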