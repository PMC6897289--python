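"""Linear-time dense-neighborhood detection via MinHash and inverse indexing.

Signatures are computed on the unweighted feature support, so signature
agreement estimates the Jaccard similarity of two windows' feature sets.
Banded slices of the signatures feed an inverse index; windows co-occurring
in at least one band bucket are neighbor candidates, which caps the work per
window at a constant for fixed signature parameters and makes the stage
linear in the number of windows.  Exact weighted similarity to the candidate
center is used only for the final member ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .kernel import SparseFeatureVector, similarity

logger = logging.getLogger("rnastructclust")

_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True, eq=False)
class MinHashSignature:
    values: np.ndarray  # K uint64 slot minima
    seed: int

    @property
    def K(self) -> int:
        return len(self.values)

    @property
    def is_sentinel(self) -> bool:
        return bool((self.values == _SENTINEL).all())


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the fast-clustering stage (all CLI-exposed).

    The inverse index maps every single signature slot value to the windows
    holding it; two windows with support Jaccard J are expected to collide in
    ``K * J`` slots, so the collision count is a sensitive neighbor detector
    even at the modest Jaccard levels that diverged homologs reach.  Buckets
    larger than ``max_bucket`` (features shared by a large fraction of the
    data) are skipped, which keeps per-window work bounded.
    """

    K: int = 512
    min_collisions: int = 8  # slots two windows must share to be neighbors
    max_bucket: int = 200
    seed: int = 42
    min_cluster_size: int = 3
    max_cluster_size: int = 25
    max_candidates: int = 50
    min_density: float = 0.4
    density_top: int = 3  # density = mean similarity of this many top members
    min_member_fraction: float = 0.25  # member floor relative to density
    max_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


@dataclass
class ClusterCandidate:
    """A dense neighborhood seed: a center window and its ranked neighbors."""

    center_id: str
    member_ids: list[str]  # ordered by similarity to center, center first
    density: float  # mean exact similarity of members to center
    est_similarities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.center_id not in self.member_ids:
            raise ValueError("center must be among the members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("duplicate member ids in candidate")


def _hash_coefficients(K: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    # odd multipliers for multiply-shift hashing modulo 2**64
    a = rng.integers(1, 1 << 62, size=K, dtype=np.uint64) * np.uint64(2) + np.uint64(1)
    b = rng.integers(0, 1 << 62, size=K, dtype=np.uint64)
    return a, b


def minhash_signature(
    vec: SparseFeatureVector, K: int = 512, seed: int = 42,
    _coeffs: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> MinHashSignature:
    """K-permutation MinHash signature of the vector's support.

    An empty support gets an all-sentinel signature (and is excluded from
    indexing downstream).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if vec.is_empty():
        logger.warning("empty feature vector: emitting sentinel signature")
        return MinHashSignature(values=np.full(K, _SENTINEL, dtype=np.uint64), seed=seed)
    a, b = _coeffs if _coeffs is not None else _hash_coefficients(K, seed)
    support = np.fromiter(vec.entries.keys(), dtype=np.uint64)
    with np.errstate(over="ignore"):
        hashed = a[:, None] * support[None, :] + b[:, None]  # mod 2**64
    return MinHashSignature(values=hashed.min(axis=1), seed=seed)


def signature_agreement(s1: MinHashSignature, s2: MinHashSignature) -> float:
    """Fraction of agreeing signature slots: unbiased Jaccard estimator."""
    if s1.K != s2.K:
        raise ValueError("signature lengths differ")
    return float(np.mean(s1.values == s2.values))


def compute_signatures(
    vectors: dict[str, SparseFeatureVector], K: int = 512, seed: int = 42
) -> dict[str, MinHashSignature]:
    coeffs = _hash_coefficients(K, seed)
    return {wid: minhash_signature(v, K, seed, _coeffs=coeffs) for wid, v in vectors.items()}


def _slot_collision_keys(values: np.ndarray, max_bucket: int):
    """Yield, per signature slot, packed (a*n + b) keys for every ordered
    pair of windows sharing that slot's value.

    Equivalent to an inverse index from (slot, value) to window indices;
    buckets above ``max_bucket`` (features shared by a large fraction of the
    data) are skipped, bounding the per-window work.  All pair generation is
    vectorized so the stage stays fast even when collisions are plentiful.
    """
    n, K = values.shape
    for k in range(K):
        col = values[:, k]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        bounds = np.concatenate(([0], np.nonzero(np.diff(sorted_vals))[0] + 1, [n]))
        sizes = np.diff(bounds)
        run = np.nonzero((sizes >= 2) & (sizes <= max_bucket))[0]
        if len(run) == 0:
            continue
        s = sizes[run]
        starts = bounds[run]
        # concatenated members of all qualifying runs, run-major
        offs = np.concatenate(([0], np.cumsum(s)[:-1]))
        pos = np.arange(int(s.sum())) - np.repeat(offs, s) + np.repeat(starts, s)
        members = order[pos].astype(np.int64)
        # x: each member repeated (its run size) times; y: each run tiled
        x = np.repeat(members, np.repeat(s, s))
        sq = s * s
        offs2 = np.concatenate(([0], np.cumsum(sq)[:-1]))
        within = np.arange(int(sq.sum())) - np.repeat(offs2, sq)
        run_of_pair = np.repeat(np.arange(len(s)), sq)
        y = members[offs[run_of_pair] + within % s[run_of_pair]]
        mask = x != y
        yield x[mask] * n + y[mask]


def candidate_dense_sets(
    signatures: dict[str, MinHashSignature],
    vectors: dict[str, SparseFeatureVector],
    params: ClusterParams = ClusterParams(),
) -> list[ClusterCandidate]:
    """Detect dense neighborhoods of the feature space.

    Counts per-window signature-slot collisions through a per-slot inverse
    index to find neighbor candidates (>= ``min_collisions`` shared slots,
    i.e. an estimated support Jaccard of min_collisions/K), ranks the
    neighbors of each window by exact weighted similarity to it, and greedily
    emits the densest non-duplicate neighborhoods (a candidate is dropped
    when more than ``max_overlap`` of its members are already taken).
    """
    if params.min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    ids = [wid for wid in sorted(signatures) if not signatures[wid].is_sentinel]
    neighbor_lists: dict[str, list[str]] = {wid: [] for wid in signatures}
    if ids:
        values = np.stack([signatures[w].values for w in ids])
        chunks = list(_slot_collision_keys(values, params.max_bucket))
        if chunks:
            keys = np.concatenate(chunks)
            uniq, counts = np.unique(keys, return_counts=True)
            n_ids = len(ids)
            for key in uniq[counts >= params.min_collisions]:
                neighbor_lists[ids[int(key) // n_ids]].append(ids[int(key) % n_ids])
    raw: list[ClusterCandidate] = []
    for wid in sorted(signatures):
        others = neighbor_lists[wid]
        if len(others) + 1 < params.min_cluster_size:
            continue
        sims = {o: similarity(vectors[wid], vectors[o]) for o in others}
        ranked = sorted(others, key=lambda o: (-sims[o], o))
        ranked = ranked[: params.max_cluster_size - 1]
        top = ranked[: params.density_top]
        density = sum(sims[o] for o in top) / len(top)
        if density < params.min_density:
            continue
        # drop incidental low-similarity neighbors (chance slot collisions)
        ranked = [o for o in ranked if sims[o] >= params.min_member_fraction * density]
        if len(ranked) + 1 < params.min_cluster_size:
            continue
        raw.append(
            ClusterCandidate(
                center_id=wid,
                member_ids=[wid] + ranked,
                density=density,
                est_similarities={wid: 1.0, **{o: sims[o] for o in ranked}},
            )
        )
    raw.sort(key=lambda c: (-c.density, -len(c.member_ids), c.center_id))
    emitted: list[ClusterCandidate] = []
    taken: set[str] = set()
    for cand in raw:
        if len(emitted) >= params.max_candidates:
            break
        overlap = sum(1 for m in cand.member_ids if m in taken)
        if overlap > params.max_overlap * len(cand.member_ids):
            continue
        emitted.append(cand)
        taken.update(cand.member_ids)
    return emitted


@dataclass
class RoundState:
    round_index: int
    unclustered_ids: set[str]
    accepted_clusters: list = field(default_factory=list)
    # (round, candidate_rank, center_id, member_id, est_similarity) log
    candidate_log: list = field(default_factory=list)


def run_round(
    state: RoundState,
    vectors: dict[str, SparseFeatureVector],
    params: ClusterParams,
    refiner: Callable[[ClusterCandidate, set[str]], Optional[object]],
) -> RoundState:
    """One clustering iteration over the not-yet-clustered windows.

    Candidates are recomputed over the unclustered ids only; each surviving
    refined cluster (as returned by ``refiner``, which may prune, extend, or
    reject by returning None) has its members removed before the next round.
    """
    if not state.unclustered_ids:
        raise ValueError("no unclustered ids left")
    sub_vectors = {wid: vectors[wid] for wid in state.unclustered_ids}
    signatures = compute_signatures(sub_vectors, params.K, params.seed)
    candidates = candidate_dense_sets(signatures, sub_vectors, params)
    accepted = list(state.accepted_clusters)
    remaining = set(state.unclustered_ids)
    log = list(state.candidate_log)
    for rank, cand in enumerate(candidates, start=1):
        for m in cand.member_ids:
            log.append(
                (state.round_index, rank, cand.center_id, m, cand.est_similarities[m])
            )
    for cand in candidates:
        cand.member_ids = [m for m in cand.member_ids if m in remaining]
        if cand.center_id not in cand.member_ids or len(cand.member_ids) < params.min_cluster_size:
            continue
        cluster = refiner(cand, remaining)
        if cluster is None:
            continue
        accepted.append(cluster)
        remaining -= set(cluster.members)
    return RoundState(
        round_index=state.round_index + 1,
        unclustered_ids=remaining,
        accepted_clusters=accepted,
        candidate_log=log,
    )
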