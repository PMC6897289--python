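"""Sparse hashed decomposition-kernel features over labeled structure graphs.

The kernel follows the neighborhood-subgraph-pairwise-distance decomposition:
a feature is a pair of radius-``r`` neighborhood subgraphs rooted at two
vertices at shortest-path distance ``d`` (``r <= R``, ``d <= D``, same
component).  Neighborhoods are canonicalized with Weisfeiler-Lehman-style
iterative relabeling, hashed with a stable (platform- and run-independent)
64-bit hash, and folded into a ``2**bits`` feature space.  Vectors are
L2-normalized so the kernel value is the sparse dot product in [0, 1].
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

#: hash seed baked into every feature hash; recorded in output metadata
HASH_SEED = 0


def stable_hash(*parts) -> int:
    """Order-sensitive 64-bit hash, stable across runs and platforms."""
    h = hashlib.blake2b(digest_size=8, person=b"nspdk")
    h.update(str(HASH_SEED).encode())
    for p in parts:
        h.update(b"\x1f")
        h.update(str(p).encode())
    return int.from_bytes(h.digest(), "big")


@dataclass(frozen=True)
class KernelParams:
    max_radius: int = 3  # R
    max_distance: int = 3  # D
    bits: int = 20
    wl_iterations: int = 3

    def __post_init__(self) -> None:
        if self.max_radius < 0 or self.max_distance < 0:
            raise ValueError("max_radius and max_distance must be >= 0")
        if not (8 <= self.bits <= 32):
            raise ValueError("bits must be in [8, 32]")
        if self.wl_iterations < self.max_radius:
            raise ValueError("wl_iterations must be >= max_radius")


@dataclass
class SparseFeatureVector:
    """L2-normalized sparse feature vector in a ``2**bits`` hashed space."""

    entries: dict[int, float]
    bits: int

    @property
    def support(self) -> frozenset[int]:
        return frozenset(self.entries)

    def norm(self) -> float:
        return sum(w * w for w in self.entries.values()) ** 0.5

    def is_empty(self) -> bool:
        return not self.entries


def wl_relabel(graph: nx.Graph, iterations: int) -> list[dict[int, int]]:
    """Iterative neighborhood relabeling.

    Iteration 0 labels are stable hashes of the vertex labels; iteration t
    labels hash the own label at t-1 together with the sorted multiset of
    ``(edge relation, neighbor label at t-1)``.  Isomorphic labeled graphs get
    identical label multisets at every iteration.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    labels = {u: stable_hash("v", graph.nodes[u]["label"]) for u in graph.nodes}
    history = [labels]
    for _ in range(iterations):
        prev = history[-1]
        nxt = {}
        for u in graph.nodes:
            neigh = sorted(
                (graph.edges[u, v]["relation"], prev[v]) for v in graph.adj[u]
            )
            nxt[u] = stable_hash("wl", prev[u], *neigh)
        history.append(nxt)
    return history


def _bounded_bfs(graph: nx.Graph, source: int, max_depth: int) -> dict[int, int]:
    """Shortest-path distances from ``source`` up to ``max_depth`` (inclusive)."""
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        du = dist[u]
        if du == max_depth:
            continue
        for v in graph.adj[u]:
            if v not in dist:
                dist[v] = du + 1
                q.append(v)
    return dist


def neighborhood_labels(
    graph: nx.Graph, params: KernelParams
) -> dict[int, list[int]]:
    """Canonical label of the radius-r ball around every vertex, r = 0..R.

    The ball's induced subgraph is canonicalized by running the WL relabeling
    *inside the ball only* (min(r, wl_iterations) sweeps) and hashing the
    multiset of ``(distance from root, in-ball WL label)``.  Confining the
    relabeling to the induced subgraph keeps the feature a function of the
    radius-r neighborhood alone, so a label change outside the ball can never
    perturb it.
    """
    out: dict[int, list[int]] = {}
    for u in graph.nodes:
        dist = _bounded_bfs(graph, u, params.max_radius)
        labels = []
        for r in range(params.max_radius + 1):
            ball = [w for w, d in dist.items() if d <= r]
            sub = graph.subgraph(ball)
            wl = wl_relabel(sub, min(r, params.wl_iterations))
            items = sorted((dist[w], wl[-1][w]) for w in ball)
            labels.append(stable_hash("nb", r, *items))
        out[u] = labels
    return out


def iter_feature_keys(
    graph: nx.Graph, params: KernelParams
) -> Iterable[tuple[int, int, int, int]]:
    """Yield one ``(r, d, label_a, label_b)`` key per rooted-pair feature.

    Pairs are unordered (labels sorted) and restricted to vertices in the same
    component at distance ``d <= D``; the root pair (u, u) at d = 0 is
    included.  This is the un-hashed feature stream shared by the hashed
    vector builder and by count-based oracle checks.
    """
    nb = neighborhood_labels(graph, params)
    for u in sorted(graph.nodes):
        dist = _bounded_bfs(graph, u, params.max_distance)
        for v, d in sorted(dist.items()):
            if v < u:
                continue  # each unordered pair once
            for r in range(params.max_radius + 1):
                la, lb = nb[u][r], nb[v][r]
                if lb < la:
                    la, lb = lb, la
                yield (r, d, la, lb)


def block_normalize(
    weighted_keys: dict[tuple, float]
) -> dict[tuple, float]:
    """Two-level normalization of raw feature counts.

    Counts are first L2-normalized within each (r, d) block so that every
    decomposition level contributes equally, then the concatenation is
    L2-normalized overall.  Without the per-block step the few massively
    repeated radius-0 composition features dominate the norm and wash out the
    discriminative larger-radius features.
    """
    block_norms: dict[tuple[int, int], float] = {}
    for key, w in weighted_keys.items():
        blk = (key[0], key[1])
        block_norms[blk] = block_norms.get(blk, 0.0) + w * w
    block_norms = {b: n ** 0.5 for b, n in block_norms.items()}
    out = {
        key: w / block_norms[(key[0], key[1])]
        for key, w in weighted_keys.items()
        if block_norms[(key[0], key[1])] > 0
    }
    total = sum(w * w for w in out.values()) ** 0.5
    if total > 0:
        out = {k: w / total for k, w in out.items()}
    return out


def nspdk_features(graph: nx.Graph, params: KernelParams = KernelParams()) -> SparseFeatureVector:
    """Hashed, L2-normalized decomposition-kernel feature vector of a graph."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot extract features from an empty graph")
    mask = (1 << params.bits) - 1
    counts: dict[tuple, float] = {}
    for key in iter_feature_keys(graph, params):
        counts[key] = counts.get(key, 0.0) + 1.0
    entries: dict[int, float] = {}
    for key, w in block_normalize(counts).items():
        idx = stable_hash("f", *key) & mask
        entries[idx] = entries.get(idx, 0.0) + w
    norm = sum(w * w for w in entries.values()) ** 0.5
    if norm > 0:  # re-normalize: hash collisions can merge entries
        entries = {k: w / norm for k, w in entries.items()}
    return SparseFeatureVector(entries=entries, bits=params.bits)


def similarity(u: SparseFeatureVector, v: SparseFeatureVector) -> float:
    """Sparse dot product of two normalized vectors (cosine kernel value)."""
    if u.bits != v.bits:
        raise ValueError(f"feature spaces differ: {u.bits} vs {v.bits} bits")
    if len(u.entries) > len(v.entries):
        u, v = v, u
    return sum(w * v.entries.get(k, 0.0) for k, w in u.entries.items())


def dump_sparse(vectors: dict[str, SparseFeatureVector]) -> str:
    """'id idx:weight idx:weight ...' text dump, one line per window."""
    lines = []
    for wid, vec in vectors.items():
        parts = " ".join(f"{k}:{w:.6g}" for k, w in sorted(vec.entries.items()))
        lines.append(f"{wid} {parts}")
    return "\n".join(lines)
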