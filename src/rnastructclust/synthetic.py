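"""Synthetic RNA families, shuffled decoys, simulated reactivities, and ARI.

The generator emulates a homologous ncRNA family: members descend from a
common ancestor, share one consensus secondary structure, and diverge to a
controlled pairwise sequence identity.  Substitutions at paired positions are
compensatory double substitutions (both partners change, pairing preserved)
with a configurable probability, otherwise pairability-preserving single
substitutions — the covariation signal real structure-conserving families
exhibit.  Decoy backgrounds are mono- or dinucleotide-preserving shuffles of
the input, and simulated reactivity profiles draw paired and unpaired
positions from distinct low/high distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .folding import SecondaryStructure
from .preprocess import ReactivityProfile, SeqRecord
from .refine import Partition

PAIR_TYPES = ("GC", "CG", "AU", "UA", "GU", "UG")
_CAN_PAIR = frozenset(PAIR_TYPES)
BASES = "ACGU"


@dataclass(frozen=True)
class SynthFamilySpec:
    """Parameters of one synthetic homologous family."""

    n_sequences: int = 20
    structure_length: int = 80
    target_identity: float = 0.7  # mean pairwise identity between members
    compensatory_fraction: float = 0.8
    paired_fraction: float = 0.55  # fraction of positions in the true structure's pairs
    min_loop: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure_length < 20:
            raise ValueError("structure_length must be >= 20")
        if self.target_identity < 0.25 or self.target_identity > 1.0:
            raise ValueError("target_identity must be in [0.25, 1]")
        if not (0.0 <= self.compensatory_fraction <= 1.0):
            raise ValueError("compensatory_fraction must be in [0, 1]")
        if self.paired_fraction < 0.3:
            raise ValueError("paired_fraction must be >= 0.3")


def _sample_structure(rng: np.random.Generator, spec: SynthFamilySpec) -> SecondaryStructure:
    """Random nested structure built from stacked helices with occasional
    multiloop splits; at least ``paired_fraction`` of positions paired."""
    L, min_loop = spec.structure_length, spec.min_loop
    target_pairs = int(math.ceil(spec.paired_fraction * L / 2))
    pairs: set[tuple[int, int]] = set()
    intervals: list[tuple[int, int]] = [(0, L - 1)]  # inclusive unpaired spans
    while len(pairs) < target_pairs:
        usable = [iv for iv in intervals if iv[1] - iv[0] + 1 >= min_loop + 2]
        if not usable:
            break
        i, j = usable[int(rng.integers(len(usable)))]
        intervals.remove((i, j))
        max_h = (j - i + 1 - min_loop) // 2
        h = int(min(max_h, rng.integers(2, 9)))
        for t in range(h):
            pairs.add((i + t, j - t))
        lo, hi = i + h, j - h
        if hi - lo + 1 >= min_loop:
            if hi - lo + 1 >= 2 * (min_loop + 2) and rng.random() < 0.3:
                cut = int(rng.integers(lo + min_loop + 1, hi - min_loop))
                intervals.extend([(lo, cut), (cut + 1, hi)])
            else:
                intervals.append((lo, hi))
    return SecondaryStructure(length=L, pairs=frozenset(pairs))


def _sample_ancestor(rng: np.random.Generator, structure: SecondaryStructure) -> str:
    seq = [""] * structure.length
    # stems favor G:C (stable), loops are A-rich, as in natural structured RNA
    pair_p = np.array([0.45, 0.35, 0.2])  # GC/CG, AU/UA, GU/UG groups
    loop_p = np.array([0.4, 0.2, 0.2, 0.2])  # A, C, G, U
    for i, j in sorted(structure.pairs):
        group = rng.choice(3, p=pair_p)
        pt = PAIR_TYPES[2 * group + int(rng.integers(2))]
        seq[i], seq[j] = pt[0], pt[1]
    for i in range(structure.length):
        if not seq[i]:
            seq[i] = BASES[int(rng.choice(4, p=loop_p))]
    return "".join(seq)


def _mutate_member(
    rng: np.random.Generator, ancestor: str, structure: SecondaryStructure,
    spec: SynthFamilySpec,
) -> str:
    # per-member divergence q chosen so that two independently mutated members
    # have expected pairwise identity ~ target: (1-q)^2 ~ target
    q = 1.0 - math.sqrt(spec.target_identity)
    budget = round(q * len(ancestor))
    seq = list(ancestor)
    partner = structure.partner()
    order = rng.permutation(len(ancestor))
    changed: set[int] = set()
    for pos in order:
        if len(changed) >= budget:
            break
        pos = int(pos)
        if pos in changed:
            continue
        j = partner.get(pos)
        if j is None:
            alts = [b for b in BASES if b != seq[pos]]
            seq[pos] = alts[int(rng.integers(len(alts)))]
            changed.add(pos)
            continue
        i, jj = (pos, j) if pos < j else (j, pos)
        current = seq[i] + seq[jj]
        if rng.random() < spec.compensatory_fraction:
            alts = [p for p in PAIR_TYPES if p != current]
            new = alts[int(rng.integers(len(alts)))]
            seq[i], seq[jj] = new[0], new[1]
            changed.update((i, jj))
        else:
            # single substitution at `pos` that keeps the pair canonical
            other = seq[jj] if pos == i else seq[i]
            if pos == i:
                alts = [b for b in BASES if b != seq[i] and (b + other) in _CAN_PAIR]
            else:
                alts = [b for b in BASES if b != seq[jj] and (other + b) in _CAN_PAIR]
            if alts:
                seq[pos] = alts[int(rng.integers(len(alts)))]
                changed.add(pos)
            else:  # no pairable single substitution exists: compensatory swap
                alts2 = [p for p in PAIR_TYPES if p != current]
                new = alts2[int(rng.integers(len(alts2)))]
                seq[i], seq[jj] = new[0], new[1]
                changed.update((i, jj))
    return "".join(seq)


def sample_family(spec: SynthFamilySpec) -> tuple[list[SeqRecord], SecondaryStructure]:
    """Sample one homologous family sharing a consensus structure.

    Every member is compatible with the family structure: each true pair is a
    canonical AU/UA/GC/CG/GU/UG pair in every member.
    """
    rng = np.random.default_rng(spec.seed)
    structure = _sample_structure(rng, spec)
    ancestor = _sample_ancestor(rng, structure)
    records = []
    for k in range(spec.n_sequences):
        seq = _mutate_member(rng, ancestor, structure, spec) if spec.target_identity < 1.0 else ancestor
        records.append(SeqRecord(id=f"fam{spec.seed}_m{k}", sequence=seq))
    return records, structure


def mean_pairwise_identity(sequences: Sequence[str], max_pairs: int = 100,
                           seed: int = 0) -> float:
    """Empirical mean pairwise identity over (a sample of) sequence pairs."""
    pairs = list(itertools.combinations(range(len(sequences)), 2))
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        pairs = [pairs[i] for i in rng.choice(len(pairs), size=max_pairs, replace=False)]
    vals = []
    for a, b in pairs:
        sa, sb = sequences[a], sequences[b]
        vals.append(sum(x == y for x, y in zip(sa, sb)) / len(sa))
    return float(np.mean(vals))


@dataclass(frozen=True)
class ReactivitySimParams:
    paired_mean: float = 0.1
    unpaired_mean: float = 0.9


def simulate_reactivities(
    structure: SecondaryStructure,
    params: ReactivitySimParams = ReactivitySimParams(),
    seed: int = 0,
) -> ReactivityProfile:
    """Exponential reactivities: low at paired, high at unpaired positions."""
    rng = np.random.default_rng(seed)
    paired = set()
    for i, j in structure.pairs:
        paired.update((i, j))
    values = []
    for i in range(structure.length):
        mean = params.paired_mean if i in paired else params.unpaired_mean
        values.append(float(rng.exponential(mean)))
    return ReactivityProfile(tuple(values))


def _mononucleotide_shuffle(rng: np.random.Generator, seq: str) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def _dinucleotide_shuffle(rng: np.random.Generator, seq: str) -> str:
    """Euler-path (Altschul-Erickson) shuffle preserving dinucleotide counts."""
    if len(seq) <= 3:
        return seq
    # multigraph: edge u->v for every adjacent pair
    edges: dict[str, list[str]] = {}
    for u, v in zip(seq, seq[1:]):
        edges.setdefault(u, []).append(v)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges.keys() | {last})
    for _ in range(1000):
        # choose a random last exit edge for every vertex except `last`
        last_edge: dict[str, str] = {}
        ok = True
        for u in vertices:
            if u == last:
                continue
            outs = edges.get(u, [])
            if not outs:
                ok = False
                break
            last_edge[u] = outs[int(rng.integers(len(outs)))]
        if not ok:
            break
        # the chosen last edges must connect every vertex to `last`
        def reaches(u: str) -> bool:
            seen = set()
            while u != last:
                if u in seen or u not in last_edge:
                    return False
                seen.add(u)
                u = last_edge[u]
            return True
        if not all(reaches(u) for u in vertices if u != last):
            continue
        shuffled: dict[str, list[str]] = {}
        for u, outs in edges.items():
            rest = list(outs)
            if u != last:
                rest.remove(last_edge[u])
            rng.shuffle(rest)
            if u != last:
                rest.append(last_edge[u])
            shuffled[u] = rest
        walk = [first]
        ptr = {u: 0 for u in shuffled}
        u = first
        for _ in range(len(seq) - 1):
            v = shuffled[u][ptr[u]]
            ptr[u] += 1
            walk.append(v)
            u = v
        return "".join(walk)
    return seq  # degenerate composition: only one arrangement


def shuffle_background(
    records: Sequence[SeqRecord], n_decoys: int, order: int = 2, seed: int = 0
) -> list[SeqRecord]:
    """Generate shuffled decoys with the source length and composition.

    ``order`` 1 preserves mononucleotide counts exactly; 2 preserves
    dinucleotide counts exactly.  Decoys are drawn round-robin from the
    input records.
    """
    if not records:
        raise ValueError("shuffle_background requires input records")
    if order not in (1, 2):
        raise ValueError(f"shuffle order must be 1 or 2, got {order}")
    rng = np.random.default_rng(seed)
    decoys = []
    for k in range(n_decoys):
        src = records[k % len(records)]
        if order == 1:
            seq = _mononucleotide_shuffle(rng, src.sequence)
        else:
            seq = _dinucleotide_shuffle(rng, src.sequence)
        decoys.append(SeqRecord(id=f"decoy{k}_{src.id}", sequence=seq))
    return decoys


def fold_disagreement(
    records: Sequence[SeqRecord], structure: SecondaryStructure, fold_params=None
) -> float:
    """Mean fraction of the family's true pairs missed by unguided folding."""
    from .folding import FoldParams, fold

    fp = fold_params or FoldParams()
    miss = []
    for rec in records:
        pred = fold(rec.sequence, fp)
        miss.append(1.0 - len(pred.pairs & structure.pairs) / len(structure.pairs))
    return float(np.mean(miss))


def make_benchmark(
    n_families: int = 5,
    members_per_family: int = 20,
    structure_length: int = 80,
    target_identity: float = 0.7,
    compensatory_fraction: float = 0.8,
    n_decoys: int = 100,
    shuffle_order: int = 2,
    seed: int = 42,
    with_reactivities: bool = False,
    require_misfolding: Optional[float] = None,
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Assemble a labeled clustering benchmark: families plus shuffled decoys.

    Family members are labeled ``family<i>``; every decoy gets its own unique
    label (a decoy belongs to no family, so the ideal clustering leaves it
    unclustered).  With ``with_reactivities`` each family member carries a
    reactivity profile simulated from the family's true structure.  With
    ``require_misfolding`` family seeds are scanned (deterministically) until
    each family's unguided fold misses at least that fraction of true pairs —
    the regime where probing data has room to help.
    """
    records: list[SeqRecord] = []
    truth: dict[str, str] = {}
    fam_seed = seed
    for f in range(n_families):
        while True:
            spec = SynthFamilySpec(
                n_sequences=members_per_family,
                structure_length=structure_length,
                target_identity=target_identity,
                compensatory_fraction=compensatory_fraction,
                seed=fam_seed,
            )
            fam_seed += 1
            recs, struct = sample_family(spec)
            if require_misfolding is None:
                break
            if fold_disagreement(recs, struct) >= require_misfolding:
                break
        for k, rec in enumerate(recs):
            if with_reactivities:
                rec.reactivities = simulate_reactivities(
                    struct, seed=(seed * 100003 + f * 1009 + k) % (2**31)
                )
            records.append(rec)
            truth[rec.id] = f"family{f}"
    if n_decoys:
        for rec in shuffle_background(records, n_decoys, order=shuffle_order,
                                      seed=(seed + 7919) % (2**31)):
            records.append(rec)
            truth[rec.id] = f"decoy_{rec.id}"
    return records, truth


def benchmark_ari(records: Sequence[SeqRecord], truth: dict[str, str], params=None) -> float:
    """Run the full pipeline on a labeled benchmark and return the ARI
    (unclustered elements count as singletons)."""
    from .pipeline import PipelineParams, cluster_sequences

    result = cluster_sequences(list(records), params or PipelineParams())
    predicted = partition_labels(result.sequence_partition(), sorted(truth))
    return adjusted_rand_index(predicted, truth).ari


@dataclass
class PartitionComparison:
    rand_index: float
    expected_rand_index: float
    ari: float
    contingency: np.ndarray


def partition_labels(
    partition: Partition, elements: Sequence[str], unclustered_policy: str = "singletons"
) -> dict[str, object]:
    """Predicted label per element; unclustered elements become singletons
    (default) or are dropped (policy ``"drop"``)."""
    labels: dict[str, object] = {}
    for eid in elements:
        cids = partition.assignments.get(eid)
        if cids:
            labels[eid] = min(cids)
        elif unclustered_policy == "singletons":
            labels[eid] = f"_singleton_{eid}"
        elif unclustered_policy != "drop":
            raise ValueError(f"unknown unclustered policy {unclustered_policy!r}")
    return labels


def adjusted_rand_index(
    predicted: dict[str, object], reference: dict[str, object]
) -> PartitionComparison:
    """Chance-corrected pair-counting agreement of two hard partitions.

    The Rand index is the fraction of element pairs related identically
    (together/apart) in both partitions; its expectation under the
    permutation model is derived from the contingency table, and
    ARI = (RI - E[RI]) / (1 - E[RI]), with maximum 1 at identity.
    """
    if set(predicted) != set(reference):
        raise ValueError("predicted and reference cover different elements")
    elements = sorted(predicted)
    n = len(elements)
    if n < 2:
        raise ValueError("need at least 2 elements")
    p_classes = sorted({str(predicted[e]) for e in elements})
    r_classes = sorted({str(reference[e]) for e in elements})
    p_idx = {c: i for i, c in enumerate(p_classes)}
    r_idx = {c: i for i, c in enumerate(r_classes)}
    cont = np.zeros((len(p_classes), len(r_classes)), dtype=np.int64)
    for e in elements:
        cont[p_idx[str(predicted[e])], r_idx[str(reference[e])]] += 1

    def comb2(x: np.ndarray) -> float:
        return float((x * (x - 1) // 2).sum())

    both = comb2(cont)
    A = comb2(cont.sum(axis=1))
    B = comb2(cont.sum(axis=0))
    total = n * (n - 1) / 2
    ri = (total - A - B + 2 * both) / total
    e_ri = (total - A - B + 2 * A * B / total) / total
    denom = 1.0 - e_ri
    if abs(denom) < 1e-15:
        ari = 1.0 if abs(ri - 1.0) < 1e-15 else 0.0
    else:
        ari = (ri - e_ri) / denom
    return PartitionComparison(
        rand_index=float(ri), expected_rand_index=float(e_ri),
        ari=float(ari), contingency=cont,
    )
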