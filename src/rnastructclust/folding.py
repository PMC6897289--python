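"""Secondary-structure prediction by weighted base-pair maximization.

One structure is predicted per window with an O(n^3) Nussinov-style dynamic
program over weighted canonical pairs (GC 3, AU 2, GU 1), optionally biased by
per-position pseudo-energy scores derived from chemical-probing reactivities
via the standard log-linear conversion ``m * ln(1 + reactivity) + b``.  The
predictor is deliberately pluggable: externally computed structures can be
supplied as dot-bracket and bypass the internal model entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .preprocess import ReactivityProfile

_EPS = 1e-9

#: canonical pair weights (Watson-Crick + wobble); everything else never pairs
DEFAULT_PAIR_SCORES: dict[str, float] = {
    "GC": 3.0, "CG": 3.0,
    "AU": 2.0, "UA": 2.0,
    "GU": 1.0, "UG": 1.0,
}


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested (pseudoknot-free) set of base pairs over a sequence."""

    length: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"position in more than one pair near ({i},{j})")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for b in range(a + 1, len(ordered)):
                k, l = ordered[b]
                if k > j:
                    break
                if not (i < k < l < j):
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")

    @property
    def dotbracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def pair_state(self) -> str:
        """Per-position state string: '(' opening, ')' closing, '.' unpaired."""
        return self.dotbracket


@dataclass(frozen=True)
class PseudoEnergyParams:
    """Slope/intercept of the reactivity -> pseudo-score conversion.

    ``m`` and ``b`` follow common SHAPE-directed folding practice (score
    units); a missing reactivity contributes ``missing_value_score`` (default
    0 = no bias for unprobed positions).
    """

    m: float = 1.8
    b: float = -0.6
    missing_value_score: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m", "b", "missing_value_score"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class FoldParams:
    min_loop: int = 3
    pair_scores: tuple[tuple[str, float], ...] = tuple(DEFAULT_PAIR_SCORES.items())
    pseudo_weight: float = 1.0  # lambda multiplying the pseudo-score penalty

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if self.pseudo_weight < 0:
            raise ValueError("pseudo_weight must be >= 0")

    @property
    def score_table(self) -> dict[str, float]:
        return dict(self.pair_scores)


def reactivity_to_pseudo_scores(
    profile: ReactivityProfile, params: PseudoEnergyParams = PseudoEnergyParams()
) -> list[float]:
    """Convert reactivities to per-position pseudo-scores m*ln(1+r)+b.

    High reactivity marks accessible (unpaired) nucleotides, so a high score
    penalizes pairing at that position when subtracted in the fold objective.
    """
    scores: list[float] = []
    for v in profile.values:
        if v is None:
            scores.append(params.missing_value_score)
        else:
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"invalid reactivity value {v!r}")
            scores.append(params.m * math.log1p(v) + params.b)
    return scores


def _pair_score_matrix(
    sequence: str, params: FoldParams, pseudo: Optional[Sequence[float]]
) -> np.ndarray:
    n = len(sequence)
    table = params.score_table
    S = np.full((n, n), -np.inf)
    lam = params.pseudo_weight
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            w = table.get(sequence[i] + sequence[j])
            if w is None:
                continue
            s = w
            if pseudo is not None and lam > 0:
                s -= lam * (pseudo[i] + pseudo[j])
            S[i, j] = s
    return S


def maximize_nested_pairing(S: np.ndarray, min_loop: int) -> tuple[float, frozenset]:
    """Maximum-score nested pairing for an arbitrary pair-score matrix.

    ``S[i, j]`` is the net gain of pairing positions i < j (``-inf`` forbids
    the pair).  Only pairs with a non-negative contribution to the optimum are
    taken; traceback is canonical (pairing the right end preferred over
    leaving it unpaired at score ties, leftmost partner first) so results are
    platform-deterministic.  Returns ``(objective, pairs)``.
    """
    n = S.shape[0]
    M = np.zeros((n + 1, n + 1))  # M[i][j] over half-open [i, j)
    # fill by span; inner maximization over the partner k of position j-1
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # half-open end; last index j-1
            best = M[i, j - 1]
            ks = np.arange(i, j - 1 - min_loop)
            if len(ks):
                cand = M[i, ks] + M[ks + 1, j - 1] + S[ks, j - 1]
                m = cand.max()
                if m > best:
                    best = m
            M[i, j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 2:
            continue
        target = M[i, j]
        paired = False
        for k in range(i, j - 1 - min_loop):
            if S[k, j - 1] == -np.inf:
                continue
            if abs(M[i, k] + M[k + 1, j - 1] + S[k, j - 1] - target) <= _EPS:
                pairs.add((k, j - 1))
                stack.append((i, k))
                stack.append((k + 1, j - 1))
                paired = True
                break
        if not paired:
            stack.append((i, j - 1))
    return float(M[0, n]), frozenset(pairs)


def fold(
    sequence: str,
    fold_params: FoldParams = FoldParams(),
    pseudo_scores: Optional[Sequence[float]] = None,
) -> SecondaryStructure:
    """Predict the maximum-score nested structure for ``sequence``.

    Maximizes sum over pairs of ``pair_score(i,j) - lambda*(pseudo[i] +
    pseudo[j])`` subject to nesting and the minimum hairpin-loop length.
    Pairs with a negative net contribution are never forced, so an adverse
    pseudo-score simply leaves positions unpaired.
    """
    n = len(sequence)
    if n < 1:
        raise ValueError("cannot fold an empty sequence")
    if pseudo_scores is not None and len(pseudo_scores) != n:
        raise ValueError(
            f"pseudo score vector length {len(pseudo_scores)} != sequence length {n}"
        )
    S = _pair_score_matrix(sequence, fold_params, pseudo_scores)
    _, pairs = maximize_nested_pairing(S, fold_params.min_loop)
    return SecondaryStructure(length=n, pairs=pairs)


def fold_objective(
    structure: SecondaryStructure,
    sequence: str,
    fold_params: FoldParams = FoldParams(),
    pseudo_scores: Optional[Sequence[float]] = None,
) -> float:
    """Score an arbitrary structure under the fold objective."""
    table = fold_params.score_table
    lam = fold_params.pseudo_weight
    total = 0.0
    for i, j in structure.pairs:
        w = table.get(sequence[i] + sequence[j])
        if w is None:
            return -math.inf
        total += w
        if pseudo_scores is not None and lam > 0:
            total -= lam * (pseudo_scores[i] + pseudo_scores[j])
    return total


def parse_dotbracket(s: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a structure (stack pairing)."""
    pairs: set[tuple[int, int]] = set()
    stack: list[int] = []
    for idx, ch in enumerate(s):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at index {idx}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at index {idx}")
    if stack:
        raise ValueError(f"unbalanced '(' at index {stack[0]}")
    return SecondaryStructure(length=len(s), pairs=frozenset(pairs))


def to_dotbracket(structure: SecondaryStructure) -> str:
    return structure.dotbracket


def read_dotbracket_file(path) -> dict[str, tuple[str, SecondaryStructure]]:
    """Read Vienna-style blocks: '>id' / sequence / dot-bracket, one per entry."""
    out: dict[str, tuple[str, SecondaryStructure]] = {}
    lines = [ln.strip() for ln in open(path) if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>id' header, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise ValueError(f"truncated block for {lines[i]!r}")
        sid = lines[i][1:].split()[0]
        seq, db = lines[i + 1], lines[i + 2].split()[0]
        if len(seq) != len(db):
            raise ValueError(f"sequence/structure length mismatch for {sid!r}")
        out[sid] = (seq, parse_dotbracket(db))
        i += 3
    return out


def write_dotbracket_file(path, entries: dict[str, tuple[str, SecondaryStructure]]) -> None:
    with open(path, "w") as fh:
        for sid, (seq, struct) in entries.items():
            fh.write(f">{sid}\n{seq}\n{struct.dotbracket}\n")
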