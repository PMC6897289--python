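"""Input handling: FASTA I/O, sliding windows, redundancy removal, reactivities.

All coordinates are 0-based half-open internally; the two-column reactivity
dialect and human-facing reports use 1-based positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger("rnastructclust")

#: sentinel for a missing (unprobed) reactivity value in the two-column dialect
MISSING_REACTIVITY = -999.0

VALID_BASES = frozenset("ACGUN")
_INPUT_BASES = frozenset("ACGUNTacgunt")


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-nucleotide chemical-probing reactivities.

    ``values[i]`` is a non-negative float, or ``None`` where the position was
    not probed.  Length always equals the length of the associated sequence.
    """

    values: tuple[Optional[float], ...]

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_present(self) -> int:
        return sum(1 for v in self.values if v is not None)

    @property
    def n_nonzero(self) -> int:
        return sum(1 for v in self.values if v is not None and v > 0.0)

    def slice(self, start: int, end: int) -> "ReactivityProfile":
        return ReactivityProfile(self.values[start:end])


@dataclass
class SeqRecord:
    """A single input RNA sequence (DNA is converted on ingest)."""

    id: str
    sequence: str
    description: str = ""
    reactivities: Optional[ReactivityProfile] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.reactivities is not None and len(self.reactivities) != len(self.sequence):
            raise ValueError(
                f"reactivity profile length {len(self.reactivities)} does not match "
                f"sequence length {len(self.sequence)} for id {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Window:
    """A sliding-window fragment of a parent sequence."""

    parent_id: str
    start: int
    end: int
    sequence: str
    reactivities: Optional[ReactivityProfile] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window coordinates [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("window sequence length does not match coordinates")
        if self.reactivities is not None and len(self.reactivities) != len(self.sequence):
            raise ValueError("window reactivity slice not aligned with sequence")

    @property
    def window_id(self) -> str:
        return f"{self.parent_id}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str, *, record_id: str = "?") -> str:
    """Uppercase, convert T->U, and reject anything outside {A,C,G,U,N}."""
    for pos, ch in enumerate(raw):
        if ch not in _INPUT_BASES:
            raise ValueError(
                f"invalid character {ch!r} at position {pos + 1} in sequence {record_id!r}"
            )
    return raw.upper().replace("T", "U")


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into a list of validated :class:`SeqRecord`.

    T/t is converted to U and sequences are uppercased.  Duplicate ids and
    non-nucleotide characters raise ``ValueError``.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = normalize_sequence(str(entry.seq), record_id=entry.id)
        records.append(SeqRecord(id=entry.id, sequence=seq, description=entry.description))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Sequence[SeqRecord], path) -> None:
    entries = []
    for r in records:
        desc = r.description
        if desc.startswith(r.id):  # SeqIO descriptions embed the id
            desc = desc[len(r.id):].strip()
        entries.append(BioSeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(entries, str(path), "fasta")


def split_windows(record: SeqRecord, window_len: int, shift_fraction: float) -> list[Window]:
    """Fragment ``record`` into sliding windows.

    The step is ``max(1, round(shift_fraction * window_len))``.  A final
    end-anchored window ``[len - window_len, len)`` is emitted when the last
    stepped window would otherwise drop the 3' end, so every position of the
    parent is covered.
    """
    if window_len <= 0:
        raise ValueError(f"window_len must be >= 1, got {window_len}")
    if not (0.0 < shift_fraction <= 1.0):
        raise ValueError(f"shift_fraction must be in (0, 1], got {shift_fraction}")
    n = len(record)
    prof = record.reactivities

    def make(start: int, end: int) -> Window:
        return Window(
            parent_id=record.id,
            start=start,
            end=end,
            sequence=record.sequence[start:end],
            reactivities=prof.slice(start, end) if prof is not None else None,
        )

    if n <= window_len:
        return [make(0, n)]
    step = max(1, round(shift_fraction * window_len))
    starts = list(range(0, n - window_len + 1, step))
    last = n - window_len
    if starts[-1] != last:
        starts.append(last)
    return [make(s, s + window_len) for s in starts]


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_identity(a: str, b: str, k: int = 8) -> float:
    """Shared-k-mer estimate of pairwise identity (CD-HIT-style shortcut)."""
    ka, kb = _kmer_set(a, k), _kmer_set(b, k)
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 0.0
    return len(ka & kb) / denom


def filter_redundant(
    records: Sequence[SeqRecord],
    identity_threshold: float = 0.9,
    k: int = 8,
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Greedy longest-first redundancy removal.

    Records are visited longest-first; each joins the first existing
    representative whose k-mer-estimated identity reaches the threshold,
    otherwise it founds a new representative.  At threshold 1.0 only
    byte-identical sequences are collapsed (exact comparison, no estimate).

    Returns ``(representatives, member_id -> representative_id)``; the mapping
    covers non-representative members only.
    """
    if not records:
        raise ValueError("filter_redundant requires at least one record")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    order = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[SeqRecord] = []
    mapping: dict[str, str] = {}
    for rec in order:
        assigned = False
        for rep in reps:
            if identity_threshold >= 1.0:
                hit = rec.sequence == rep.sequence
            else:
                hit = kmer_identity(rec.sequence, rep.sequence, k) >= identity_threshold
            if hit:
                mapping[rec.id] = rep.id
                assigned = True
                break
        if not assigned:
            reps.append(rec)
    # restore input order of representatives
    input_pos = {r.id: i for i, r in enumerate(records)}
    reps.sort(key=lambda r: input_pos[r.id])
    return reps, mapping


def read_reactivities(path) -> dict[str, ReactivityProfile]:
    """Read per-sequence reactivity profiles.

    The dialect is FASTA-like blocks: a ``>id`` header followed by two-column
    rows ``position value`` with 1-based consecutive positions; ``-999`` marks
    a missing (unprobed) value.  Negative non-missing values are clamped to 0
    (a count of clamped entries is logged).
    """
    path = Path(path)
    profiles: dict[str, ReactivityProfile] = {}
    current_id: Optional[str] = None
    values: list[Optional[float]] = []
    clamped = 0

    def flush() -> None:
        nonlocal values
        if current_id is not None:
            if current_id in profiles:
                raise ValueError(f"duplicate reactivity block for id {current_id!r}")
            profiles[current_id] = ReactivityProfile(tuple(values))
        values = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0]
                continue
            if current_id is None:
                raise ValueError(f"{path}:{lineno}: data row before any >id header")
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
            pos, val = int(fields[0]), float(fields[1])
            if not math.isfinite(val):
                raise ValueError(f"{path}:{lineno}: non-finite reactivity value")
            if pos != len(values) + 1:
                raise ValueError(
                    f"{path}:{lineno}: non-consecutive position {pos} "
                    f"(expected {len(values) + 1})"
                )
            if val == MISSING_REACTIVITY:
                values.append(None)
            elif val < 0.0:
                values.append(0.0)
                clamped += 1
            else:
                values.append(val)
    flush()
    if clamped:
        logger.info("clamped %d negative reactivity values to 0", clamped)
    return profiles


def associate_reactivities(
    records: Sequence[SeqRecord], profiles: dict[str, ReactivityProfile]
) -> None:
    """Attach profiles to records in place; length mismatches are hard errors.

    Profile ids with no matching record produce a warning and are dropped.
    """
    by_id = {r.id: r for r in records}
    for pid, prof in profiles.items():
        rec = by_id.get(pid)
        if rec is None:
            logger.warning("reactivity profile %r has no matching sequence; dropped", pid)
            continue
        if len(prof) != len(rec):
            raise ValueError(
                f"reactivity profile for {pid!r} has length {len(prof)} "
                f"but sequence has length {len(rec)}"
            )
        rec.reactivities = prof


def filter_low_information(
    profile: ReactivityProfile, min_nonzero_fraction: float = 0.01
) -> bool:
    """Return True (keep) unless fewer than ``min_nonzero_fraction`` of the
    positions carry a non-zero reactivity.

    Low-information profiles are an artifact of poor read coverage in
    transcriptome-wide probing and bias folding toward the unguided result;
    the strict ``<`` means an exactly-1% profile is kept at the default.
    """
    if len(profile) < 1:
        raise ValueError("empty reactivity profile")
    return not (profile.n_nonzero / len(profile) < min_nonzero_fraction)
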