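"""Seed-and-extend mapping of trimmed reads against a dual-orientation reference.

Every reference entry is indexed twice: as-is (``chr1``) and reverse
complemented (``chr1_rc``).  Reads are only ever placed in the forward
orientation of an oriented entry, so a read from the minus strand surfaces as
a forward hit on the ``_rc`` copy — mirroring the trick of mapping against
the reference in both orientations and keeping FLAG = 0 records only.

Mapping seeds on every read k-mer, extends ungapped along each candidate
diagonal, and scores by Hamming mismatches.  A read is reported only when its
best placement is within the mismatch budget and strictly better than the
second best; ties are discarded as ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .layout import revcomp
from .seqio import AlignmentRecord, Orientation, SeqRecord

__all__ = [
    "MapPolicy",
    "ReferenceIndex",
    "build_index",
    "map_read",
    "map_reads",
    "rc_to_forward_leftmost",
]


@dataclass(frozen=True, slots=True)
class MapPolicy:
    """Seed length, mismatch budget and ambiguity handling."""

    k: int = 21
    max_mismatch_rate: float = 0.05
    require_unique_best: bool = True
    min_read_len: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.max_mismatch_rate < 0.5:
            raise ValueError("max_mismatch_rate must be in (0, 0.5)")

    def max_mismatches(self, read_len: int) -> int:
        return int(self.max_mismatch_rate * read_len)


class ReferenceIndex:
    """K-mer index over both oriented copies of every reference entry."""

    def __init__(self, entries: list[tuple[str, str]], k: int):
        self.k = k
        self.entries = entries  # [(oriented id, sequence)]
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        for idx, (_, seq) in enumerate(entries):
            for pos0 in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos0 : pos0 + k], []).append((idx, pos0))

    def entry_id(self, idx: int) -> str:
        return self.entries[idx][0]

    def entry_seq(self, idx: int) -> str:
        return self.entries[idx][1]

    def __len__(self) -> int:
        return len(self.entries)


def build_index(refs: list[SeqRecord], policy: MapPolicy = MapPolicy()) -> ReferenceIndex:
    """Index forward and reverse-complement copies of each reference entry.

    Entries shorter than the seed length are skipped with a warning.
    """
    if not refs:
        raise ValueError("reference list is empty")
    entries: list[tuple[str, str]] = []
    for rec in refs:
        if len(rec.sequence) < policy.k:
            warnings.warn(
                f"reference {rec.id!r} shorter than k={policy.k}; skipped", stacklevel=2
            )
            continue
        entries.append((rec.id, rec.sequence))
        entries.append((rec.id + "_rc", revcomp(rec.sequence)))
    if not entries:
        raise ValueError("no reference entry long enough to index")
    return ReferenceIndex(entries, policy.k)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit past ``limit``."""
    nm = 0
    for x, y in zip(a, b):
        if x != y:
            nm += 1
            if nm > limit:
                return nm
    return nm


def map_read(
    read: SeqRecord, index: ReferenceIndex, policy: MapPolicy = MapPolicy()
) -> AlignmentRecord | None:
    """Place a read on the dual-orientation reference, or return ``None``.

    Seeds on all read k-mers, extends ungapped at every candidate diagonal and
    keeps the unique best placement (fewest mismatches, within
    ``floor(max_mismatch_rate x read length)``).  Ambiguous reads — equal best
    score at two placements — are discarded.
    """
    seq = read.sequence
    L = len(seq)
    if L < policy.min_read_len or L < index.k:
        return None
    k = index.k
    kmers = index.kmers
    candidates: set[tuple[int, int]] = set()
    for i in range(L - k + 1):
        hits = kmers.get(seq[i : i + k])
        if not hits:
            continue
        for entry_idx, pos0 in hits:
            start0 = pos0 - i
            if start0 >= 0 and start0 + L <= len(index.entry_seq(entry_idx)):
                candidates.add((entry_idx, start0))
    if not candidates:
        return None
    budget = policy.max_mismatches(L)
    best: tuple[int, int, int] | None = None  # (nm, entry_idx, start0)
    second_nm: int | None = None
    for entry_idx, start0 in candidates:
        ref_seq = index.entry_seq(entry_idx)
        segment = ref_seq[start0 : start0 + L]
        nm = 0 if segment == seq else _count_mismatches(seq, segment, budget)
        if best is None or (nm, entry_idx, start0) < best:
            if best is not None:
                second_nm = best[0] if second_nm is None else min(second_nm, best[0])
            best = (nm, entry_idx, start0)
        else:
            second_nm = nm if second_nm is None else min(second_nm, nm)
    nm, entry_idx, start0 = best
    if nm > budget:
        return None
    if policy.require_unique_best and second_nm is not None and second_nm <= nm:
        return None
    entry_id = index.entry_id(entry_idx)
    return AlignmentRecord(
        query_id=read.id,
        ref_id=entry_id,
        orientation=Orientation.RC if entry_id.endswith("_rc") else Orientation.FWD,
        pos=start0 + 1,
        mismatches=nm,
        mapped_len=L,
    )


def map_reads(
    reads: Iterable[SeqRecord], index: ReferenceIndex, policy: MapPolicy = MapPolicy()
) -> Iterator[AlignmentRecord]:
    """Map a stream of reads, yielding only placed (non-ambiguous) records."""
    for read in reads:
        rec = map_read(read, index, policy)
        if rec is not None:
            yield rec


def rc_to_forward_leftmost(pos_rc: int, mapped_len: int, entry_len: int) -> int:
    """Project a leftmost coordinate on an ``_rc`` entry back to forward space.

    A read occupying ``[pos_rc, pos_rc + mapped_len - 1]`` on the reverse
    complement of an entry of length ``entry_len`` covers forward positions
    ending at ``entry_len - pos_rc + 1``; its forward-space leftmost
    coordinate is ``entry_len - (pos_rc + mapped_len - 1) + 1``.
    """
    return entry_len - (pos_rc + mapped_len - 1) + 1
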