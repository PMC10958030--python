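"""Two-round junction trimming of Read 1.

Round 1 locates the 29-nt anchor + 5'-mosaic-end pattern near the read start,
tolerating up to 10% errors (floor(0.10 x 29) = 2), and removes everything up
to and including the match — this implicitly discards the 3-6 nt balancer.
Round 2 then requires the read to continue with the exact 10-nt mosaic-end
remnant and removes it.  Reads failing either round, or left shorter than a
mappability floor, are discarded together with their Read 2 mates.

The round-1 error model is semi-global edit distance by default (unit-cost
substitutions and indels, pattern fully aligned inside the read prefix), with
a substitution-only Hamming mode available.  Edit-distance matching uses
edlib's infix (HW) mode.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import edlib

from .layout import ME10, ROUND1_PATTERN
from .seqio import ReadPair, SeqRecord

__all__ = [
    "ErrorModel",
    "TrimPolicy",
    "TrimStatus",
    "TrimOutcome",
    "TrimStats",
    "Round1Match",
    "locate_round1",
    "trim_pair",
    "filter_pairs",
]


class ErrorModel(str, enum.Enum):
    EDIT = "edit"
    HAMMING = "hamming"


@dataclass(frozen=True, slots=True)
class TrimPolicy:
    """Parameters of the two-round junction filter.

    ``round1_window`` caps the search to the read prefix: balancer (max 6) +
    pattern (29) + 2 nt of indel slack = 37 by default.  ``round2_errors`` is
    fixed at 0 — the mosaic-end remnant must follow exactly.
    """

    round1_pattern: str = ROUND1_PATTERN
    round1_error_rate: float = 0.10
    round1_window: int = 6 + len(ROUND1_PATTERN) + 2
    round2_pattern: str = ME10
    round2_errors: int = 0
    min_remaining_len: int = 20
    error_model: ErrorModel = ErrorModel.EDIT

    @property
    def round1_max_errors(self) -> int:
        """Allowed round-1 errors: floor(error_rate x pattern length)."""
        return int(self.round1_error_rate * len(self.round1_pattern))


class Round1Match(NamedTuple):
    end_offset: int  # offset of the first base after the match (0-based)
    n_errors: int


class TrimStatus(str, enum.Enum):
    KEPT = "KEPT"
    DROP_ROUND1 = "DROP_ROUND1"
    DROP_ROUND2 = "DROP_ROUND2"
    DROP_SHORT = "DROP_SHORT"


@dataclass(slots=True)
class TrimOutcome:
    status: TrimStatus
    trimmed_read1: SeqRecord | None = None
    removed_prefix_len_r1: int = 0
    removed_r2_mate: bool = True


@dataclass(slots=True)
class TrimStats:
    """Input/kept counters; ``usable_fraction`` is kept over raw input pairs."""

    n_input: int = 0
    n_kept: int = 0
    n_drop_round1: int = 0
    n_drop_round2: int = 0
    n_drop_short: int = 0

    @property
    def usable_fraction(self) -> float:
        return self.n_kept / self.n_input if self.n_input else 0.0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_drop_round1": self.n_drop_round1,
            "n_drop_round2": self.n_drop_round2,
            "n_drop_short": self.n_drop_short,
            "usable_fraction": self.usable_fraction,
        }


def locate_round1(read1: SeqRecord, policy: TrimPolicy = TrimPolicy()) -> Round1Match | None:
    """Find the best round-1 pattern occurrence in the read prefix.

    Searches the first ``round1_window`` bases.  The best match minimizes
    (errors, end offset); ``None`` when no occurrence fits the error budget.
    In edit mode errors are unit-cost substitutions and indels of a semi-global
    (pattern-infix) alignment; in Hamming mode, substitutions only.
    """
    pattern = policy.round1_pattern
    seq = read1.sequence
    if len(seq) < len(pattern):
        return None
    window = seq[: policy.round1_window]
    budget = policy.round1_max_errors
    if policy.error_model is ErrorModel.EDIT:
        res = edlib.align(pattern, window, mode="HW", task="locations", k=budget)
        if res["editDistance"] < 0:
            return None
        end = min(loc[1] for loc in res["locations"])
        return Round1Match(end_offset=end + 1, n_errors=res["editDistance"])
    # Hamming: slide the pattern over every admissible start offset
    best: Round1Match | None = None
    for off in range(0, len(window) - len(pattern) + 1):
        nm = sum(a != b for a, b in zip(pattern, seq[off : off + len(pattern)]))
        if nm <= budget and (best is None or nm < best.n_errors):
            best = Round1Match(end_offset=off + len(pattern), n_errors=nm)
    return best


def trim_pair(pair: ReadPair, policy: TrimPolicy = TrimPolicy()) -> TrimOutcome:
    """Apply both trimming rounds to a mate pair.

    Round 1 removes everything through the 29-nt match; round 2 requires and
    removes the exact mosaic-end remnant at the new 5' end; reads left shorter
    than ``min_remaining_len`` are dropped.  Non-KEPT outcomes drop the Read 2
    mate as well.
    """
    m = locate_round1(pair.read1, policy)
    if m is None:
        return TrimOutcome(TrimStatus.DROP_ROUND1)
    seq = pair.read1.sequence
    rest = seq[m.end_offset :]
    r2pat = policy.round2_pattern
    if not rest.startswith(r2pat):
        return TrimOutcome(TrimStatus.DROP_ROUND2)
    removed = m.end_offset + len(r2pat)
    trimmed_seq = seq[removed:]
    if len(trimmed_seq) < policy.min_remaining_len:
        return TrimOutcome(TrimStatus.DROP_SHORT, removed_prefix_len_r1=removed)
    qual = pair.read1.quality
    trimmed = SeqRecord(
        id=pair.read1.id,
        sequence=trimmed_seq,
        quality=qual[removed:] if qual is not None else None,
    )
    return TrimOutcome(
        TrimStatus.KEPT,
        trimmed_read1=trimmed,
        removed_prefix_len_r1=removed,
        removed_r2_mate=False,
    )


def filter_pairs(
    pairs: Iterable[ReadPair], policy: TrimPolicy = TrimPolicy(), stats: TrimStats | None = None
) -> tuple[Iterator[ReadPair], TrimStats]:
    """Stream kept, trimmed pairs and tally a :class:`TrimStats`.

    Returns ``(iterator, stats)``; the stats object fills in as the iterator
    is consumed (it is complete once the stream is exhausted).  Kept pairs
    carry the trimmed Read 1 and the untouched Read 2 mate, in input order.
    """
    st = stats if stats is not None else TrimStats()

    def _gen() -> Iterator[ReadPair]:
        for pair in pairs:
            st.n_input += 1
            out = trim_pair(pair, policy)
            if out.status is TrimStatus.KEPT:
                st.n_kept += 1
                yield ReadPair(out.trimmed_read1, pair.read2)
            elif out.status is TrimStatus.DROP_ROUND1:
                st.n_drop_round1 += 1
            elif out.status is TrimStatus.DROP_ROUND2:
                st.n_drop_round2 += 1
            else:
                st.n_drop_short += 1

    return _gen(), st
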