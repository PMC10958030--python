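"""Junction calling: dedup, CPM filtering, subsampling and condition reports.

A junction (unique insertion site, UIS) is the leftmost mapped coordinate of
a trimmed junction read on an oriented reference entry.  Alignments are
de-duplicated by (entry, position) into *putative* junctions with read
counts; putative junctions supported by fewer than 1 count per million mapped
reads (CPM) are rejected, the survivors being *true* junctions.  Junction
identity lives in oriented-entry space: ``(chr1, 100)`` and ``(chr1_rc, 250)``
are distinct sites even if they project to the same genomic base, because
they represent opposite transposon orientations.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TypeVar

import numpy as np
import pandas as pd

from .seqio import AlignmentRecord
from .simlib import InsertionTruth, truth_to_oriented

__all__ = [
    "JunctionTable",
    "ComparisonReport",
    "ConditionSummary",
    "putative_junctions",
    "classify_true",
    "subsample_stream",
    "subsample_pairs",
    "compare_conditions",
    "recovery_metrics",
]

_T = TypeVar("_T")

_COLUMNS = ["ref_entry", "pos", "count", "cpm", "is_true"]


@dataclass(slots=True)
class JunctionTable:
    """Putative/true junctions with counts and CPM support.

    ``df`` columns: ``ref_entry`` (oriented id), ``pos`` (1-based), ``count``,
    ``cpm`` (= count / total_mapped_reads x 1e6), ``is_true`` (None until
    classified).  ``total_mapped_reads`` equals the sum of counts.
    """

    total_mapped_reads: int
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.df.columns) != _COLUMNS:
            raise ValueError(f"junction table needs columns {_COLUMNS}")
        if len(self.df) and int(self.df["count"].sum()) != self.total_mapped_reads:
            raise ValueError("junction counts must sum to total_mapped_reads")
        if self.df.duplicated(subset=["ref_entry", "pos"]).any():
            raise ValueError("duplicate (ref_entry, pos) junction rows")

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, int], int], total_mapped_reads: int | None = None
    ) -> "JunctionTable":
        total = sum(counts.values()) if total_mapped_reads is None else total_mapped_reads
        rows = sorted(counts.items())
        df = pd.DataFrame(
            {
                "ref_entry": [k[0] for k, _ in rows],
                "pos": [k[1] for k, _ in rows],
                "count": [c for _, c in rows],
            }
        )
        df["cpm"] = df["count"] / total * 1e6 if total else 0.0
        df["is_true"] = None
        return cls(total_mapped_reads=total, df=df)

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[tuple[str, int, int, float, bool | None]],
        total_mapped_reads: int,
    ) -> "JunctionTable":
        df = pd.DataFrame(rows, columns=_COLUMNS)
        return cls(total_mapped_reads=total_mapped_reads, df=df)

    @property
    def classified(self) -> bool:
        return len(self.df) == 0 or self.df["is_true"].notna().all()

    @property
    def uis_count(self) -> int:
        """Number of true junctions (unique insertion sites)."""
        if not self.classified:
            raise ValueError("table not yet classified; run classify_true first")
        return int(self.df["is_true"].sum()) if len(self.df) else 0

    def __len__(self) -> int:
        return len(self.df)


def putative_junctions(alignments: Iterable[AlignmentRecord]) -> JunctionTable:
    """De-duplicate alignments by (oriented entry, leftmost position).

    Reverse-strand records (SAM FLAG 16 from external alignments) are dropped
    here, so only forward-orientation placements are counted; the returned
    ``total_mapped_reads`` is the number of counted alignments.
    """
    counts: dict[tuple[str, int], int] = {}
    for aln in alignments:
        if aln.flag_reverse:
            continue
        key = (aln.ref_id, aln.pos)
        counts[key] = counts.get(key, 0) + 1
    return JunctionTable.from_counts(counts)


def classify_true(table: JunctionTable, cpm_min: float = 1.0) -> JunctionTable:
    """Flag junctions with CPM support at or above ``cpm_min`` as true.

    Junctions with fewer than ``cpm_min`` counts per million mapped reads are
    rejected (strict less-than), so a row at exactly the threshold is kept.
    Rows are retained either way, only flagged.
    """
    df = table.df.copy()
    if table.total_mapped_reads == 0:
        df["is_true"] = [False] * len(df)
    else:
        df["is_true"] = [bool(v) for v in df["cpm"] >= cpm_min]
    return JunctionTable(total_mapped_reads=table.total_mapped_reads, df=df)


def subsample_stream(items: Iterable[_T], n_target: int, seed: int = 0) -> Iterator[_T]:
    """Uniform, order-preserving sample of ``min(n_target, available)`` items.

    Single-pass reservoir sampling (algorithm R) over a stream of unknown
    length, deterministic for a given seed.  Warns when the stream holds
    fewer items than requested and returns them all.
    """
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    rng = random.Random(seed)
    reservoir: list[tuple[int, _T]] = []
    n_seen = 0
    for item in items:
        if n_seen < n_target:
            reservoir.append((n_seen, item))
        else:
            j = rng.randrange(n_seen + 1)
            if j < n_target:
                reservoir[j] = (n_seen, item)
        n_seen += 1
    if n_seen < n_target:
        warnings.warn(
            f"requested {n_target} items but only {n_seen} available; returning all",
            stacklevel=2,
        )
    reservoir.sort(key=lambda t: t[0])
    for _, item in reservoir:
        yield item


def subsample_pairs(pairs: Iterable[_T], n_target: int = 5_000_000, seed: int = 0) -> Iterator[_T]:
    """Subsample read pairs to a fixed depth (default 5 million) before calling."""
    return subsample_stream(pairs, n_target, seed)


@dataclass(slots=True)
class ConditionSummary:
    condition: str
    n_replicates: int
    mean_uis: float
    relative_pct: float
    variance_pct: float  # +/- half-range for 2 replicates, sd for more


@dataclass(slots=True)
class ComparisonReport:
    """Relative UIS recovery across conditions, against a reference condition."""

    reference_condition: str
    conditions: list[ConditionSummary]
    cfu: dict[str, int] = field(default_factory=dict)
    cfu_to_uis_ratio: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "condition": [c.condition for c in self.conditions],
                "n_replicates": [c.n_replicates for c in self.conditions],
                "mean_uis": [c.mean_uis for c in self.conditions],
                "relative_pct": [c.relative_pct for c in self.conditions],
                "variance_pct": [c.variance_pct for c in self.conditions],
            }
        )
        if self.cfu:
            df["cfu"] = [self.cfu.get(c.condition) for c in self.conditions]
            df["uis_per_cfu"] = [
                self.cfu_to_uis_ratio.get(c.condition) for c in self.conditions
            ]
        return df


def compare_conditions(
    tables: Mapping[str, Sequence[JunctionTable]],
    reference: str,
    cfu: Mapping[str, int] | None = None,
) -> ComparisonReport:
    """Summarize UIS recovery per condition relative to a reference.

    Each condition holds one or more replicate junction tables (classified).
    ``relative_pct`` is 100 x mean UIS over the reference's mean UIS; the
    spread is the +/- half-range of per-replicate relative percentages for 2
    replicates, or their standard deviation for more.  Optional CFU counts
    per condition yield the unique-mutants-per-CFU ratio.
    """
    if reference not in tables:
        raise ValueError(f"reference condition {reference!r} missing")
    ref_uis = [t.uis_count for t in tables[reference]]
    ref_mean = float(np.mean(ref_uis))
    if ref_mean == 0:
        raise ValueError("reference condition recovered zero UIS")
    conditions = []
    ratio: dict[str, float] = {}
    for name, reps in tables.items():
        if not reps:
            raise ValueError(f"condition {name!r} has no replicates")
        uis = np.array([t.uis_count for t in reps], dtype=float)
        rel = 100.0 * uis / ref_mean
        if len(uis) == 1:
            spread = 0.0
        elif len(uis) == 2:
            spread = float(rel.max() - rel.min()) / 2.0
        else:
            spread = float(rel.std(ddof=1))
        conditions.append(
            ConditionSummary(
                condition=name,
                n_replicates=len(uis),
                mean_uis=float(uis.mean()),
                relative_pct=float(rel.mean()),
                variance_pct=spread,
            )
        )
        if cfu and name in cfu:
            ratio[name] = float(uis.mean()) / cfu[name]
    return ComparisonReport(
        reference_condition=reference,
        conditions=conditions,
        cfu=dict(cfu) if cfu else {},
        cfu_to_uis_ratio=ratio,
    )


def recovery_metrics(
    table: JunctionTable,
    truth: InsertionTruth,
    genome,
    tolerance_bp: int = 0,
    min_abundance: float = 0.0,
) -> dict:
    """Precision/recall of true junctions against simulated truth sites.

    Truth sites are projected into oriented-entry space with the same
    convention as the mapper.  A true junction matches a truth site when on
    the same oriented entry within ``tolerance_bp``.  ``min_abundance``
    restricts the recall denominator to well-covered sites.  Precision over
    an empty junction set is 1.0 by convention.  ``detected_abundance_floor``
    is the smallest truth abundance among recovered sites (NaN if none).
    """
    truth_coords = truth_to_oriented(truth, genome)
    lengths = {r.id: len(r.sequence) for r in genome}
    abund: dict[tuple[str, int], float] = {}
    for row in truth.df.itertuples(index=False):
        if row.orientation == "FWD":
            key = (row.ref_id, int(row.pos))
        else:
            key = (row.ref_id + "_rc", lengths[row.ref_id] - int(row.pos) + 1)
        abund[key] = float(row.abundance)

    called = [
        (str(r.ref_entry), int(r.pos))
        for r in table.df.itertuples(index=False)
        if bool(r.is_true)
    ]

    def _match(coord: tuple[str, int], targets: set[tuple[str, int]]) -> bool:
        entry, pos = coord
        return any((entry, pos + d) in targets for d in range(-tolerance_bp, tolerance_bp + 1))

    called_set = set(called)
    matched_called = sum(1 for c in called if _match(c, truth_coords))
    eligible = {k for k in truth_coords if abund[k] >= min_abundance}
    matched_truth = {k for k in eligible if _match(k, called_set)}
    precision = matched_called / len(called) if called else 1.0
    recall = len(matched_truth) / len(eligible) if eligible else 1.0
    floor = min((abund[k] for k in matched_truth), default=float("nan"))
    return {
        "precision": precision,
        "recall": recall,
        "detected_abundance_floor": floor,
        "n_called_true": len(called),
        "n_truth": len(truth_coords),
        "n_truth_eligible": len(eligible),
    }
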