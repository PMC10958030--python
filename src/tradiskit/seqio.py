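"""Record types and readers/writers shared by every pipeline stage.

Covers FASTA references, paired FASTQ reads (plain or gzip), SAM text
ingest of external alignments, and the junction-table TSV/BED output.
FASTA/FASTQ parsing is delegated to Biopython and SAM parsing to pysam;
this module only defines the thin domain records the stages exchange.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator

import pysam
from Bio import SeqIO as BioSeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord as BioSeqRecord

__all__ = [
    "Orientation",
    "SeqRecord",
    "ReadPair",
    "AlignmentRecord",
    "PairingError",
    "pair_key",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_alignments",
    "write_junction_table",
    "read_junction_table",
]

_VALID_SEQ = re.compile(r"[ACGTN]+")


class Orientation(str, Enum):
    """Which oriented copy of a reference a coordinate lives on."""

    FWD = "FWD"
    RC = "RC"


class PairingError(ValueError):
    """Read 1 / Read 2 files disagree in record count or pair identifiers."""


@dataclass(slots=True)
class SeqRecord:
    """A named DNA sequence with optional per-base quality.

    ``sequence`` is uppercase over {A,C,G,T,N}; ``quality`` (when present)
    is a Phred string of equal length.
    """

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not _VALID_SEQ.fullmatch(self.sequence):
            raise ValueError(f"record {self.id!r}: sequence has non-ACGTN characters")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"record {self.id!r}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


_PAIR_SUFFIX = re.compile(r"/[12]$")


def pair_key(read_id: str) -> str:
    """Pair identifier: the id up to a trailing ``/1``/``/2`` or first space."""
    return _PAIR_SUFFIX.sub("", read_id.split(None, 1)[0])


@dataclass(slots=True)
class ReadPair:
    """A mate pair; both reads must share a pair identifier."""

    read1: SeqRecord
    read2: SeqRecord

    def __post_init__(self) -> None:
        if pair_key(self.read1.id) != pair_key(self.read2.id):
            raise PairingError(
                f"mates {self.read1.id!r} and {self.read2.id!r} do not pair"
            )


@dataclass(slots=True)
class AlignmentRecord:
    """A mapped Read 1: oriented reference entry plus 1-based leftmost POS.

    ``orientation`` says which oriented copy of the reference was hit (RC for
    entries named ``*_rc``).  ``flag_reverse`` marks SAM FLAG-16 records from
    external alignments, which callers drop to emulate the keep-FLAG-0 filter.
    """

    query_id: str
    ref_id: str
    orientation: Orientation
    pos: int
    mismatches: int = 0
    mapped_len: int = 1
    flag_reverse: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.query_id!r}: POS must be 1-based (got {self.pos})")
        if self.mapped_len < 1:
            raise ValueError(f"{self.query_id!r}: mapped_len must be >= 1")
        if self.mismatches < 0:
            raise ValueError(f"{self.query_id!r}: negative mismatch count")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read all records of a (optionally gzipped) FASTA file."""
    with _open_text(path) as fh:
        return [SeqRecord(id=r.id, sequence=str(r.seq)) for r in BioSeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        BioSeqIO.write(
            (BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
            fh,
            "fasta",
        )


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a 4-line FASTQ file, gzip handled transparently."""
    with _open_text(path) as fh:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                yield SeqRecord(id=title.split(None, 1)[0], sequence=seq, quality=qual)
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed FASTQ near line {n * 4 + 1}: {exc}"
            ) from exc


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write 4-line FASTQ; quality defaults to Q40 ('I') when absent."""
    with _open_text(path, "wt") as fh:
        for r in records:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


_SENTINEL = object()


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized mate pairs from two FASTQ files.

    Raises
    ------
    PairingError
        If the files hold unequal record counts or ids that do not pair.
    ValueError
        On a malformed (non 4-line) record, naming the approximate line.
    """
    it1, it2 = read_fastq(path1), read_fastq(path2)
    while True:
        r1 = next(it1, _SENTINEL)
        r2 = next(it2, _SENTINEL)
        if r1 is _SENTINEL and r2 is _SENTINEL:
            return
        if r1 is _SENTINEL or r2 is _SENTINEL:
            short = path1 if r1 is _SENTINEL else path2
            raise PairingError(f"unequal record counts: {short} ended early")
        yield ReadPair(r1, r2)


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> int:
    """Write mate pairs to two synchronized FASTQ files; returns pair count."""
    n = 0
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for p in pairs:
            for r, fh in ((p.read1, f1), (p.read2, f2)):
                qual = r.quality if r.quality is not None else "I" * len(r.sequence)
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM ingest
# ---------------------------------------------------------------------------


def read_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from SAM text.

    Unmapped records (FLAG 4) are skipped.  FLAG-16 (reverse-strand) records
    are emitted with ``flag_reverse=True`` so the caller can apply the
    keep-forward-only filter; FLAG-0 records come out with
    ``flag_reverse=False``.  Orientation follows the oriented-entry naming
    convention (``*_rc`` means the reverse-complement copy).
    """
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise ValueError(f"{path}: cannot parse SAM: {exc}") from exc
    with sam:
        try:
            for aln in sam:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                ref = aln.reference_name
                mlen = aln.reference_length or len(aln.query_sequence or "")
                try:
                    nm = int(aln.get_tag("NM"))
                except KeyError:
                    nm = 0
                yield AlignmentRecord(
                    query_id=aln.query_name,
                    ref_id=ref,
                    orientation=Orientation.RC if ref.endswith("_rc") else Orientation.FWD,
                    pos=aln.reference_start + 1,
                    mismatches=nm,
                    mapped_len=max(1, mlen),
                    flag_reverse=aln.is_reverse,
                )
        except (ValueError, OSError) as exc:
            raise ValueError(f"{path}: malformed SAM body: {exc}") from exc


# ---------------------------------------------------------------------------
# Junction tables
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["ref", "orientation", "pos", "count", "cpm", "is_true"]


def _split_entry(ref_entry: str) -> tuple[str, str]:
    if ref_entry.endswith("_rc"):
        return ref_entry[:-3], Orientation.RC.value
    return ref_entry, Orientation.FWD.value


def write_junction_table(table, path: str | Path, format: str = "tsv") -> None:
    """Write a junction table as TSV or BED6.

    TSV columns are ``ref, orientation, pos (1-based), count, cpm, is_true``
    with the mapped-read total in a ``#total_mapped_reads=`` header comment.
    BED6 converts each junction to the 0-based half-open interval
    ``[pos-1, pos)`` with ``name`` = orientation and ``score`` = read count.
    """
    fmt = format.lower()
    if fmt not in ("tsv", "bed"):
        raise ValueError(f"unknown junction table format {format!r}")
    with _open_text(path, "wt") as fh:
        if fmt == "tsv":
            fh.write(f"#total_mapped_reads={table.total_mapped_reads}\n")
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for row in table.df.itertuples(index=False):
                ref, orient = _split_entry(row.ref_entry)
                is_true = "" if row.is_true is None else str(bool(row.is_true))
                fh.write(
                    f"{ref}\t{orient}\t{row.pos}\t{row.count}\t{row.cpm:.6g}\t{is_true}\n"
                )
        else:
            for row in table.df.itertuples(index=False):
                ref, orient = _split_entry(row.ref_entry)
                strand = "+" if orient == Orientation.FWD.value else "-"
                fh.write(
                    f"{ref}\t{row.pos - 1}\t{row.pos}\t{orient}\t{row.count}\t{strand}\n"
                )


def read_junction_table(path: str | Path):
    """Read a junction-table TSV written by :func:`write_junction_table`."""
    from .junctions import JunctionTable  # deferred: junctions imports seqio

    total = 0
    rows: list[tuple[str, int, int, float, bool | None]] = []
    with _open_text(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#total_mapped_reads="):
                total = int(line.split("=", 1)[1])
                continue
            if not header_seen:
                header_seen = True  # column header line
                continue
            ref, orient, pos, count, cpm, is_true = line.split("\t")
            entry = ref + "_rc" if orient == Orientation.RC.value else ref
            flag = None if is_true == "" else is_true == "True"
            rows.append((entry, int(pos), int(count), float(cpm), flag))
    return JunctionTable.from_rows(rows, total_mapped_reads=total)
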