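"""Synthetic transposon-mutant sequencing libraries with known truth.

Simulates (i) a random genome, (ii) a mutant library as a set of unique
insertion sites with log-normal clone abundances, and (iii) 150-bp paired-end
reads with the junction-fragment layout::

    Read 1 = balancer(3-6 nt) + anchor(20) + mosaic end(19) + genomic sequence
    Read 2 = reverse complement of the distal end of the fragment

A tunable fraction of pairs are plain genomic (non-junction) fragments,
emulating the carryover that makes real libraries less than 100% usable.
Sequencing error is substitution-only, i.i.d. per base.  All randomness flows
from a single seed; reruns are byte-identical.

Coordinate convention: a truth site's ``pos`` is the 1-based coordinate of the
first genomic base downstream of the transposon *in read orientation*.  A FWD
site reads off the plus strand starting at ``pos``; an RC site reads off the
minus strand, i.e. its Read 1 genomic segment is the reverse complement of the
plus-strand window ending at ``pos``.  After dual-orientation mapping a FWD
site surfaces at ``(ref, pos)`` and an RC site at ``(ref_rc, L - pos + 1)``
where ``L`` is the reference length (see :func:`truth_to_oriented`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .layout import ANCHOR20, ME19, revcomp
from .seqio import Orientation, ReadPair, SeqRecord, write_fasta, write_fastq_pairs

__all__ = [
    "SimConfig",
    "InsertionTruth",
    "SimOutput",
    "simulate_genome",
    "sample_truth",
    "generate_pairs",
    "simulate_reads",
    "truth_to_oriented",
]

_JUNCTION_PREFIX = ANCHOR20 + ME19  # 39 nt between balancer and genome
_BASES = "ACGT"


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Study conditions for one simulated library.

    Defaults model the real workflow: 300-400 bp fragments, 150 bp paired-end
    reads, ~80% of pairs carrying a junction (the observed usable-read scale),
    log-normal clone-abundance skew with shape 1.0, and a 0.1% per-base
    substitution error rate.
    """

    n_insertions: int = 1000
    n_read_pairs: int = 100_000
    genome_len: int = 200_000
    n_chromosomes: int = 1
    abundance_sigma: float = 1.0
    junction_fraction: float = 0.8
    fragment_len_range: tuple[int, int] = (300, 400)
    read_len: int = 150
    base_error_rate: float = 0.001
    balancer_mode: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.junction_fraction <= 1.0:
            raise ValueError("junction_fraction must be in [0, 1]")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.n_insertions > self.genome_len - 2 * self.read_len:
            raise ValueError("n_insertions too large for the genome length")
        if self.balancer_mode not in ("random", "fixed_set"):
            raise ValueError(f"unknown balancer_mode {self.balancer_mode!r}")


@dataclass(slots=True)
class InsertionTruth:
    """The simulated library: unique insertion sites with clone abundances.

    ``df`` columns: ``ref_id`` (str), ``pos`` (1-based int), ``orientation``
    (``FWD``/``RC``), ``abundance`` (float, normalized to sum 1).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        keys = list(zip(self.df["ref_id"], self.df["pos"], self.df["orientation"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (ref, pos, orientation) truth sites")
        total = float(self.df["abundance"].sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InsertionTruth":
        return cls(pd.read_csv(path, sep="\t", dtype={"ref_id": str}))


@dataclass(slots=True)
class SimOutput:
    """File manifest of one simulation run."""

    genome_fasta: Path
    fastq_r1: Path
    fastq_r2: Path
    truth_tsv: Path
    manifest: dict


def simulate_genome(length: int, n_chrom: int = 1, seed: int = 0) -> list[SeqRecord]:
    """Seeded random ACGT chromosomes ``chr1..chrN`` splitting ``length`` evenly."""
    if length < 1000:
        raise ValueError("genome length must be at least 1000 bp")
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    sizes = [length // n_chrom + (1 if i < length % n_chrom else 0) for i in range(n_chrom)]
    records = []
    for i, size in enumerate(sizes, start=1):
        codes = rng.integers(0, 4, size=size, dtype=np.uint8)
        seq = codes.tobytes().translate(bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT"))
        records.append(SeqRecord(id=f"chr{i}", sequence=seq.decode("ascii")))
    return records


def sample_truth(
    genome: list[SeqRecord],
    n: int,
    sigma: float = 1.0,
    seed: int = 0,
    read_len: int = 150,
) -> InsertionTruth:
    """Draw ``n`` unique insertion sites with log-normal clone abundances.

    Positions are uniform over each chromosome, at least ``read_len`` from
    either end so every junction read fits; orientations are FWD/RC with equal
    probability; abundances are i.i.d. log-normal(0, sigma) normalized to 1.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([len(r.sequence) for r in genome])
    capacity = int(np.sum(np.maximum(0, lengths - 2 * read_len + 1))) * 2
    if n > capacity:
        raise ValueError(f"cannot place {n} unique sites (capacity {capacity})")
    seen: set[tuple[int, int, int]] = set()
    rows: list[tuple[str, int, str]] = []
    weights = np.maximum(0, lengths - 2 * read_len + 1).astype(float)
    weights /= weights.sum()
    while len(rows) < n:
        m = n - len(rows)
        chrom = rng.choice(len(genome), size=m, p=weights)
        orient = rng.integers(0, 2, size=m)
        for c, o in zip(chrom, orient):
            lo, hi = read_len, int(lengths[c]) - read_len  # 1-based inclusive
            pos = int(rng.integers(lo, hi + 1))
            key = (int(c), pos, int(o))
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                (genome[c].id, pos, Orientation.FWD.value if o == 0 else Orientation.RC.value)
            )
    abund = rng.lognormal(mean=0.0, sigma=sigma, size=n) if sigma > 0 else np.ones(n)
    abund = abund / abund.sum()
    df = pd.DataFrame(rows, columns=["ref_id", "pos", "orientation"])
    df["abundance"] = abund
    return InsertionTruth(df)


def truth_to_oriented(truth: InsertionTruth, genome: list[SeqRecord]) -> set[tuple[str, int]]:
    """Project truth sites into oriented-entry junction coordinates.

    FWD sites map to ``(ref, pos)``; RC sites to ``(ref + "_rc", L - pos + 1)``
    — the leftmost coordinate their junction reads take on the
    reverse-complement reference copy.
    """
    lengths = {r.id: len(r.sequence) for r in genome}
    out: set[tuple[str, int]] = set()
    for row in truth.df.itertuples(index=False):
        if row.orientation == Orientation.FWD.value:
            out.add((row.ref_id, int(row.pos)))
        else:
            out.add((row.ref_id + "_rc", lengths[row.ref_id] - int(row.pos) + 1))
    return out


def _decode_bases(codes: np.ndarray) -> str:
    return codes.astype(np.uint8).tobytes().translate(
        bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")
    ).decode("ascii")


_BALANCER_FIXED = ("TAC", "GATC", "CTGAC", "ATCGAT")


def generate_pairs(
    config: SimConfig,
    genome: list[SeqRecord],
    truth: InsertionTruth,
    yield_site: bool = False,
    batch: int = 50_000,
) -> Iterator:
    """Stream simulated read pairs (optionally tagged with their truth row).

    With probability ``junction_fraction`` a pair is a junction fragment from
    a truth site drawn with probability equal to its abundance; otherwise it
    is a plain genomic fragment.  Fragment lengths are uniform in
    ``fragment_len_range``; each read base is substituted independently with
    probability ``base_error_rate``.  Yields ``ReadPair`` or, with
    ``yield_site=True``, ``(ReadPair, site_index)`` where ``site_index`` is
    -1 for non-junction pairs.
    """
    rng = np.random.default_rng(config.seed)
    chrom_seqs = [r.sequence for r in genome]
    chrom_ids = {r.id: i for i, r in enumerate(genome)}
    lengths = np.array([len(s) for s in chrom_seqs])

    t_chrom = np.array([chrom_ids[r] for r in truth.df["ref_id"]])
    t_pos = truth.df["pos"].to_numpy()
    t_fwd = (truth.df["orientation"] == Orientation.FWD.value).to_numpy()
    t_abund = truth.df["abundance"].to_numpy()
    t_abund = t_abund / t_abund.sum()

    frag_lo, frag_hi = config.fragment_len_range
    rl = config.read_len
    prefix = _JUNCTION_PREFIX
    win_weights = np.maximum(1, lengths - frag_hi).astype(float)
    win_weights /= win_weights.sum()

    emitted = 0
    pair_idx = 0
    while emitted < config.n_read_pairs:
        b = min(batch, config.n_read_pairs - emitted)
        is_jx = rng.random(b) < config.junction_fraction
        sites = rng.choice(len(t_pos), size=b, p=t_abund)
        frags = rng.integers(frag_lo, frag_hi + 1, size=b)
        bal_lens = rng.integers(3, 7, size=b)
        bal_codes = rng.integers(0, 4, size=(b, 6), dtype=np.uint8)
        bal_pick = rng.integers(0, len(_BALANCER_FIXED), size=b)
        nj_chrom = rng.choice(len(chrom_seqs), size=b, p=win_weights)
        nj_start = rng.random(b)  # scaled per pair below

        # error positions drawn per batch as a Bernoulli field over max length
        if config.base_error_rate > 0:
            err_mask = rng.random((b, 2, rl)) < config.base_error_rate
            err_rows, err_mate, err_cols = np.nonzero(err_mask)
            err_shift = rng.integers(1, 4, size=len(err_rows), dtype=np.uint8)
            err_ptr = 0
            order = np.lexsort((err_cols, err_mate, err_rows))
            err_rows, err_mate, err_cols, err_shift = (
                err_rows[order], err_mate[order], err_cols[order], err_shift[order],
            )
        else:
            err_rows = np.empty(0, dtype=int)
            err_ptr = 0

        for j in range(b):
            if is_jx[j]:
                s = int(sites[j])
                c = int(t_chrom[s])
                pos = int(t_pos[s])
                bal_len = int(bal_lens[j])
                if config.balancer_mode == "random":
                    balancer = _decode_bases(bal_codes[j, :bal_len])
                else:
                    balancer = _BALANCER_FIXED[int(bal_pick[j])]
                    bal_len = len(balancer)
                g_nominal = int(frags[j]) - len(prefix) - bal_len
                if t_fwd[s]:
                    avail = len(chrom_seqs[c]) - (pos - 1)
                    gseg = chrom_seqs[c][pos - 1 : pos - 1 + min(g_nominal, avail)]
                else:
                    avail = pos
                    gseg = revcomp(chrom_seqs[c][pos - min(g_nominal, avail) : pos])
                fragment = balancer + prefix + gseg
                site_idx = s
            else:
                c = int(nj_chrom[j])
                flen = int(frags[j])
                start = int(nj_start[j] * (len(chrom_seqs[c]) - flen))
                fragment = chrom_seqs[c][start : start + flen]
                site_idx = -1
            r1 = fragment[:rl]
            r2 = revcomp(fragment)[:rl]

            if config.base_error_rate > 0:
                # apply this pair's pre-drawn substitution errors
                while err_ptr < len(err_rows) and err_rows[err_ptr] == j:
                    mate = err_mate[err_ptr]
                    col = int(err_cols[err_ptr])
                    shift = int(err_shift[err_ptr])
                    target = r1 if mate == 0 else r2
                    if col < len(target):
                        old = _BASES.find(target[col])
                        new = _BASES[(old + shift) % 4]
                        target = target[:col] + new + target[col + 1 :]
                        if mate == 0:
                            r1 = target
                        else:
                            r2 = target
                    err_ptr += 1

            rid = f"sim{pair_idx:08d}"
            pair = ReadPair(
                SeqRecord(id=rid + "/1", sequence=r1, quality="I" * len(r1)),
                SeqRecord(id=rid + "/2", sequence=r2, quality="I" * len(r2)),
            )
            pair_idx += 1
            yield (pair, site_idx) if yield_site else pair
        emitted += b


def simulate_reads(
    config: SimConfig, genome: list[SeqRecord], truth: InsertionTruth, outdir: str | Path
) -> SimOutput:
    """Run the generator and write genome FASTA, FASTQ pair and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_fasta = outdir / "genome.fasta"
    fastq_r1 = outdir / "reads_R1.fastq"
    fastq_r2 = outdir / "reads_R2.fastq"
    truth_tsv = outdir / "truth.tsv"
    write_fasta(genome, genome_fasta)
    truth.to_tsv(truth_tsv)
    n = write_fastq_pairs(generate_pairs(config, genome, truth), fastq_r1, fastq_r2)
    manifest = {
        "n_read_pairs": n,
        "n_insertions": len(truth),
        "seed": config.seed,
        "junction_fraction": config.junction_fraction,
        "base_error_rate": config.base_error_rate,
        "fragment_len_range": list(config.fragment_len_range),
        "read_len": config.read_len,
        "genome_len": int(sum(len(r.sequence) for r in genome)),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return SimOutput(
        genome_fasta=genome_fasta,
        fastq_r1=fastq_r1,
        fastq_r2=fastq_r2,
        truth_tsv=truth_tsv,
        manifest=manifest,
    )
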