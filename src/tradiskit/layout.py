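"""Junction-fragment layout constants and transposome arithmetic.

The library-preparation scheme sequences transposon-genome junctions.  Read 1
of a junction fragment has a fixed 5' layout::

    [balancer 3-6 nt][anchor 20 nt][mosaic end 19 nt][genomic sequence ...]

The anchor is the transposon-internal priming site of the first-PCR forward
primer; the 19-bp Tn5 mosaic end (ME) is the transposase recognition sequence
that remains attached to the genome after insertion.  Read trimming removes
the first 29 nt (anchor + 5' 9 nt of the ME) with mismatch tolerance, then the
remaining 10-nt ME remnant exactly.  Every module that touches these sequences
(simulator, trimmer, cassette builder) imports them from here.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

__all__ = [
    "ANCHOR20",
    "ME5",
    "ME10",
    "ME19",
    "ROUND1_PATTERN",
    "LayoutConstants",
    "CassetteSpec",
    "TransposomeMix",
    "LayoutError",
    "revcomp",
    "build_cassette",
    "primer_components",
    "molar_ratio",
    "complete_transposome_fraction",
]

#: 20-nt transposon-internal anchor targeted by the first-PCR forward primer.
ANCHOR20 = "GCATGCAAGCTTCAGGGTTG"
#: 5' 9 nt of the 19-bp Tn5 mosaic end (trimmed together with the anchor).
ME5 = "AGATGTGTA"
#: Remaining 10 nt of the mosaic end (trimmed exactly in round 2).
ME10 = "TAAGAGACAG"
#: Full 19-bp Tn5 mosaic end.
ME19 = ME5 + ME10
#: 29-nt round-1 trimming pattern: anchor followed by the 5' ME portion.
ROUND1_PATTERN = ANCHOR20 + ME5

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class LayoutError(ValueError):
    """A sequence does not conform to the expected fragment/primer layout."""


@dataclass(frozen=True, slots=True)
class LayoutConstants:
    """Immutable bundle of the junction layout constants.

    Attributes
    ----------
    anchor20, me5, me10, me19, round1_pattern
        The junction sequences described in the module docstring.
    balancer_len_range
        Inclusive length range of the balancer, the 3-6 variable bases in the
        first-PCR primer that stagger cluster phasing.
    nextera_partial_len
        Length of the partial Nextera i5 adapter at the primer 5' end.
    read_len
        Sequencing read length (150 bp paired-end).
    """

    anchor20: str = ANCHOR20
    me5: str = ME5
    me10: str = ME10
    me19: str = ME19
    round1_pattern: str = ROUND1_PATTERN
    balancer_len_range: tuple[int, int] = (3, 6)
    nextera_partial_len: int = 34
    read_len: int = 150

    def __post_init__(self) -> None:
        if len(self.round1_pattern) != 29:
            raise LayoutError("round-1 pattern must be 29 nt")
        if len(self.me19) != 19 or self.me19 != self.me5 + self.me10:
            raise LayoutError("mosaic end must be the 9+10 nt split, 19 nt total")
        if self.round1_pattern != self.anchor20 + self.me5:
            raise LayoutError("round-1 pattern must equal anchor + 5' ME")


DEFAULT_LAYOUT = LayoutConstants()

#: Default length of the KAN2 kanamycin-resistance transposon cassette, bp.
KAN2_LEN = 1221


@dataclass(frozen=True, slots=True)
class CassetteSpec:
    """Specification for a synthetic transposon cassette.

    The cassette is a stand-in for the vendor KAN2 sequence: correct total
    length and correct terminal sequences (mosaic ends, read-side anchor),
    seeded-random interior.
    """

    total_len: int = KAN2_LEN
    seed: int = 0

    # room for a mosaic end at each terminus plus the read-side anchor
    MIN_LEN = 2 * 19 + 20

    def __post_init__(self) -> None:
        if self.total_len < self.MIN_LEN:
            raise LayoutError(
                f"cassette length {self.total_len} below minimum {self.MIN_LEN}"
            )


def _random_filler(n: int, rng: random.Random, max_homopolymer: int = 6) -> str:
    """Seeded random filler at 50% GC with homopolymer runs capped."""
    bases = "ACGT"
    out: list[str] = []
    run = 0
    prev = ""
    while len(out) < n:
        b = bases[rng.randrange(4)]
        if b == prev:
            run += 1
            if run > max_homopolymer:
                continue
        else:
            prev, run = b, 1
        out.append(b)
    return "".join(out)


def build_cassette(spec: CassetteSpec = CassetteSpec()):
    """Build a synthetic transposon cassette sequence.

    The returned record has the read-side terminus ``anchor20 + me19`` (so a
    junction Read 1 runs anchor, mosaic end, then genome) and the reverse
    complement of the mosaic end at the opposite terminus.  The interior is
    seeded-random filler; only length and termini matter downstream.

    Returns
    -------
    SeqRecord
        Record id ``"KAN2_synthetic"`` of length ``spec.total_len``.
    """
    from .seqio import SeqRecord  # local import to avoid a cycle

    rng = random.Random(spec.seed)
    left = revcomp(ME19)
    right = ANCHOR20 + ME19
    fill_len = spec.total_len - len(left) - len(right)
    while True:
        filler = _random_filler(fill_len, rng)
        seq = left + filler + right
        # termini must be unique: exactly one read-side anchor+ME occurrence
        if seq.count(right) == 1 and seq.count(left) == 1:
            return SeqRecord(id="KAN2_synthetic", sequence=seq)


def primer_components(primer: str) -> dict[str, str]:
    """Split a first-PCR forward primer into its three components.

    The primer is ``partial Nextera i5 adapter (34 nt) + balancer (3-6 nt) +
    anchor (20 nt)``.  The anchor must be the exact 3' suffix.

    Returns
    -------
    dict with keys ``nextera_part``, ``balancer``, ``anchor``.

    Raises
    ------
    LayoutError
        If the primer does not end with the anchor or the balancer length is
        outside 3-6 nt.
    """
    primer = primer.upper()
    n34 = DEFAULT_LAYOUT.nextera_partial_len
    lo, hi = DEFAULT_LAYOUT.balancer_len_range
    if len(primer) < n34 + lo + len(ANCHOR20):
        raise LayoutError(f"primer too short ({len(primer)} nt) for the 34+3+20 layout")
    if not primer.endswith(ANCHOR20):
        raise LayoutError("primer does not end with the 20-nt transposon anchor")
    balancer = primer[n34 : len(primer) - len(ANCHOR20)]
    if not lo <= len(balancer) <= hi:
        raise LayoutError(
            f"balancer length {len(balancer)} outside the {lo}-{hi} nt range"
        )
    return {
        "nextera_part": primer[:n34],
        "balancer": balancer,
        "anchor": ANCHOR20,
    }


@dataclass(frozen=True, slots=True)
class TransposomeMix:
    """Composition of a transposome assembly reaction.

    Tn5 transposase is mixed with transposon DNA by volume; the molar ratio of
    enzyme to cassette determines how many complete transposomes (2 Tn5 per
    cassette) can form.

    Attributes
    ----------
    dna_mass_ng : transposon DNA input mass, ng.
    cassette_len_bp : cassette length, bp.
    dna_conc_ng_per_ul : concentration of the DNA solution, ng/uL.
    tn5_conc_uM : Tn5 transposase concentration, uM.
    volume_ratio_tn5_to_dna : parts of Tn5 solution per part of DNA solution.
    avg_bp_mass_da : average mass of one double-stranded base pair, Da
        (default 650, the standard dsDNA approximation).
    """

    dna_mass_ng: float
    cassette_len_bp: int
    dna_conc_ng_per_ul: float
    tn5_conc_uM: float
    volume_ratio_tn5_to_dna: float
    avg_bp_mass_da: float = 650.0

    def __post_init__(self) -> None:
        for name in (
            "dna_mass_ng",
            "cassette_len_bp",
            "dna_conc_ng_per_ul",
            "tn5_conc_uM",
            "volume_ratio_tn5_to_dna",
            "avg_bp_mass_da",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def molar_ratio(mix: TransposomeMix) -> float:
    """Molar ratio of Tn5 transposase to transposon DNA in the assembly mix.

    Transposon moles come from mass over molecular weight
    (``cassette_len_bp * avg_bp_mass_da`` g/mol); Tn5 moles come from the
    pipetted volume (``dna_mass / dna_conc * volume_ratio`` uL) times the
    enzyme molarity.  The ratio is independent of the DNA mass at fixed
    concentration, since both mole quantities scale linearly with it.
    """
    transposon_mol = mix.dna_mass_ng * 1e-9 / (mix.cassette_len_bp * mix.avg_bp_mass_da)
    dna_volume_ul = mix.dna_mass_ng / mix.dna_conc_ng_per_ul
    tn5_mol = dna_volume_ul * mix.volume_ratio_tn5_to_dna * mix.tn5_conc_uM * 1e-12
    return tn5_mol / transposon_mol


def complete_transposome_fraction(ratio: float) -> float:
    """Maximum fraction of Tn5 molecules that can sit in complete transposomes.

    A complete transposome binds 2 Tn5 molecules per transposon, so with a
    Tn5:transposon molar ratio *r* at most ``min(1, 2/r)`` of the enzyme can be
    productively loaded.
    """
    if ratio <= 0:
        raise ValueError("molar ratio must be positive")
    return min(1.0, 2.0 / ratio)
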