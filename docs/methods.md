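# Methods

## The workflow

Transposon mutagenesis with a Tn5 transposome inserts a selectable cassette
(here a 1221-bp kanamycin-resistance "KAN2" cassette flanked by the 19-bp Tn5
mosaic end, ME) at quasi-random genomic positions. Sequencing the
transposon–genome junctions enumerates the mutants: each *unique insertion
site* (UIS) is one clone in the library. The library design amplifies
junction fragments with a first-PCR primer made of a 34-nt partial Nextera
i5 adapter, a 3–6 nt balancer (random-offset bases that keep per-cycle
nucleotide diversity high on patterned flow cells), and a 20-nt anchor
inside the cassette. Read 1 of a junction fragment is therefore

```
balancer (3–6) + anchor (20) + ME (19) + genome (to 150 bp)
```

and the analysis is: trim the fixed prefix in two rounds, map what remains,
and call junctions from leftmost mapped coordinates.

Assumptions inherited from this design: junction identity is entirely
determined by the first mapped base (read length and fragment length do not
matter); only Read 1 is informative (Read 2 is carried for pair bookkeeping
and discarded whenever its mate fails a filter); and insertion orientation
is recovered by mapping against both the reference and its reverse
complement rather than by interpreting SAM strand flags.

## Trimming

Round 1 searches the first 37 bases of Read 1 (max balancer 6 + pattern 29 +
2 nt indel slack) for the 29-nt anchor + 5′-ME pattern with at most
floor(0.10 × 29) = 2 errors. The default error model is semi-global edit
distance (substitutions and indels at unit cost, pattern fully contained in
the window), computed with edlib's infix mode; a Hamming
(substitution-only) mode is provided and is never more permissive. Ties are
broken by fewest errors, then smallest match end. Everything up to the match
end is removed — this deletes the balancer implicitly, which is why no
separate balancer-removal step exists. Round 2 then requires the exact
10-nt ME remnant (`TAAGAGACAG`) at the new 5′ end, zero mismatches, and
removes it. Reads shorter than 20 nt after trimming are dropped
(a mappability floor; 20 nt is just below the mapper's 21-nt seed, so such
reads could never seed anyway). The usable-read fraction is kept reads over
raw input pairs.

Consequence worth knowing: with per-base substitution error ε, a junction
read survives round 2 with probability (1−ε)^10, so at ε = 0.005 about 4.9%
of genuine junction reads are discarded and the usable fraction sits ~4
percentage points below the true junction fraction. This is the designed,
literal behaviour of the exact-match round, not a defect; at the default
ε = 0.001 the loss is ~1%.

## Mapping

The reference is duplicated: each entry is indexed as-is and reverse
complemented (`chr1`, `chr1_rc`), with 21-mer seeds. A read is seeded on all
its k-mers, extended ungapped on each candidate diagonal, scored by Hamming
mismatches, and reported only if the best placement is within
floor(0.05 × read length) mismatches **and** strictly better than the second
best — ambiguous reads (e.g. from repeats) are discarded rather than placed
arbitrarily. Ungapped extension is sufficient because the simulator's error
model is substitution-only and junction identity uses only the leftmost
coordinate. For reads with ≤ 2% substitutions and k = 21, a true placement
always shares an intact seed (pigeonhole), so the heuristic is exactly
equivalent to an exhaustive scan; the test suite asserts this equivalence
against an independent numpy full-scan oracle and cross-checks coordinates
against `bwa mem` on the dual-orientation FASTA. Coordinates are 1-based
leftmost (SAM POS semantics) within the oriented entry;
`mapper.rc_to_forward_leftmost` projects `_rc` coordinates back to forward
space for interpretation, but junction identity deliberately stays in
oriented space because opposite-orientation insertions at the same base are
distinct mutants.

External alignments are ingested from SAM text via pysam (a valid header is
required); only primary, mapped, forward-strand records — FLAG 0 — are
counted, matching the original filter bit-for-bit.

## Junction calling

Forward alignments are de-duplicated by (oriented entry, position); the
group sizes are read counts of *putative junctions*. With N mapped reads,
junctions with count/N × 10⁶ < 1 CPM are rejected (strict less-than: a
junction at exactly 1.0 CPM is kept) and the remainder are *true junctions*.
The CPM denominator is the post-filter mapped-read count. `classify_true` is
monotone in the threshold, and junction counts always sum to N.

Subsampling to a fixed depth (default 5,000,000 pairs) uses single-pass
reservoir sampling (algorithm R) over the raw pairs, order-preserving and
seeded, before any trimming — depth normalization precedes UIS
determination. Condition comparison reports, per condition, the
replicate-mean UIS as a percentage of a reference condition's mean; the
spread is the ± half-range of per-replicate percentages for two replicates
and the standard deviation for more. Optional CFU counts per condition
yield UIS/CFU, the fraction of colonies that are unique mutants.

## The simulator

`simlib` emulates: junction fragments with the full Read-1 layout and a
random 3–6 nt balancer; fragment lengths uniform in 300–400 bp; Read 2 as
the reverse complement of the fragment's distal end; a `junction_fraction`
of pairs carrying junctions (default 0.8, the scale observed in real
libraries of this design) with the rest plain genomic fragments; clone
abundances i.i.d. log-normal(0, σ = 1) normalized to 1 (a one-parameter
model of clonal expansion during selection; per-site read counts are then
multinomial); and i.i.d. substitution errors (default 0.001). It does *not*
model: PCR duplicates, GC or fragmentation bias, indel errors, quality-score
degradation (qualities are constant Q40 and never consulted), adapter
read-through artifacts (all non-usable reads are genomic carryover), or the
9-bp target-site duplication of real Tn5 integration (invisible to
leftmost-coordinate junction calling). Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under substitution noise
and abundance skew — not robustness to indels, duplicates or biased
coverage in real data.

Truth sites are unique (reference, position, orientation) triples placed at
least one read length from contig ends; orientations are equiprobable. A FWD
site's junction reads map to `(ref, pos)`; an RC site's to
`(ref_rc, L − pos + 1)`.

## Numerical and design choices

- Random filler (genome, cassette interior) is 50% GC; the cassette filler
  additionally caps homopolymers at 6 nt and is regenerated in the
  (astronomically unlikely) event its termini recur internally.
- Transposome arithmetic uses 650 Da per base pair of dsDNA (configurable).
  The molar-ratio operation exposes DNA mass, concentration, enzyme
  molarity and volume ratio explicitly; the worked example (400 ng of a
  1221-bp cassette at 100 ng/µL with 2 volumes of 1 µM Tn5) gives 15.87:1
  and a maximum complete-transposome fraction 2/15.87 ≈ 0.126.
- Pipeline seeding: one global seed, fanned out as seed + stage ordinal, so
  stages are independently reproducible; all outputs are byte-identical
  across reruns at a fixed seed.
- Degenerate inputs: an empty trim stream yields usable fraction 0; an
  empty junction table has UIS 0 and precision 1.0 by convention; a
  subsample request larger than the stream warns and returns everything;
  a reference shorter than one seed is skipped with a warning.
- Problem sizes in the test suite were chosen for desk-scale runs: oracle
  equivalence on a 40 kb genome × 5,000 reads, trimming oracle on 10,000
  reads, end-to-end recovery on a 200 kb genome with 1,000 sites and
  2,000,000 pairs, subsampling from a 6,000,000-record pool.

## Known limitations

- The mapper is exact only within the substitution regime described above;
  reads with indels relative to the reference will drop out rather than
  map approximately.
- Junction calling has no positional tolerance by default (tolerance is a
  parameter of the recovery metric, not of calling), so an indel-induced
  off-by-one placement would register as a separate putative junction —
  in practice removed by the CPM filter.
- SAM ingest requires a header (pysam); headerless SAM fragments are not
  accepted.
- The condition-comparison report consumes junction tables from any source
  but does not model selection dynamics itself.
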