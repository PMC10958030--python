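import shutil
import subprocess

import pytest

from conftest import random_dna
from oracles import exhaustive_map
from tradiskit import seqio
from tradiskit.layout import revcomp
from tradiskit.mapper import (
    MapPolicy,
    build_index,
    map_read,
    map_reads,
    rc_to_forward_leftmost,
)
from tradiskit.seqio import Orientation, SeqRecord
from tradiskit.simlib import (
    SimConfig,
    generate_pairs,
    sample_truth,
    simulate_genome,
    truth_to_oriented,
)
from tradiskit.trimmer import filter_pairs

POLICY = MapPolicy()


@pytest.fixture(scope="module")
def indexed_genome(small_genome):
    return build_index(small_genome, POLICY)


class TestIndex:
    def test_dual_entries_and_kmer_count(self):
        ref = simulate_genome(10_000, 1, seed=30)
        idx = build_index(ref, POLICY)
        assert len(idx) == 2
        assert [e for e, _ in idx.entries] == ["chr1", "chr1_rc"]
        n_positions = sum(len(v) for v in idx.kmers.values())
        assert n_positions == (10_000 - POLICY.k + 1) * 2

    def test_rc_entry_is_reverse_complement(self, indexed_genome, small_genome):
        assert indexed_genome.entry_seq(1) == revcomp(small_genome[0].sequence)
        assert revcomp(indexed_genome.entry_seq(1)) == indexed_genome.entry_seq(0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            build_index([], POLICY)

    def test_short_entry_skipped_with_warning(self, small_genome):
        with pytest.warns(UserWarning, match="skipped"):
            idx = build_index(small_genome + [SeqRecord("tiny", "ACGT")], POLICY)
        assert len(idx) == 2


class TestMapRead:
    def test_exact_forward_substring(self, indexed_genome, small_genome):
        seq = small_genome[0].sequence[1000:1111]  # 1-based 1001, 111 nt
        rec = map_read(SeqRecord("q", seq), indexed_genome)
        assert rec is not None
        assert (rec.ref_id, rec.pos, rec.mismatches) == ("chr1", 1001, 0)
        assert rec.orientation is Orientation.FWD

    def test_revcomp_substring_maps_to_rc_entry(self, indexed_genome, small_genome):
        L = len(small_genome[0].sequence)
        seq = revcomp(small_genome[0].sequence[5000:5100])  # fwd start 5001, len 100
        rec = map_read(SeqRecord("q", seq), indexed_genome)
        assert rec is not None
        assert rec.ref_id == "chr1_rc"
        assert rec.pos == L - 5100 + 1
        # projection helper recovers the forward-space leftmost coordinate
        assert rc_to_forward_leftmost(rec.pos, rec.mapped_len, L) == 5001

    def test_duplicated_locus_is_ambiguous(self, rng):
        block = random_dna(rng, 300)
        chrom = random_dna(rng, 2000) + block + random_dna(rng, 2000) + block + random_dna(rng, 700)
        idx = build_index([SeqRecord("chr1", chrom)], POLICY)
        assert map_read(SeqRecord("q", block[50:150]), idx) is None

    def test_junk_read_unmapped(self, indexed_genome, rng):
        assert map_read(SeqRecord("q", random_dna(rng, 100)), indexed_genome) is None

    def test_short_read_skipped(self, indexed_genome):
        assert map_read(SeqRecord("q", "ACGTACGTACGT"), indexed_genome) is None

    def test_oracle_equivalence(self, rng):
        """Seed-and-extend agrees with the exhaustive numpy scan (decisions
        and coordinates) on reads with up to 2% substitutions plus junk and
        repeat-derived reads."""
        block = random_dna(rng, 400)
        chrom = (
            random_dna(rng, 6_000) + block + random_dna(rng, 6_000)
            + block + random_dna(rng, 2_000)
        )
        refs = [SeqRecord("chr1", chrom)]
        idx = build_index(refs, POLICY)
        entries = idx.entries
        n_checked = 0
        for i in range(1_500):
            L = rng.randint(40, 140)
            kind = rng.random()
            if kind < 0.75:  # genomic read, <=2% substitutions
                start = rng.randrange(len(chrom) - L)
                seq = chrom[start : start + L]
                n_err = rng.randint(0, max(0, int(0.02 * L)))
                seq = list(seq)
                for p in rng.sample(range(L), n_err):
                    seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
                seq = "".join(seq)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
            elif kind < 0.9:  # junk
                seq = random_dna(rng, L)
            else:  # straight from the repeat
                off = rng.randrange(len(block) - L) if L < len(block) else 0
                seq = block[off : off + min(L, len(block))]
            got = map_read(SeqRecord("q", seq), idx, POLICY)
            want = exhaustive_map(seq, entries, POLICY.max_mismatches(len(seq)))
            if want is None:
                assert got is None, seq
            else:
                assert got is not None, seq
                assert (got.ref_id, got.pos, got.mismatches) == want, seq
            n_checked += 1
        assert n_checked == 1_500

    def test_error_free_junction_reads_recover_truth(self, small_genome):
        truth = sample_truth(small_genome, 40, sigma=0.0, seed=31)
        cfg = SimConfig(
            n_insertions=40, genome_len=10_000, n_read_pairs=400,
            junction_fraction=1.0, base_error_rate=0.0, seed=31,
        )
        kept, _ = filter_pairs(generate_pairs(cfg, small_genome, truth))
        idx = build_index(small_genome, POLICY)
        expected = truth_to_oriented(truth, small_genome)
        n = 0
        for rec in map_reads((p.read1 for p in kept), idx, POLICY):
            assert (rec.ref_id, rec.pos) in expected
            n += 1
        assert n == 400


class TestBwaCrossCheck:
    def test_flag0_coordinates_match_bwa(self, tmp_path, small_genome):
        """bwa-mem on the dual-orientation reference: every FLAG-0 primary
        placement equals the built-in mapper's placement for that read."""
        bwa = shutil.which("bwa")
        assert bwa is not None, "bwa expected on PATH"
        truth = sample_truth(small_genome, 30, sigma=0.0, seed=32)
        cfg = SimConfig(
            n_insertions=30, genome_len=10_000, n_read_pairs=200,
            junction_fraction=1.0, base_error_rate=0.0, seed=32,
        )
        kept, _ = filter_pairs(generate_pairs(cfg, small_genome, truth))
        reads = [p.read1 for p in kept]
        idx = build_index(small_genome)
        # bwa trims trailing /1 from read names; key by the pair id
        ours = {seqio.pair_key(r.id): map_read(r, idx) for r in reads}

        ref_fa = tmp_path / "dual.fasta"
        seqio.write_fasta(
            [SeqRecord(e, s) for e, s in idx.entries], ref_fa
        )
        fq = tmp_path / "reads.fastq"
        seqio.write_fastq(reads, fq)
        subprocess.run([bwa, "index", str(ref_fa)], check=True, capture_output=True)
        sam = tmp_path / "out.sam"
        with open(sam, "w") as fh:
            subprocess.run(
                [bwa, "mem", "-v", "1", str(ref_fa), str(fq)],
                check=True, stdout=fh, stderr=subprocess.DEVNULL,
            )
        n_flag0 = 0
        for rec in seqio.read_alignments(sam):
            if rec.flag_reverse:
                continue
            mine = ours[seqio.pair_key(rec.query_id)]
            assert mine is not None
            assert (mine.ref_id, mine.pos) == (rec.ref_id, rec.pos)
            n_flag0 += 1
        assert n_flag0 > 50  # bwa picks one of the two equivalent placements
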