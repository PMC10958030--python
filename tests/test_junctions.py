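import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tradiskit.junctions import (
    JunctionTable,
    classify_true,
    compare_conditions,
    putative_junctions,
    recovery_metrics,
    subsample_pairs,
    subsample_stream,
)
from tradiskit.seqio import AlignmentRecord, Orientation
from tradiskit.simlib import InsertionTruth, sample_truth


def _aln(ref, pos, qid="q", reverse=False):
    return AlignmentRecord(
        query_id=qid,
        ref_id=ref,
        orientation=Orientation.RC if ref.endswith("_rc") else Orientation.FWD,
        pos=pos,
        flag_reverse=reverse,
    )


class TestPutative:
    def test_grouping_and_totals(self):
        alns = [_aln("chr1", 100)] * 5 + [_aln("chr1_rc", 250)] * 3
        t = putative_junctions(iter(alns))
        assert len(t) == 2
        assert t.total_mapped_reads == 8
        assert dict(zip(zip(t.df.ref_entry, t.df.pos), t.df["count"])) == {
            ("chr1", 100): 5,
            ("chr1_rc", 250): 3,
        }

    def test_empty_stream(self):
        t = putative_junctions(iter([]))
        assert len(t) == 0 and t.total_mapped_reads == 0

    def test_single_pileup(self):
        t = putative_junctions(_aln("chr1", 7) for _ in range(1000))
        assert len(t) == 1
        assert t.df["count"].iloc[0] == 1000

    def test_reverse_flagged_records_dropped(self):
        alns = [_aln("chr1", 100)] * 2 + [_aln("chr1", 100, reverse=True)] * 3
        t = putative_junctions(iter(alns))
        assert t.total_mapped_reads == 2

    def test_conservation_and_permutation_invariance(self, rng):
        alns = [
            _aln(rng.choice(["chr1", "chr1_rc"]), rng.randint(1, 50)) for _ in range(500)
        ]
        t1 = putative_junctions(iter(alns))
        shuffled = alns[:]
        rng.shuffle(shuffled)
        t2 = putative_junctions(iter(shuffled))
        assert int(t1.df["count"].sum()) == t1.total_mapped_reads == 500
        assert classify_true(t1).uis_count == classify_true(t2).uis_count


class TestClassify:
    def _boundary_table(self):
        # total forced to 2,000,000: cpm(count=1)=0.5, cpm(count=2)=1.0
        return JunctionTable.from_counts(
            {("chr1", 10): 1, ("chr1", 20): 2, ("chr1", 30): 1_999_997},
            total_mapped_reads=2_000_000,
        )

    def test_cpm_boundary_strict_less_than(self):
        t = classify_true(self._boundary_table(), cpm_min=1.0)
        flags = dict(zip(t.df.pos, t.df.is_true))
        assert flags[10] is False  # 0.5 cpm removed
        assert flags[20] is True  # exactly 1.0 cpm kept
        assert t.uis_count == 2

    def test_zero_total_all_false(self):
        t = classify_true(JunctionTable.from_counts({}), cpm_min=1.0)
        assert t.uis_count == 0

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=30), st.floats(0.0, 2e6))
    def test_monotone_in_threshold(self, counts, cpm_min):
        table = JunctionTable.from_counts(
            {("chr1", i + 1): c for i, c in enumerate(counts)}
        )
        lo = classify_true(table, cpm_min=cpm_min)
        hi = classify_true(table, cpm_min=cpm_min * 2 + 1)
        assert hi.uis_count <= lo.uis_count

    def test_unclassified_table_refuses_uis(self):
        with pytest.raises(ValueError, match="classif"):
            JunctionTable.from_counts({("chr1", 1): 5}).uis_count


class TestSubsample:
    def test_exact_target_from_larger_input(self):
        out = list(subsample_stream(range(60_000), 50_000, seed=3))
        assert len(out) == 50_000
        assert out == sorted(out)  # order preserving
        assert len(set(out)) == 50_000  # without replacement

    def test_short_input_returned_whole_with_warning(self):
        with pytest.warns(UserWarning, match="only"):
            out = list(subsample_pairs(iter(range(1_000)), n_target=5_000_000, seed=0))
        assert out == list(range(1_000))

    def test_deterministic_for_seed(self):
        a = list(subsample_stream(range(10_000), 500, seed=9))
        b = list(subsample_stream(range(10_000), 500, seed=9))
        c = list(subsample_stream(range(10_000), 500, seed=10))
        assert a == b
        assert a != c

    def test_uniformity(self):
        # each item kept with probability 1/2; first-decile count is binomial
        hits = sum(
            1
            for s in range(200)
            for x in subsample_stream(range(100), 50, seed=s)
            if x < 10
        )
        assert 800 <= hits <= 1200  # mean 1000, sd ~21

    def test_downsampling_never_increases_uis(self, rng):
        sites = [("chr1", rng.randint(1, 30)) for _ in range(2_000)]
        full = classify_true(putative_junctions(_aln(r, p) for r, p in sites))
        sub_sites = list(subsample_stream(sites, 1_000, seed=4))
        sub = classify_true(putative_junctions(_aln(r, p) for r, p in sub_sites))
        assert sub.uis_count <= full.uis_count


class TestCompare:
    def _table(self, uis, count_per=10):
        return classify_true(
            JunctionTable.from_counts({("chr1", i + 1): count_per for i in range(uis)})
        )

    def test_relative_percent_table_format(self):
        report = compare_conditions(
            {
                "agar": [self._table(10_000)],
                "liquid": [self._table(8_500)],
            },
            reference="agar",
        )
        by_name = {c.condition: c for c in report.conditions}
        assert by_name["agar"].relative_pct == 100.0
        assert by_name["liquid"].relative_pct == pytest.approx(85.0)

    def test_reference_vs_itself(self):
        report = compare_conditions({"a": [self._table(500)]}, reference="a")
        assert report.conditions[0].relative_pct == 100.0

    def test_two_replicates_half_range(self):
        report = compare_conditions(
            {
                "agar": [self._table(10_000), self._table(10_000)],
                "liquid": [self._table(8_400), self._table(8_600)],
            },
            reference="agar",
        )
        liquid = {c.condition: c for c in report.conditions}["liquid"]
        assert liquid.relative_pct == pytest.approx(85.0)
        assert liquid.variance_pct == pytest.approx(1.0)

    def test_cfu_ratio(self):
        report = compare_conditions(
            {"a": [self._table(900)]}, reference="a", cfu={"a": 3_000}
        )
        assert report.cfu_to_uis_ratio["a"] == pytest.approx(0.3)

    def test_zero_reference_errors(self):
        empty = classify_true(JunctionTable.from_counts({}))
        with pytest.raises(ValueError, match="zero"):
            compare_conditions({"a": [empty]}, reference="a")

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            compare_conditions({"a": [self._table(10)]}, reference="b")


class TestRecovery:
    def _setup(self, small_genome):
        truth = sample_truth(small_genome, 20, sigma=0.0, seed=40)
        from tradiskit.simlib import truth_to_oriented

        coords = sorted(truth_to_oriented(truth, small_genome))
        table = classify_true(
            JunctionTable.from_counts({c: 100 for c in coords})
        )
        return truth, coords, table

    def test_perfect_recovery(self, small_genome):
        truth, _, table = self._setup(small_genome)
        m = recovery_metrics(table, truth, small_genome)
        assert m["precision"] == 1.0 and m["recall"] == 1.0
        assert m["detected_abundance_floor"] == pytest.approx(1 / 20)

    def test_empty_table_convention(self, small_genome):
        truth, _, _ = self._setup(small_genome)
        empty = classify_true(JunctionTable.from_counts({}))
        m = recovery_metrics(empty, truth, small_genome)
        assert m["precision"] == 1.0
        assert m["recall"] == 0.0

    def test_tolerance_monotone(self, small_genome):
        truth, coords, _ = self._setup(small_genome)
        shifted = classify_true(
            JunctionTable.from_counts({(r, p + 2): 100 for r, p in coords})
        )
        r0 = recovery_metrics(shifted, truth, small_genome, tolerance_bp=0)["recall"]
        r2 = recovery_metrics(shifted, truth, small_genome, tolerance_bp=2)["recall"]
        assert r0 <= r2
        assert r2 == 1.0

    def test_min_abundance_restricts_denominator(self, small_genome):
        truth = sample_truth(small_genome, 50, sigma=1.0, seed=41)
        empty = classify_true(JunctionTable.from_counts({}))
        m = recovery_metrics(
            empty, truth, small_genome, min_abundance=truth.df["abundance"].median()
        )
        assert m["n_truth_eligible"] < m["n_truth"]
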