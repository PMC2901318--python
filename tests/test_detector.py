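"""Detector unit and property tests: primitivity, runs, overlaps, flanks."""

import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tandemscan import (
    DetectionParams,
    RepeatRecord,
    SequenceRecord,
    brute_force_oracle,
    extract_flanks,
    find_runs_for_period,
    find_tandem_repeats,
    is_primitive,
    resolve_overlaps,
    smallest_period,
    window_comparison_count,
)
from conftest import random_dna


@pytest.mark.parametrize(
    "unit, primitive",
    [
        ("ACTAACTAACTA", False),  # (ACTA)_3 fills the 12-mer window
        ("CAG", True),
        ("ACCCTCCAGAGCTGCCAG", True),
        ("AAAA", False),
        ("AA", False),
        ("A", True),
        ("ATATAT", False),
        ("ATATATA", True),  # length 7 is prime and letters differ
    ],
)
def test_primitivity(unit, primitive):
    assert is_primitive(unit) is primitive


def test_smallest_period_gives_subrepeat_copy_count():
    # the invalid 12-mer window contains a period-4 sub-repeat in 3 copies
    unit = "ACTAACTAACTA"
    assert smallest_period(unit) == 4
    assert len(unit) // smallest_period(unit) == 3


def test_empty_unit_is_an_error():
    with pytest.raises(ValueError):
        is_primitive("")
    with pytest.raises(ValueError):
        smallest_period("")


class TestFindRunsForPeriod:
    def test_trinucleotide_run(self):
        rec = SequenceRecord("c", "CAG" * 10)
        assert find_runs_for_period(rec, 3, 10) == [(1, 10)]

    def test_homopolymer_yields_no_period3_run(self):
        rec = SequenceRecord("c", "A" * 50)
        assert find_runs_for_period(rec, 3, 10) == []

    def test_random_sequence_without_adjacent_equality(self):
        rec = SequenceRecord("c", random_dna(np.random.default_rng(7), 60))
        assert find_runs_for_period(rec, 4, 2) == find_runs_for_period(rec, 4, 2)
        assert find_runs_for_period(rec, 4, 10) == []

    def test_period_longer_than_half_sequence(self):
        rec = SequenceRecord("c", "ACGTACGT")
        assert find_runs_for_period(rec, 5, 2) == []

    def test_n_breaks_runs(self):
        rec = SequenceRecord("c", "CAG" * 5 + "N" + "CAG" * 5)
        assert find_runs_for_period(rec, 3, 10) == []
        assert find_runs_for_period(rec, 3, 5) == [(1, 5), (17, 5)]


def _rec(beg, period, copies, unit, contig="c"):
    return RepeatRecord(
        contig=contig,
        period=period,
        unit=unit,
        copy_number=copies,
        beg=beg,
        end=beg + period * copies - 1,
        repeat_seq=unit * copies,
    )


class TestResolveOverlaps:
    def test_largest_copy_number_wins(self):
        a = _rec(1, 4, 12, "ACGT")
        b = _rec(3, 4, 11, "GTAC")
        assert resolve_overlaps([a, b]) == [a]

    def test_disjoint_records_are_retained(self):
        a = _rec(1, 4, 10, "ACGT")
        b = _rec(100, 4, 10, "GTAC")
        assert resolve_overlaps([a, b]) == [a, b]

    def test_tie_broken_by_smaller_beg(self):
        a = _rec(1, 4, 10, "ACGT")
        b = _rec(3, 4, 10, "GTAC")
        assert resolve_overlaps([b, a]) == [a]

    def test_cross_period_overlaps_kept_by_default(self):
        a = _rec(1, 4, 12, "ACGT")
        b = _rec(2, 5, 10, "CGTAC")
        assert resolve_overlaps([a, b]) == sorted([a, b], key=lambda r: r.beg)

    def test_cross_period_resolution_prefers_more_copies(self):
        a = _rec(1, 4, 12, "ACGT")
        b = _rec(2, 5, 10, "CGTAC")
        params = DetectionParams(cross_period_overlaps="resolve")
        assert resolve_overlaps([a, b], params) == [a]

    def test_idempotent_and_order_insensitive(self):
        records = [
            _rec(1, 4, 12, "ACGT"),
            _rec(3, 4, 11, "GTAC"),
            _rec(60, 4, 10, "TTAC"),
            _rec(62, 4, 10, "ACTT"),
            _rec(200, 3, 15, "CAG"),
        ]
        resolved = resolve_overlaps(records)
        assert resolve_overlaps(resolved) == resolved
        shuffled = records[:]
        random.Random(5).shuffle(shuffled)
        assert resolve_overlaps(shuffled) == resolved

    def test_mixed_contigs_rejected(self):
        with pytest.raises(ValueError, match="contig"):
            resolve_overlaps([_rec(1, 3, 10, "CAG", "a"), _rec(1, 3, 10, "CAG", "b")])


class TestExtractFlanks:
    def test_full_flanks_available(self, rng):
        seq = random_dna(rng, 2000)
        rec = SequenceRecord("c", seq)
        rpt = _rec(601, 3, 20, seq[600:603])
        f5, f3 = extract_flanks(rec, rpt, 500)
        assert f5 == seq[100:600] and len(f5) == 500
        assert f3 == seq[660:1160] and len(f3) == 500

    def test_flank_truncated_at_contig_start(self, rng):
        seq = random_dna(rng, 300)
        rpt = _rec(1, 3, 10, seq[0:3])
        f5, f3 = extract_flanks(SequenceRecord("c", seq), rpt, 500)
        assert f5 == ""
        assert f3 == seq[30:300]

    def test_flank_truncated_at_contig_end(self, rng):
        seq = random_dna(rng, 1000)
        rpt = _rec(871, 3, 10, seq[870:873])  # ends 100 bp before contig end
        _, f3 = extract_flanks(SequenceRecord("c", seq), rpt, 500)
        assert len(f3) == 100

    def test_out_of_bounds_coordinates_rejected(self):
        rec = SequenceRecord("c", "ACGT" * 10)
        with pytest.raises(ValueError):
            extract_flanks(rec, _rec(30, 4, 10, "ACGT"), 5)


class TestFindTandemRepeats:
    def test_trinucleotide_worked_example(self):
        out = find_tandem_repeats(SequenceRecord("c", "CAG" * 10))
        assert len(out) == 1
        r = out[0]
        assert (r.period, r.unit, r.copy_number, r.beg, r.end) == (3, "CAG", 10, 1, 30)

    def test_pentamer_worked_example(self):
        out = find_tandem_repeats(SequenceRecord("c", "AAGCT" * 10))
        assert len(out) == 1
        assert (out[0].period, out[0].copy_number) == (5, 10)

    def test_case_folding_policy(self):
        lower = SequenceRecord("c", "cag" * 10)
        assert len(find_tandem_repeats(lower)) == 1
        respect = DetectionParams(case_policy="respect")
        assert find_tandem_repeats(lower, respect) == []

    def test_empty_sequence(self):
        assert find_tandem_repeats(SequenceRecord("c", "")) == []

    def test_trailing_partial_copy_not_counted(self):
        out = find_tandem_repeats(SequenceRecord("c", "ACGTT" * 10 + "ACG"))
        assert len(out) == 1
        assert (out[0].copy_number, out[0].end) == (10, 50)

    def test_records_satisfy_invariants(self, rng, loose_params):
        for _ in range(25):
            seq = random_dna(rng, 400, alphabet="ACGTN")
            # salt with a few genuine runs
            pos = int(rng.integers(0, 300))
            seq = seq[:pos] + "TGA" * 6 + seq[pos:]
            rec = SequenceRecord("c", seq)
            for r in find_tandem_repeats(rec, loose_params):
                assert rec.seq[r.beg - 1 : r.end] == r.unit * r.copy_number
                assert r.repeat_seq == r.unit * r.copy_number
                assert is_primitive(r.unit)
                # maximality: bordering windows differ or fall off the contig
                before = rec.seq[max(0, r.beg - 1 - r.period) : r.beg - 1]
                after = rec.seq[r.end : r.end + r.period]
                assert before != r.unit
                assert after != r.unit


class TestOracleEquivalence:
    def test_matches_on_worked_examples(self):
        for seq in ("CAG" * 10, "AAGCT" * 10, "A" * 60, "ACGT" * 30):
            rec = SequenceRecord("c", seq)
            assert find_tandem_repeats(rec) == brute_force_oracle(rec)

    def test_matches_on_salted_random_sequences(self, rng, loose_params):
        for _ in range(30):
            seq = random_dna(rng, 250, alphabet="ACGTN")
            pos = int(rng.integers(0, 200))
            seq = seq[:pos] + "AT" * 8 + seq[pos:]
            rec = SequenceRecord("c", seq)
            assert find_tandem_repeats(rec, loose_params) == brute_force_oracle(
                rec, loose_params
            )

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=120))
    def test_matches_on_arbitrary_sequences(self, seq):
        params = DetectionParams(min_period=1, max_period=6, min_copies=3, flank_len=4)
        rec = SequenceRecord("c", seq)
        assert find_tandem_repeats(rec, params) == brute_force_oracle(rec, params)


def test_comparison_count_grows_linearly():
    """One scan pass per period does work proportional to sequence length."""
    rng = np.random.default_rng(0)
    sizes = [10_000, 100_000, 1_000_000]
    counts = []
    for n in sizes:
        rec = SequenceRecord("c", random_dna(rng, n))
        counts.append(window_comparison_count(rec, 5))
    # fit count = a*n + b through the first two sizes; the third must obey it
    a = (counts[1] - counts[0]) / (sizes[1] - sizes[0])
    b = counts[0] - a * sizes[0]
    assert counts[2] <= a * sizes[2] + b + 1e-6
    assert all(c <= n for c, n in zip(counts, sizes))
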