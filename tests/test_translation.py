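"""Cyclic translation, rotation canonicalisation and consensus matching."""

import pytest
from Bio.Seq import Seq

from tandemscan import (
    ConsensusPattern,
    CyclicPeptide,
    canonical_rotation,
    match_consensus,
    six_frame_cyclic_translate,
    tally_consensus,
    unit_matches_consensus,
)
from tandemscan import zv8


def canon_set(peptides):
    return {canonical_rotation(p) for p in peptides}


class TestCanonicalRotation:
    @pytest.mark.parametrize(
        "a, b",
        [("TLQSCQ", "LQSCQT"), ("AAAA", "AAAA"), ("BA", "AB")],
    )
    def test_rotation_equivalence(self, a, b):
        assert canonical_rotation(a) == canonical_rotation(b)

    def test_minimal_among_rotations(self):
        pep = CyclicPeptide("QLTRWPTPVL")
        assert pep.canonical_form in pep.rotations()
        assert all(pep.canonical_form <= r for r in pep.rotations())

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            canonical_rotation("")


class TestSixFrameCyclicTranslate:
    def test_proline_rich_18mer(self):
        peps = six_frame_cyclic_translate("ACCCTCCAGAGCTGCCAG")
        expected = ["PPELPD", "VWQLWR", "PSRAAR", "LQSCQT", "GLAALE", "GSSGGS"]
        assert canon_set(p.residues for p in peps) == canon_set(expected)

    def test_30mer_translates_to_conserved_decapeptide(self):
        peps = six_frame_cyclic_translate("AGCCCCTGAGCGCCCTCCAGTGTCGGCTCC")
        assert canonical_rotation("APAPERPPVS") in canon_set(p.residues for p in peps)

    def test_hand_translated_hexamer(self):
        peps = six_frame_cyclic_translate("AAAGGG")
        forward = [p.residues for p in peps[:3]]
        reverse = [p.residues for p in peps[3:]]
        assert canon_set(forward) == canon_set(["KG", "KG", "RE"])
        assert canon_set(reverse) == canon_set(["PF", "PF", "LS"])

    def test_each_peptide_has_length_period_over_three(self):
        for unit in ("CAGCAG", "ACCCTCCAGAGCTGCCAG"):
            peps = six_frame_cyclic_translate(unit)
            assert len(peps) == 6
            assert all(len(p) == len(unit) // 3 for p in peps)

    @pytest.mark.parametrize("bad", ["ACGT", "AC", "ACGNCA"])
    def test_invalid_units_rejected(self, bad):
        with pytest.raises(ValueError):
            six_frame_cyclic_translate(bad)

    def test_rotating_unit_by_codons_preserves_peptide_classes(self):
        unit = "ACCCTCCAGAGCTGCCAG"
        base = canon_set(p.residues for p in six_frame_cyclic_translate(unit))
        for shift in (3, 6, 9):
            rotated = unit[shift:] + unit[:shift]
            assert canon_set(
                p.residues for p in six_frame_cyclic_translate(rotated)
            ) == base

    def test_reverse_complement_swaps_strand_triples(self):
        unit = "ACCCTCCAGAGCTGCCAG"
        rc = str(Seq(unit).reverse_complement())
        fwd = six_frame_cyclic_translate(unit)
        rev = six_frame_cyclic_translate(rc)
        assert canon_set(p.residues for p in fwd[:3]) == canon_set(
            p.residues for p in rev[3:]
        )
        assert canon_set(p.residues for p in fwd[3:]) == canon_set(
            p.residues for p in rev[:3]
        )


class TestConsensusMatching:
    @pytest.mark.parametrize(
        "peptide, pattern, expected",
        [
            ("PPELPD", "PP[E|V]LPD", True),
            ("PPVLPD", "PP[E|V]LPD", True),
            ("GSSGGS", "PP[E|V]LPD", False),
            ("ELPDPP", "PP[E|V]LPD", True),  # a rotation must match too
            ("PGPRQLHA", "PGP.QLHA", True),
            ("VMISCVVAR", "V[L|M][IVNSK]S[C|G]VVAR", True),
            ("PPELPDX", "PP[E|V]LPD", False),  # length mismatch is not a match
        ],
    )
    def test_match(self, peptide, pattern, expected):
        assert match_consensus(peptide, ConsensusPattern(pattern)) is expected

    def test_malformed_patterns_rejected(self):
        with pytest.raises(ValueError):
            ConsensusPattern("PP[]LPD").positions
        with pytest.raises(ValueError):
            ConsensusPattern("").positions

    def test_tally_empty_rows(self):
        assert tally_consensus([], ConsensusPattern("PP[E|V]LPD")) == 0

    def test_tally_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            tally_consensus([("ACCCTCCAGAGCTGCCAG", 0)], ConsensusPattern("PP[E|V]LPD"))


class TestCuratedFamilyTables:
    """The curated Zv8 family tables agree with the genetic code."""

    @pytest.mark.parametrize("length", sorted(zv8.FAMILY_TABLES))
    def test_catalogued_translations_match_computed(self, length):
        for row in zv8.family_rows(length):
            corrected = [
                zv8.TRANSLATION_ERRATA.get((row.unit, p), p) for p in row.translations
            ]
            computed = canon_set(
                p.residues for p in six_frame_cyclic_translate(row.unit)
            )
            assert canon_set(corrected) == computed, row.unit

    def test_table_row_and_locus_totals(self):
        totals = {
            L: (len(rows), sum(r.count for r in rows))
            for L, rows in zv8.FAMILY_TABLES.items()
        }
        assert totals == {18: (9, 21), 24: (10, 18), 27: (30, 40), 30: (14, 117)}
        assert len(zv8.LONGEST_REPEAT_UNIT) == 54
        assert zv8.LONGEST_REPEAT_COPIES == 14

    def test_27mer_consensus_groups_cover_all_but_six(self):
        rows = zv8.unit_counts(27)
        tallies = [
            tally_consensus(rows, ConsensusPattern(p))
            for p in zv8.CONSENSUS_BY_LENGTH[27]
        ]
        assert tallies == [15, 5, 14]
        assert sum(tallies) == sum(c for _, c in rows) - 6

    def test_units_match_their_groups_consensus(self):
        # every group-1 18-mer family member carries the proline-rich hexapeptide
        pattern = ConsensusPattern("PP[E|V]LPD")
        for row in zv8.family_rows(18):
            assert unit_matches_consensus(row.unit, pattern) == (row.group == 1)
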