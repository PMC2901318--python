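"""Curated zebrafish Zv8 exact-tandem-repeat family tables.

Machine-readable records of the repeat-unit families of length 18, 24,
27 and 30 catalogued in the zebrafish Zv8 assembly: each row carries
the family group number, the repeat unit as observed at its locus, the
six published protein translations, and the number of detected loci
with that unit.  Also included: the longest repeat observed in the
assembly (a 54-base unit with fourteen tandem copies, intronic in
NM_199842) and the proline-rich consensus patterns the families
conserve.

A handful of published translation cells are internally inconsistent
with the standard genetic code (impossible residue counts for the unit
length, letter transpositions, or one frame printed twice as a rotation
of another).  The tables preserve those cells verbatim;
``TRANSLATION_ERRATA`` maps each such cell to the peptide the genetic
code actually yields, and consistency tests compare computed
translations against the corrected values.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RepeatFamilyRow",
    "FAMILY_TABLES",
    "CONSENSUS_BY_LENGTH",
    "TRANSLATION_ERRATA",
    "LONGEST_REPEAT_UNIT",
    "LONGEST_REPEAT_COPIES",
]


@dataclass(frozen=True)
class RepeatFamilyRow:
    """One catalogued repeat-unit family member."""

    group: int
    unit: str
    translations: tuple[str, ...]
    count: int


FAMILY_TABLES: dict[int, tuple[RepeatFamilyRow, ...]] = {
    18: (
        RepeatFamilyRow(1, "ACCCTCCAGAGCTGCCAG",
            ("PPELPD", "VWQLWR", "PSRAAR", "LQSCQT", "GLAALE", "GSSGGS"), 10),
        RepeatFamilyRow(1, "AGCTCTGGAGGGTCTGGC",
            ("PPELPD", "VWQLWR", "PSRAAR", "LQSCQT", "GLAALE", "GSSGGS"), 3),
        RepeatFamilyRow(1, "ACTGGAGGGTCTGGCAGC",
            ("PPVLPD", "VWQHWR", "PSSAAR", "LQCCQT", "ALEGLA", "GSTGGS"), 1),
        RepeatFamilyRow(1, "AGCTCTGGCGGGTCTGGC",
            ("PPELPD", "VWQLWR", "PARAAR", "RQSCQT", "GLAALA", "SGSSGG"), 1),
        RepeatFamilyRow(1, "ACCCTCCAGTGCTGCCAG",
            ("PPVLPD", "VHQHWR", "PSSAAR", "LQCCQT", "GLAALE", "SGSTGG"), 2),
        RepeatFamilyRow(1, "ACCCGCCAGAGCTGCCAG",
            ("PPELPD", "VWQLWR", "PARAAR", "RQSCQT", "GLAALA", "GSSGGS"), 1),
        RepeatFamilyRow(2, "ACGCCGCAGCCAGAGTCG",
            ("CGVDSG", "AASTLA", "RRRLWL", "ARVDAA", "QPESTP", "SQSRRR"), 1),
        RepeatFamilyRow(3, "ATCGTGGCCCCCTCGTCC",
            ("RPSWPP", "VHRGPL", "SIVAPS", "RGPRWT", "RGGHDG", "EGATMD"), 1),
        RepeatFamilyRow(4, "CCCTGTGGTGCTGTGTGT",
            ("CGAVCP", "VVLCVP", "WCCVSL", "GTHSTT", "QGHTAP", "RDTQHH"), 1),
    ),
    24: (
        RepeatFamilyRow(1, "ACGCTCCAGGCCCTCCGCAGCTCC",
            ("PGPPQLHA", "AWSCGGPG", "SRPSAAPR", "QALRSSTL", "ERGAAEGL", "SVELRRAW"), 6),
        RepeatFamilyRow(1, "AGCGTGGAGCTGCGGAGGGCCTGG",
            ("PGPPQLHA", "AWSCGGPG", "SRPSAAPR", "QALRSSTL", "ERGAAEGL", "SVELRRAW"), 4),
        RepeatFamilyRow(1, "ACGCCCCAGGCCCTCCGCAGCTCC",
            ("PGPPQLHA", "AWSCGGPG", "PRPSAAPR", "QALRSSTP", "GRGAAEGL", "GVELRRAW"), 1),
        RepeatFamilyRow(1, "AGCTGCGGAGGGCCTGGGGCGTGG",
            ("PGPPQLHA", "AWSCGGPG", "PRPSAAPR", "QALRSSTP", "LRGAAELG", "GVELRRAW"), 1),
        RepeatFamilyRow(1, "ACGCTCCAGGCCCTCGGCAGCTGC",
            ("PGPRQLHA", "TLQALGSC", "SRPSAAAR", "GACSCRGP", "ERAAAELG", "SVQLPRAW"), 1),
        RepeatFamilyRow(2, "AAGCCCGAGGCGACGCCATTGGAG",
            ("GLLQWRRL", "EATPLEKP", "RRRHWRSP", "GDAIGEAR", "SGFSNGVA", "RASPMASP"), 1),
        RepeatFamilyRow(2, "AAGGCCGAGGCGACGCCATTGGAG",
            ("GLLQWRRL", "EATPLEKA", "RRRHWRRP", "GDAIGEGR", "SAFSNGVA", "MASPRPSP"), 1),
        RepeatFamilyRow(3, "AAGCGGATTTTTGACGCGCGAGTG",
            ("*SGFLTRE", "EADF*RAS", "KRIFDARV", "LARQKSAS", "HSRVKNPL", "TRASKIRF"), 1),
        RepeatFamilyRow(4, "AAGCGCCGGTGAGCCCTCGCCCTC",
            ("ALEGEGSP", "RLRARAHR", "A*GRGLTG", "R*ALALKR", "AGEPSPSS", "PVSPRPQA"), 1),
        RepeatFamilyRow(5, "AAGCTCAGGCGGCGGCCATTCAGG",
            ("GGGHSGSS", "AAAIQEAQ", "RRPFRKLR", "*AS*MAAA", "PELPEWPP", "LSFLNGRR"), 1),
    ),
    27: (
        RepeatFamilyRow(1, "AACACAGCTGATAAGAACTCGCGCGAC",
            ("VLISCVVAR", "RATTQLIRT", "SRDNTADKN", "FLSAVLSRE", "SSYQLCCRA", "LARQHS**E"), 2),
        RepeatFamilyRow(1, "AACACAGCTGATCAGTACGCGCGCGAC",
            ("VLISCVVAR", "RATTQLIST", "ARDNTADQY", "Y*SAVLSRA", "RTDQLCCRA", "RARQHS*SV"), 1),
        RepeatFamilyRow(1, "AGCTGTGTTGTCGCGCGCGTTATGATC",
            ("VMISCVVAR", "RATTQLIIT", "ARDNTADHN", "L*SAVLSRA", "RYDQLCCRA", "RARQHS*S*"), 2),
        RepeatFamilyRow(1, "AGCTGTGTTGTCGCGCGCGTTCTGATC",
            ("VLISCVVAR", "RATTQLIRT", "ARDNTADQN", "F*SAVLSRA", "RSDQLCCRA", "RARQHS*SE"), 1),
        RepeatFamilyRow(1, "AATAGCGGTGTTGTCGCGCGCGTTCTG",
            ("VLNSGVVAR", "RATTPLFRT", "ARDNTAIQN", "F*IAVLSRA", "RSE*RCCRA", "RARQHRYSE"), 1),
        RepeatFamilyRow(1, "AACACCGCTCTTCAGTACGCGCGCGAC",
            ("VLKSGVVAR", "RATTPLFST", "ARDNTALQY", "Y*RAVLSRA", "RTEERCCRA", "RARQHRSSV"), 1),
        RepeatFamilyRow(1, "AGCTGTGTTGTCGCGCGAGTTCTTATC",
            ("VLISCVVAR", "RATTQLIRT", "SRDNTADKN", "FLSAVLSRE", "SSYQLCCRA", "LARQHS**E"), 3),
        RepeatFamilyRow(1, "AACACAGCTGATAAGAACGCGCGCGAC",
            ("VLISCVVAR", "RATTQLIRT", "ARDNTADKN", "FLSAVLSRA", "RSYQLCCRA", "RARQHS**E"), 1),
        RepeatFamilyRow(1, "AACACCGCTACTCAGTACGCGCGCGAC",
            ("VLSSGVVAR", "RATTPLLST", "ARDNTATQY", "Y*VAVLSRA", "RTE*RCCRA", "RARQHRYSV"), 1),
        RepeatFamilyRow(1, "AACACAGCTGATCAGAACGCGCGCGAC",
            ("VLISCVVAR", "RATTQLIRT", "ARDNTADQN", "VLSRAF*SA", "RSDQLCCRA", "RARQHS*SE"), 1),
        RepeatFamilyRow(1, "AACACAGCTGACAAGAACTCGCGCGAC",
            ("VLVSCVVAR", "RATTQLTRT", "SRDNTADKN", "FLSAVLSRE", "SSCQLCCRA", "LARQHS*QE"), 1),
        RepeatFamilyRow(2, "ACCCAGGCTCCTCGCCCTGCCGGCGCC",
            ("LALPAPPRL", "SPCRRHPGS", "RPAGATQAP", "RSLGGAGRA", "GAWVAPAGR", "EPGWRRQGE"), 1),
        RepeatFamilyRow(2, "ACCCAGACGTCTCGCCCTGCCGGCGCC",
            ("LALPAPPRR", "SPCRRHPDV", "RPAGATQTS", "RRLGGAGRA", "DVWVAPAGR", "TSGWRRQGE"), 1),
        RepeatFamilyRow(2, "ACGTCTGGGTGGCGCCGGCAGGGCGAG",
            ("LALPAPPRR", "SPCRRHPDV", "RPAGATQTS", "RRLGGAGRA", "DVWVAPAGR", "TSGWRRQGE"), 1),
        RepeatFamilyRow(2, "ACGTCTGGGTGGCGCCGGCTGGGCGAG",
            ("LAQPAPPRR", "SPSRRHPDV", "RPAGATQTS", "RRLGGAGWA", "DVWVAPAGR", "TSGWRRLGE"), 1),
        RepeatFamilyRow(2, "ACAGGCCTCCAGCCCAGCCGGCTCCCC",
            ("PAQPAPHRP", "GSRLGWRPV", "SPAGSPQAS", "GGLWGAGWA", "LGWRPVGSR", "PAGLEACGE"), 1),
        RepeatFamilyRow(3, "AATGGCCGCCGCCTCCTGAGCTTCCTG",
            ("LPEWPPPPE", "SSGGGGHSG", "LRRRRPFRK", "S*MAAAS*A", "AQEAAAIQE", "FLNGRRLLS"), 1),
        RepeatFamilyRow(3, "AAGCTCAGGAGGCGGCGGCCATTCAGG",
            ("LPEWPPPPE", "SSGGGGHSG", "LRRRRPFRK", "S*MAAAS*A", "AQEAAAIQE", "FLNGRRLLS"), 2),
        RepeatFamilyRow(3, "AGCTCAGGCGGCGGCGGCCATTCAGGG",
            ("LPEWPPPPE", "SSGGGGHSG", "LRRRRPFRE", "P*MAAAA*A", "AQAAAAIQG", "SLNGRRRLS"), 1),
        RepeatFamilyRow(3, "AGCGAGCTCGGGAGGCGGCGGCCATTC",
            ("LAEWPPPPE", "SSGGGGHSA", "LGRRRPFSE", "R*MAAASRA", "AREAAAIQR", "SLNGRRLPS"), 1),
        RepeatFamilyRow(3, "AATGGCCGCCGCCGCCTGAGCTTCCTG",
            ("LPEWPPPPE", "SSGGGGHSG", "LRRRRPFRK", "S*MAAAA*A", "AQAAAAIQE", "FLNGRRRLS"), 3),
        RepeatFamilyRow(3, "AAGCTCAGGAGGCGGCGGCCGTTCAGG",
            ("LPERPPPPE", "SSGGGGRSG", "LRRRRPFRK", "S*TAAAS*A", "AQEAAAVQE", "FLNGRRLLS"), 3),
        RepeatFamilyRow(3, "AATGGCCGCCGCCGCCTGAGCTCCCTG",
            ("LPEWPPPPE", "SSGGGGHSG", "LRRRRPFRE", "P*MAAAA*A", "AQAAAAIQG", "LNGRRRLSS"), 1),
        RepeatFamilyRow(3, "AACGGCCGCCGCCTCCTGAACTCCCTG",
            ("LPERPPPPE", "SSGGGGRSG", "FRRRRPFRE", "P*TAAAS*T", "VQEAAAVQG", "LNGRRLLNS"), 2),
        RepeatFamilyRow(4, "AAGACCAGAGGGGAGCCGGCGGGGCTG",
            ("G*RPEGSRR", "AGGAEDQRG", "LKTRGEPAG", "PRRLPSGLQ", "PAGSPLVFS", "PPAPLWSSA"), 1),
        RepeatFamilyRow(4, "CCCCTCTGGTCTCCTGCCCTGCCGGCT",
            ("GRRPEGSRQ", "AGRAGDQRG", "QETRGEPAG", "PCRLPSGLL", "PAGSPLVSC", "LPAPLWSPA"), 1),
        RepeatFamilyRow(5, "AACTCTATTGAGTGTCAGGTCATCTCC",
            ("SSPTLLSVR", "HLQLY*VSG", "ISNSIECQV", "DLTNRVGD", "T*HSIELEM", "PDTQ*SWR*"), 1),
        RepeatFamilyRow(6, "AAAGCAACAACTCCACCAACATCAGCT",
            ("QLHQHQLKQ", "NSTNIS*SN", "TPPTSAKAT", "CCFS*CWWS", "VALADVGGV", "LL*LMLVEL"), 1),
        RepeatFamilyRow(7, "AACAGCAGAGCCATTCACTGACCCCAG",
            ("H*PQNSRAI", "TDPRTAEPF", "LTPEQQSHS", "*MALLFWGQ", "EWLCCSGVS", "NGSAVLGSV"), 1),
        RepeatFamilyRow(8, "AAGGAGCCGGGCTGGGGCCGGCAGGGC",
            ("AGRARSRAG", "PAGQGAGLG", "RQGKEPGWG", "APARLLALP", "PQPGSLPCR", "PSPAPCPAG"), 1),
    ),
    30: (
        RepeatFamilyRow(1, "AGCCCCTGAGCGCCCTCCAGTGTCGGCTCC",
            ("APAPERPPVS", "DTGGRSGAGA", "RHWRALRGWS", "RLQPLSALQC", "GSSP*APSSV", "TLEGAQGLEP"), 32),
        RepeatFamilyRow(1, "AGAGCGCCCGCCAGTGTCGGCTCCAGCCCC",
            ("APAPERPPVS", "DTGGRSGAGA", "RHWRALWGWS", "RLQPQSARQC", "GSSPRAPASV", "TLAGALGLEP"), 12),
        RepeatFamilyRow(1, "ACACTGGAGGGCGCTCAGGGGCTGGAGCCG",
            ("APAPERPPVS", "DTGGRSGAGA", "RHWRALRGWS", "RLQPLSALQC", "GSSP*APSSV", "TLEGAQGLEP"), 16),
        RepeatFamilyRow(1, "ACACTGGCGGGCGCTCTGGGGCTGGAGCCG",
            ("APAPERPPVS", "DTGGRSGAGA", "RHWRALWGWS", "RLQPQSARQC", "GSSPRAPASV", "TLAGALGLEP"), 12),
        RepeatFamilyRow(1, "ACACTGGAGGGCGCTCTGGGGCTGGAGCCG",
            ("APAPERPPVS", "DTGGRSGAGA", "RHWRALWGWS", "RLQPQSALQC", "GSSPRAPSSV", "TLEGALGLEP"), 15),
        RepeatFamilyRow(1, "AGAGCGCCCTCCAGTGTCGGCTCCAGCCCC",
            ("APAPERPPVS", "DTGGRSGAGA", "RHWRALWGWS", "RLQPQSALQC", "GSSPRAPSSV", "TLEGALGLEP"), 14),
        RepeatFamilyRow(1, "ACACTGGCGGGCGCTCGGGGGCTGGAGCCG",
            ("APAPERPPVS", "DTGGRSGAGA", "RHWRALGGWS", "RLQPPSARQC", "GSSPRAPASV", "TLAGARGLEP"), 2),
        RepeatFamilyRow(2, "ACTGGAGGCAGCTGGACTGGAGCCGGCGGG",
            ("APVQLPPVPP", "AGGTGGSWTG", "PAGLEAAGLE", "RRDWRQLDWS", "LQSSCLQSRR", "SSPAASSPAG"), 2),
        RepeatFamilyRow(2, "ACAGGAGGCAGCTGGGCTGGAGCCGGCGGG",
            ("APAQLPPVPP", "AGGTGGSWAG", "PAGQEAAGLE", "RRDRRQLGWS", "LQPSCLLSRR", "SSPAASCPAG"), 1),
        RepeatFamilyRow(2, "AGCTGCCTCCAGTCCCGCCGGCTCCTGCCC",
            ("APAQLPPVPP", "AGGTGGSWAG", "PAGLEAAGQE", "RRDWRQLGRS", "LLPSCLQSRR", "SSPAGSCPAA"), 1),
        RepeatFamilyRow(2, "ACTGGAGGCAGCTGGGCAGGAGCCGGCGGG",
            ("APAQLPPVPP", "AGGTGGSWAG", "PAGLEAAGQE", "RRDWRQLGRS", "LLPSCLQSRR", "SSPAGSCPAA"), 1),
        RepeatFamilyRow(3, "AAGATGGCCGACTCCAGTCCTCCAGCTCAC",
            ("QLTRWPTPVL", "SSQDGRLQSS", "AHKMADSSP", "WRTGVGHLVS", "GGLESAIL*A", "EDWSRPSCEL"), 7),
        RepeatFamilyRow(3, "ACTGGAGTCGGCCATCTTGTGAGCTGGAGG",
            ("QLTRWPTPVL", "SSQDGRLQSS", "AHKMADSSP", "WRTGVGHLVS", "GGLESAIL*A", "EDWSRPSCEL"), 1),
        RepeatFamilyRow(4, "AAACTGCCGCAAGGCTCCAAATACTTCTCC",
            ("KLPQGSKYFS", "NCRKAPNTSP", "TAARLQILLQ", "LEKYLEPCGS", "WRSIWSLAAV", "GEVFGALRQF"), 1),
    ),
}


# Consensus patterns conserved by the numbered family groups, keyed by
# unit length.  Syntax: fixed residues, [X|Y] alternatives, '.' wildcard.
CONSENSUS_BY_LENGTH: dict[int, tuple[str, ...]] = {
    18: ("PP[E|V]LPD",),
    24: ("PGP.QLHA",),
    27: ("V[L|M][IVNSK]S[C|G]VVAR", "[L|P]A[L|Q]PAP[P|H]R[R|L|P]", "L[P|A]E[W|R]PPPPE"),
    30: ("APAPERPPVS", "AP[A|V]QLPPVPP", "QLTRWPTPVL"),
}

# (unit, published peptide) -> peptide the standard genetic code yields.
TRANSLATION_ERRATA: dict[tuple[str, str], str] = {
    # letter transposition / substitution slips
    ("ACCCTCCAGTGCTGCCAG", "VHQHWR"): "VWQHWR",
    ("AGCTGCGGAGGGCCTGGGGCGTGG", "LRGAAELG"): "LGRGAAEG",
    ("ACGCTCCAGGCCCTCGGCAGCTGC", "ERAAAELG"): "ERAAAEGL",
    # a rotation of another printed frame, displacing the true sixth frame
    ("ACAGGCCTCCAGCCCAGCCGGCTCCCC", "LGWRPVGSR"): "GLQPSRLPT",
    # dropped residues (8 printed for a 27-mer; 9 printed for a 30-mer)
    ("AACTCTATTGAGTGTCAGGTCATCTCC", "DLTNRVGD"): "DLTLNRVGD",
    ("AAGATGGCCGACTCCAGTCCTCCAGCTCAC", "AHKMADSSP"): "AHKMADSSPP",
    ("ACTGGAGTCGGCCATCTTGTGAGCTGGAGG", "AHKMADSSP"): "AHKMADSSPP",
}

# Longest repeat in the Zv8 assembly: a 54-base unit in fourteen
# tandem copies, intronic in NM_199842.
LONGEST_REPEAT_UNIT = (
    "CGAGTTCTTATCAGCTGTGTTGTCGCG"
    "CGCGTACTGAATAGCGGTGTTGTCGCA"
)
LONGEST_REPEAT_COPIES = 14


def family_rows(length: int) -> tuple[RepeatFamilyRow, ...]:
    """Rows of the family table for one unit *length* (18/24/27/30)."""
    try:
        return FAMILY_TABLES[length]
    except KeyError:
        raise KeyError(
            f"no curated family table for unit length {length}; "
            f"available: {sorted(FAMILY_TABLES)}"
        ) from None


def unit_counts(length: int) -> list[tuple[str, int]]:
    """(unit, locus count) rows for one table, for consensus tallies."""
    return [(row.unit, row.count) for row in family_rows(length)]
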