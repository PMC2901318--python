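"""Cyclic six-frame translation of tandem repeat units.

A repeat unit whose period is a multiple of three can sit in a coding
region without disturbing the reading frame, so an infinite tandem run
of it encodes a repeating peptide.  Because the run is effectively
circular, it has exactly six possible peptide products — the three
forward frames and the three frames of the reverse complement — and
each is only defined up to rotation (the reading frame may enter the
run at any phase).  Peptides are therefore compared via a canonical
rotation, and matched against consensus patterns with positional
alternatives written ``PP[E|V]LPD`` ('.' is a wildcard).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "CyclicPeptide",
    "ConsensusPattern",
    "TranslationReport",
    "canonical_rotation",
    "six_frame_cyclic_translate",
    "match_consensus",
    "tally_consensus",
]

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


def canonical_rotation(peptide: str) -> str:
    """Lexicographically smallest rotation of *peptide*.

    Two peptides are rotation-equivalent iff their canonical rotations
    are equal; published tables print repeat translations at arbitrary
    phases, so all comparisons go through this form.
    """
    if not peptide:
        raise ValueError("cannot canonicalise an empty peptide")
    return min(peptide[i:] + peptide[:i] for i in range(len(peptide)))


@dataclass(frozen=True)
class CyclicPeptide:
    """An amino-acid string defined up to rotation ('*' = stop)."""

    residues: str

    @property
    def canonical_form(self) -> str:
        return canonical_rotation(self.residues)

    def rotations(self) -> list[str]:
        r = self.residues
        return [r[i:] + r[:i] for i in range(len(r))]

    def __len__(self) -> int:
        return len(self.residues)

    def equivalent(self, other: "CyclicPeptide | str") -> bool:
        other_res = other.residues if isinstance(other, CyclicPeptide) else other
        return (
            len(other_res) == len(self.residues)
            and canonical_rotation(other_res) == self.canonical_form
        )


def six_frame_cyclic_translate(unit: str) -> list[CyclicPeptide]:
    """The six possible peptide products of a tandem repeat unit.

    Frames 0-2 translate rotations of *unit* with the standard nuclear
    genetic code (stops rendered '*'); frames 3-5 do the same for the
    reverse complement.  Each peptide has length ``period / 3``.
    Requires a period divisible by three (any other period cannot
    preserve a reading frame) and a unit over A/C/G/T.
    """
    if not unit or len(unit) % 3 != 0:
        raise ValueError(
            f"unit length {len(unit)} is not a multiple of 3: "
            "no frame-preserving translation exists"
        )
    if not set(unit) <= _ACGT:
        raise ValueError("unit must contain only A, C, G, T")
    peptides = []
    for strand in (unit, str(Seq(unit).reverse_complement())):
        for frame in range(3):
            rotated = strand[frame:] + strand[:frame]
            peptides.append(CyclicPeptide(str(Seq(rotated).translate())))
    return peptides


def _parse_positions(text: str) -> tuple[frozenset[str] | None, ...]:
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.index("]", i)
            letters = frozenset(text[i + 1 : j].replace("|", ""))
            if not letters:
                raise ValueError(f"empty alternative set in pattern {text!r}")
            positions.append(letters)
            i = j + 1
        elif ch == ".":
            positions.append(None)  # wildcard
            i += 1
        else:
            positions.append(frozenset(ch))
            i += 1
    if not positions:
        raise ValueError("empty consensus pattern")
    return tuple(positions)


@dataclass(frozen=True)
class ConsensusPattern:
    """A peptide consensus with positional alternatives.

    Syntax: fixed residues, bracketed alternatives ``[X|Y]`` (the bar
    is optional: ``[IVNSK]``), and ``.`` as a wildcard.  Example:
    ``PP[E|V]LPD`` matches PPELPD and PPVLPD.
    """

    text: str
    name: str = ""

    @property
    def positions(self) -> tuple[frozenset[str] | None, ...]:
        return _parse_positions(self.text)

    def __len__(self) -> int:
        return len(self.positions)

    def matches_linear(self, residues: str) -> bool:
        pos = self.positions
        return len(residues) == len(pos) and all(
            allowed is None or aa in allowed for aa, allowed in zip(residues, pos)
        )


def match_consensus(peptide: CyclicPeptide | str, pattern: ConsensusPattern) -> bool:
    """True iff some rotation of *peptide* satisfies every pattern position.

    A length mismatch is not an error — the peptide simply cannot match
    — but it is logged, since patterns are meant to be applied to
    same-length peptide groups.
    """
    if isinstance(peptide, str):
        peptide = CyclicPeptide(peptide)
    if len(peptide) != len(pattern):
        logger.debug(
            "length mismatch: peptide %r (%d) vs pattern %r (%d)",
            peptide.residues, len(peptide), pattern.text, len(pattern),
        )
        return False
    return any(pattern.matches_linear(rot) for rot in peptide.rotations())


def unit_matches_consensus(unit: str, pattern: ConsensusPattern) -> bool:
    """True iff any of the six cyclic translations of *unit* matches."""
    return any(match_consensus(p, pattern) for p in six_frame_cyclic_translate(unit))


def tally_consensus(
    rows: Iterable[tuple[str, int]], pattern: ConsensusPattern
) -> int:
    """Total locus count over (unit, count) rows matching *pattern*.

    A row contributes its count when any of the six cyclic translations
    of its unit matches the consensus.
    """
    total = 0
    for unit, count in rows:
        if count < 1:
            raise ValueError(f"row counts must be >= 1, got {count} for {unit!r}")
        if unit_matches_consensus(unit, pattern):
            total += count
    return total


@dataclass(frozen=True)
class TranslationReport:
    """Six cyclic peptides of one repeat unit plus its consensus hits."""

    unit: str
    peptides: tuple[CyclicPeptide, ...]
    matched_patterns: tuple[str, ...] = ()

    @classmethod
    def for_unit(
        cls, unit: str, patterns: Sequence[ConsensusPattern] = ()
    ) -> "TranslationReport":
        peptides = tuple(six_frame_cyclic_translate(unit))
        matched = tuple(
            pat.name or pat.text
            for pat in patterns
            if any(match_consensus(p, pat) for p in peptides)
        )
        return cls(unit=unit, peptides=peptides, matched_patterns=matched)
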