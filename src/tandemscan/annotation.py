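"""Classification of repeat loci against gene models.

Each repeat interval is placed into exactly one disjoint bin relative
to a set of transcript models: wholly inside an exon (sub-typed 5' UTR
/ CDS / 3' UTR by position relative to the coding bounds, with strand
deciding which end is 5'), wholly inside a transcript but clear of its
exons (intronic), overlapping an exon/intron or transcript boundary,
within 1,000 bp of a transcript end (near-gene), or intergenic.

Precedence when several transcripts apply: exonic > intronic >
boundary-overlap > near-gene > intergenic; ties between transcripts of
equal precedence go to the smallest transcript span.  Repeats wholly
inside an exon of a transcript with no annotated CDS are reported under
the distinct ``exonic_noncoding`` category (they have no UTR/CDS
structure to sub-type against).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .detector import RepeatRecord

__all__ = [
    "GeneModel",
    "RepeatClassification",
    "GeneIndex",
    "classify_repeat",
    "classify_repeats",
    "classification_summary",
    "NEAR_GENE_DISTANCE",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)

#: Maximum distance (bases) from a transcript end for the near-gene bin.
NEAR_GENE_DISTANCE = 1000

CATEGORIES = (
    "exonic_5utr",
    "exonic_cds",
    "exonic_3utr",
    "exonic_noncoding",
    "intronic",
    "boundary_overlap",
    "near_gene",
    "intergenic",
)

# precedence rank (lower wins); exonic sub-types share one rank
_RANK = {
    "exonic_5utr": 0,
    "exonic_cds": 0,
    "exonic_3utr": 0,
    "exonic_noncoding": 0,
    "intronic": 1,
    "boundary_overlap": 2,
    "near_gene": 3,
    "intergenic": 4,
}


@dataclass(frozen=True)
class GeneModel:
    """One transcript: bounds, coding bounds and exon blocks.

    Coordinates are 1-based inclusive.  A non-coding transcript is
    represented with ``cds_beg > cds_end`` (an empty coding interval).
    """

    gene_id: str
    contig: str
    strand: str
    tx_beg: int
    tx_end: int
    cds_beg: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tx_beg > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_beg > tx_end")
        if self.is_coding and not (
            self.tx_beg <= self.cds_beg <= self.cds_end <= self.tx_end
        ):
            raise ValueError(f"{self.gene_id}: CDS outside transcript bounds")
        prev_end = 0
        for beg, end in self.exons:
            if beg > end or beg < self.tx_beg or end > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon ({beg}, {end}) out of bounds")
            if beg <= prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = end

    @property
    def is_coding(self) -> bool:
        return self.cds_beg <= self.cds_end

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_beg + 1


@dataclass(frozen=True)
class RepeatClassification:
    """A repeat joined to its single genic category."""

    repeat: RepeatRecord
    category: str
    gene_id: str | None = None
    distance: int | None = None  # to nearest transcript end, near_gene only


class GeneIndex:
    """Per-contig interval index over transcripts (plus near-gene halo)."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.n_genes = 0
        for gene in genes:
            tree = self._trees.setdefault(gene.contig, IntervalTree())
            # half-open interval covering the transcript and its halo
            tree.addi(
                max(1, gene.tx_beg - NEAR_GENE_DISTANCE),
                gene.tx_end + NEAR_GENE_DISTANCE + 1,
                gene,
            )
            self.n_genes += 1

    def contigs(self) -> set[str]:
        return set(self._trees)

    def query(self, contig: str, beg: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(beg, end + 1)]


def _classify_against(repeat: RepeatRecord, gene: GeneModel) -> tuple[str, int | None]:
    """Category of *repeat* relative to one transcript (with distance)."""
    beg, end = repeat.beg, repeat.end
    inside_tx = gene.tx_beg <= beg and end <= gene.tx_end
    overlaps_tx = beg <= gene.tx_end and end >= gene.tx_beg

    if inside_tx:
        for ex_beg, ex_end in gene.exons:
            if ex_beg <= beg and end <= ex_end:
                if not gene.is_coding:
                    return "exonic_noncoding", None
                if gene.cds_beg <= beg and end <= gene.cds_end:
                    return "exonic_cds", None
                if end < gene.cds_beg:
                    return ("exonic_5utr" if gene.strand == "+" else "exonic_3utr"), None
                if beg > gene.cds_end:
                    return ("exonic_3utr" if gene.strand == "+" else "exonic_5utr"), None
                # straddles a CDS edge inside one exon: it touches coding bases
                return "exonic_cds", None
        if any(beg <= ex_end and end >= ex_beg for ex_beg, ex_end in gene.exons):
            return "boundary_overlap", None
        return "intronic", None

    if overlaps_tx:
        return "boundary_overlap", None

    dist = gene.tx_beg - end if end < gene.tx_beg else beg - gene.tx_end
    if dist <= NEAR_GENE_DISTANCE:
        return "near_gene", dist
    return "intergenic", None


def classify_repeat(repeat: RepeatRecord, genes: GeneIndex) -> RepeatClassification:
    """Assign *repeat* its single category against an indexed gene set.

    A contig absent from the annotation yields ``intergenic`` with a
    logged warning.
    """
    if repeat.contig not in genes.contigs():
        logger.warning(
            "contig %r absent from annotation; %d-%d classified intergenic",
            repeat.contig, repeat.beg, repeat.end,
        )
        return RepeatClassification(repeat, "intergenic")

    best: tuple[int, int, int, str] | None = None  # (rank, span, dist, ...)
    best_hit: tuple[str, GeneModel | None, int | None] = ("intergenic", None, None)
    for gene in genes.query(repeat.contig, repeat.beg, repeat.end):
        category, dist = _classify_against(repeat, gene)
        # near-gene ties prefer the closer transcript; others the smaller span
        key = (_RANK[category], dist if dist is not None else 0, gene.span, gene.gene_id)
        if best is None or key < best:
            best = key
            best_hit = (category, gene, dist)

    category, gene, dist = best_hit
    return RepeatClassification(
        repeat,
        category,
        gene_id=gene.gene_id if gene is not None and category != "intergenic" else None,
        distance=dist,
    )


def classify_repeats(
    repeats: Iterable[RepeatRecord], genes: Iterable[GeneModel] | GeneIndex
) -> list[RepeatClassification]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [classify_repeat(r, index) for r in repeats]


def classification_summary(
    classifications: Sequence[RepeatClassification],
) -> pd.DataFrame:
    """Contingency counts: category (rows) by repeat period (columns).

    Includes a ``total`` row and column; the grand total equals the
    number of classified repeats.
    """
    if not classifications:
        return pd.DataFrame(
            0, index=pd.Index(list(CATEGORIES) + ["total"], name="category"),
            columns=pd.Index(["total"], name="period"),
        )
    df = pd.DataFrame(
        {
            "category": [c.category for c in classifications],
            "period": [c.repeat.period for c in classifications],
        }
    )
    table = pd.crosstab(df["category"], df["period"]).reindex(
        list(CATEGORIES), fill_value=0
    )
    table.index.name = "category"
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table
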