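"""Seeded synthetic genomes with planted tandem repeats and gene models.

The generator emulates the study conditions of a genome-scale exact
tandem repeat scan: an A+T-rich background (A:T:G:C = 0.3:0.3:0.2:0.2,
matching the composition bias of real repeat-dense fish sequence) into
which primitive-unit tandem runs are planted at known, non-overlapping
loci.  The background is rejection-sampled until it contains no
accidental repeat meeting the detection thresholds, and the bases
immediately bordering each planted run are forced to differ from the
unit so every planted run is maximal by construction.  The emitted
truth table is therefore exhaustive: both recall and precision of a
detector are measurable against it.

The background model is i.i.d. per base; real genomes carry
correlated, approximately-repeating structure this does not emulate,
so detector performance on these genomes demonstrates algorithmic
correctness, not robustness to near-miss repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import GeneModel
from .detector import (
    DetectionParams,
    RepeatRecord,
    SequenceRecord,
    find_tandem_repeats,
    is_primitive,
)

__all__ = [
    "GenomeConfig",
    "PlantedRepeat",
    "SyntheticTruth",
    "generate_genome",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_COMPOSITION = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}


@dataclass(frozen=True)
class PlantedRepeat:
    """Ground truth for one planted tandem run (1-based inclusive)."""

    contig: str
    beg: int
    period: int
    unit: str
    copy_number: int

    @property
    def end(self) -> int:
        return self.beg + self.period * self.copy_number - 1


@dataclass(frozen=True)
class GenomeConfig:
    """Synthetic genome layout.

    ``repeat_specs`` lists (period, copy_number) pairs to plant,
    spread round-robin across contigs.  Thresholds ``min_period`` /
    ``min_copies`` define what counts as an accidental repeat that the
    background must not contain.
    """

    n_contigs: int = 1
    contig_length: int = 20_000
    repeat_specs: tuple[tuple[int, int], ...] = ((3, 10), (5, 12), (7, 11))
    composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)  # ACGT
    min_period: int = 3
    max_period: int = 54
    min_copies: int = 10
    margin: int = 10  # clear bases kept on each side of a planted run

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("need at least one contig of positive length")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        for period, copies in self.repeat_specs:
            if period * copies + 2 * self.margin > self.contig_length:
                raise ValueError(
                    f"planted repeat {period}x{copies} does not fit in a "
                    f"{self.contig_length}-base contig"
                )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted loci, planted gene models, and generation metadata."""

    repeats: tuple[PlantedRepeat, ...]
    genes: tuple[GeneModel, ...]
    seed: int
    composition: tuple[float, float, float, float]


def _random_background(
    rng: np.random.Generator, length: int, composition, params: DetectionParams
) -> np.ndarray:
    """I.i.d. background, rejection-sampled free of accidental repeats."""
    for _ in range(50):
        arr = rng.choice(_BASES, size=length, p=list(composition))
        rec = SequenceRecord("bg", arr.tobytes().decode("ascii"))
        if not find_tandem_repeats(rec, params):
            return arr
    raise RuntimeError(
        "could not sample an accidental-repeat-free background; "
        "composition too skewed for the requested thresholds"
    )


def _random_primitive_unit(rng: np.random.Generator, period: int, composition) -> str:
    while True:
        unit = rng.choice(_BASES, size=period, p=list(composition)).tobytes().decode()
        if is_primitive(unit):
            return unit


def generate_genome(
    config: GenomeConfig, seed: int
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Deterministically generate contigs with planted tandem repeats.

    The same (config, seed) pair always yields byte-identical output.
    Planted loci are non-overlapping, separated by at least
    ``config.margin`` background bases, and maximal (the bordering
    bases are forced to mismatch the unit at both ends).
    """
    rng = np.random.default_rng(seed)
    detect = DetectionParams(
        min_period=config.min_period,
        max_period=config.max_period,
        min_copies=config.min_copies,
        flank_len=0,
    )

    # round-robin assignment of repeat specs to contigs
    per_contig: list[list[tuple[int, int]]] = [[] for _ in range(config.n_contigs)]
    for i, spec in enumerate(config.repeat_specs):
        per_contig[i % config.n_contigs].append(spec)

    records: list[SequenceRecord] = []
    planted: list[PlantedRepeat] = []
    for ci in range(config.n_contigs):
        name = f"ctg{ci + 1:03d}"
        arr = _random_background(rng, config.contig_length, config.composition, detect)

        # lay the runs left to right with random gaps of at least `margin`
        specs = per_contig[ci]
        total_run = sum(p * c for p, c in specs)
        free = config.contig_length - total_run - config.margin * (len(specs) + 1)
        if free < 0:
            raise ValueError(
                f"planted repeats do not fit contig {name}: "
                f"{total_run} run bases vs length {config.contig_length}"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=len(specs))) if specs else []
        pos = 0
        for k, (period, copies) in enumerate(specs):
            gap = int(cuts[k]) if k == 0 else int(cuts[k]) - int(cuts[k - 1])
            start = pos + config.margin + gap
            unit = _random_primitive_unit(rng, period, config.composition)
            run = np.frombuffer((unit * copies).encode(), dtype=np.uint8)
            arr[start : start + run.size] = run
            # guard bases: force a mismatch one base before and after the run
            arr[start - 1] = _other_base(rng, ord(unit[-1]))
            arr[start + run.size] = _other_base(rng, ord(unit[0]))
            planted.append(
                PlantedRepeat(
                    contig=name, beg=start + 1, period=period,
                    unit=unit, copy_number=copies,
                )
            )
            pos = start + run.size
        records.append(SequenceRecord(name, arr.tobytes().decode("ascii")))

    genes = _plant_genes(rng, records)
    truth = SyntheticTruth(
        repeats=tuple(planted),
        genes=genes,
        seed=seed,
        composition=config.composition,
    )
    return records, truth


def _other_base(rng: np.random.Generator, code: int) -> int:
    choices = _BASES[_BASES != code]
    return int(rng.choice(choices))


def _plant_genes(
    rng: np.random.Generator, records: Sequence[SequenceRecord]
) -> tuple[GeneModel, ...]:
    """One simple coding transcript per sufficiently long contig."""
    genes = []
    for rec in records:
        if rec.length < 4000:
            continue
        tx_beg = int(rng.integers(1, rec.length // 4))
        tx_end = min(rec.length, tx_beg + int(rng.integers(2000, rec.length // 2)))
        third = (tx_end - tx_beg) // 3
        exons = ((tx_beg, tx_beg + third // 2), (tx_end - third // 2, tx_end))
        cds_beg = tx_beg + third // 4
        cds_end = tx_end - third // 4
        genes.append(
            GeneModel(
                gene_id=f"{rec.name}.t1",
                contig=rec.name,
                strand="+" if rng.random() < 0.5 else "-",
                tx_beg=tx_beg,
                tx_end=tx_end,
                cds_beg=cds_beg,
                cds_end=cds_end,
                exons=exons,
            )
        )
    return tuple(genes)


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    """Planted-locus table: contig, beg, end, period, unit, copy number."""
    with open(path, "wt") as out:
        out.write("contig\tbeg\tend\tperiod\tunit\tcopyNumber\n")
        for r in truth.repeats:
            out.write(
                f"{r.contig}\t{r.beg}\t{r.end}\t{r.period}\t{r.unit}\t{r.copy_number}\n"
            )
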