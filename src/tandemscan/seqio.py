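"""Readers and writers for the formats the tool touches.

Conventions: repeat tables are TSV with the columns ctgName,
rptBegPos, rptEndPos, RptLen, RptCopyNum, unit, repeatSeq,
fivePrimeSeq, threePrimeSeq (1-based inclusive coordinates); BED
output converts to 0-based half-open.  Gene models come from GFF3
(assembled per transcript from mRNA/transcript, exon and CDS features)
or BED12 (blocks are exons, thickStart/thickEnd the coding bounds).
All readers and writers round-trip losslessly.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import gffutils
import pandas as pd
from Bio import SeqIO

from .annotation import GeneModel
from .detector import RepeatRecord, SequenceRecord

__all__ = [
    "FastaParseError",
    "REPEAT_TSV_COLUMNS",
    "read_fasta",
    "read_gene_models",
    "read_contig_lengths",
    "read_repeats_tsv",
    "write_repeats_tsv",
    "write_bed",
]

logger = logging.getLogger(__name__)

REPEAT_TSV_COLUMNS = (
    "ctgName",
    "rptBegPos",
    "rptEndPos",
    "RptLen",
    "RptCopyNum",
    "unit",
    "repeatSeq",
    "fivePrimeSeq",
    "threePrimeSeq",
)


class FastaParseError(ValueError):
    """Malformed FASTA input, reported with a line number."""


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, case_policy: str = "fold") -> list[SequenceRecord]:
    """Read a (possibly gzipped) multi-record FASTA file.

    Record names are the header token up to the first whitespace and
    must be unique.  ``case_policy="fold"`` uppercases sequence;
    ``"respect"`` preserves it.  CRLF and LF files parse identically.
    """
    if case_policy not in ("fold", "respect"):
        raise ValueError(f"unknown case_policy {case_policy!r}")

    # cheap validation pass for the errors Biopython silently tolerates
    seen: set[str] = set()
    header_line = 0
    body_chars = 0
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line and body_chars == 0:
                    raise FastaParseError(
                        f"{path}: empty record at line {header_line}"
                    )
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FastaParseError(f"{path}: unnamed record at line {lineno}")
                if name in seen:
                    raise FastaParseError(
                        f"{path}: duplicate record name {name!r} at line {lineno}"
                    )
                seen.add(name)
                header_line, body_chars = lineno, 0
            else:
                if not header_line:
                    raise FastaParseError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                body_chars += len(line)
        if header_line and body_chars == 0:
            raise FastaParseError(f"{path}: empty record at line {header_line}")

    records = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if case_policy == "fold":
                seq = seq.upper()
            records.append(SequenceRecord(name=rec.id, seq=seq))
    return records


# --------------------------------------------------------------------------
# Gene models


def _gene_models_from_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feature_type in ("mRNA", "transcript"):
        for tx in db.features_of_type(feature_type):
            exons = sorted(
                (f.start, f.end) for f in db.children(tx, featuretype="exon")
            )
            cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
            if cds:
                cds_beg = min(b for b, _ in cds)
                cds_end = max(e for _, e in cds)
            else:
                cds_beg, cds_end = tx.end + 1, tx.end  # empty: non-coding
            try:
                genes.append(
                    GeneModel(
                        gene_id=tx.id,
                        contig=tx.seqid,
                        strand=tx.strand,
                        tx_beg=tx.start,
                        tx_end=tx.end,
                        cds_beg=cds_beg,
                        cds_end=cds_end,
                        exons=tuple(exons) or ((tx.start, tx.end),),
                    )
                )
            except ValueError as exc:
                logger.warning("skipping transcript %s: %s", tx.id, exc)
    return genes


def _gene_models_from_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: BED12 requires 12 fields, got {len(fields)}"
                )
            contig, chrom_start, chrom_end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            exons = tuple(
                (chrom_start + off + 1, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            )
            if thick_start >= thick_end:  # non-coding convention
                cds_beg, cds_end = chrom_end + 1, chrom_end
            else:
                cds_beg, cds_end = thick_start + 1, thick_end
            try:
                genes.append(
                    GeneModel(
                        gene_id=name,
                        contig=contig,
                        strand=strand,
                        tx_beg=chrom_start + 1,
                        tx_end=chrom_end,
                        cds_beg=cds_beg,
                        cds_end=cds_end,
                        exons=exons,
                    )
                )
            except ValueError as exc:
                logger.warning("%s:%d: skipping record %s: %s", path, lineno, name, exc)
    return genes


def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read transcript models, normalised to 1-based inclusive coordinates.

    ``format`` is ``"gff3"`` or ``"bed12"``.  Records whose exons fall
    outside the transcript bounds are skipped with a warning.
    """
    if format == "gff3":
        return _gene_models_from_gff3(path)
    if format == "bed12":
        return _gene_models_from_bed12(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (name, length) -> mapping; names must be unique."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["name", "length"], comment="#",
        dtype={"name": str, "length": int},
    )
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"{path}: duplicate contig names {dupes}")
    if (df["length"] < 1).any():
        raise ValueError(f"{path}: contig lengths must be >= 1")
    return dict(zip(df["name"], df["length"]))


# --------------------------------------------------------------------------
# Repeat tables


def write_repeats_tsv(repeats: Iterable[RepeatRecord], path: str | Path) -> None:
    """Write the canonical repeat table (one header + one line per locus)."""
    rows = [
        (r.contig, r.beg, r.end, r.period, r.copy_number, r.unit, r.repeat_seq,
         r.flank5, r.flank3)
        for r in repeats
    ]
    df = pd.DataFrame(rows, columns=list(REPEAT_TSV_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_repeats_tsv(path: str | Path) -> list[RepeatRecord]:
    """Read a repeat table written by `write_repeats_tsv` (lossless)."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_filter=False
    )
    missing = set(REPEAT_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        RepeatRecord(
            contig=row.ctgName,
            beg=int(row.rptBegPos),
            end=int(row.rptEndPos),
            period=int(row.RptLen),
            copy_number=int(row.RptCopyNum),
            unit=row.unit,
            repeat_seq=row.repeatSeq,
            flank5=row.fivePrimeSeq,
            flank3=row.threePrimeSeq,
        )
        for row in df.itertuples(index=False)
    ]


def write_bed(repeats: Iterable[RepeatRecord], path: str | Path) -> None:
    """BED6 output: 0-based half-open, name = unit x copies, score capped.

    ``chromStart = rptBegPos - 1``, ``chromEnd = rptEndPos``; score is
    the copy number capped at 1000; strand reported '+' (detection is
    strand-specific to the given sequence).
    """
    with open(path, "wt") as out:
        for r in repeats:
            name = f"{r.unit}x{r.copy_number}"
            score = min(r.copy_number, 1000)
            out.write(
                f"{r.contig}\t{r.beg - 1}\t{r.end}\t{name}\t{score}\t+\n"
            )
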