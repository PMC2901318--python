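"""Exact tandem repeat detection.

A tandem repeat is a nucleotide pattern (the *unit*, or base pattern)
occurring in immediately adjacent, character-for-character identical
copies: ``CAGCAGCAG...`` is ``(CAG)_k`` with period 3 and copy number
``k``.  This module finds every maximal such run whose unit is
*primitive* (not itself a whole-number power of a shorter string),
resolves frame-shift overlaps in favour of the largest copy number,
and attaches flanking sequence for downstream primer design.

The fast scanner works per period ``p`` by comparing each base with the
base ``p`` positions ahead (a vectorised form of the sliding-window
equality test); a maximal stretch of ``L`` consecutive agreements is a
periodic region of ``L + p`` bases holding ``(L + p) // p`` complete
copies.  The work per period is one pass over the sequence, so total
cost is ``C * n`` for ``C`` periods over ``n`` bases.

An independent O(n^2 * C) brute-force scanner (`brute_force_oracle`)
re-derives the same records by direct copy counting and is kept free of
any code shared with the fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SequenceRecord",
    "DetectionParams",
    "RepeatRecord",
    "is_primitive",
    "smallest_period",
    "find_runs_for_period",
    "window_comparison_count",
    "resolve_overlaps",
    "extract_flanks",
    "find_tandem_repeats",
    "brute_force_oracle",
]

_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """One named contig / linkage-group sequence."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence record requires a non-empty name")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds and policies.

    Defaults mirror a genome-scale VNTR-mining run: unit length
    (period) of at least three bases, at least ten exact adjacent
    copies, and 500 bases of flanking sequence (where available)
    reported for primer placement.  ``max_period`` defaults to 54, the
    longest unit length observed in the zebrafish Zv8 survey, and is
    freely configurable upward.

    ``case_policy``: ``"fold"`` uppercases input so soft-masked
    (lowercase) bases still match exactly; ``"respect"`` leaves case
    alone, which excludes soft-masked regions because only uppercase
    A/C/G/T participate in matches.

    ``cross_period_overlaps``: ``"keep"`` retains staggered overlapping
    repeats of *different* periods as distinct loci (per-period tallies
    stay independent); ``"resolve"`` applies the largest-copy-number
    rule across periods as well.
    """

    min_period: int = 3
    max_period: int = 54
    min_copies: int = 10
    flank_len: int = 500
    case_policy: str = "fold"
    cross_period_overlaps: str = "keep"

    def __post_init__(self) -> None:
        if not 1 <= self.min_period <= self.max_period:
            raise ValueError(
                f"need 1 <= min_period <= max_period, got "
                f"[{self.min_period}, {self.max_period}]"
            )
        if self.min_copies < 2:
            raise ValueError("min_copies must be at least 2")
        if self.flank_len < 0:
            raise ValueError("flank_len must be non-negative")
        if self.case_policy not in ("fold", "respect"):
            raise ValueError(f"unknown case_policy {self.case_policy!r}")
        if self.cross_period_overlaps not in ("keep", "resolve"):
            raise ValueError(
                f"unknown cross_period_overlaps {self.cross_period_overlaps!r}"
            )


@dataclass(frozen=True)
class RepeatRecord:
    """One detected exact tandem repeat locus.

    Coordinates are 1-based inclusive.  ``unit`` is the first
    period-length window of the run (no rotation or strand
    normalisation: AAT and ATT count as distinct bases).  Copy number
    counts complete exact copies only; a trailing partial copy is
    neither extended nor reported.
    """

    contig: str
    period: int
    unit: str
    copy_number: int
    beg: int
    end: int
    repeat_seq: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if self.end - self.beg + 1 != self.period * self.copy_number:
            raise ValueError(
                f"span [{self.beg}, {self.end}] inconsistent with "
                f"period {self.period} x {self.copy_number} copies"
            )


def is_primitive(unit: str) -> bool:
    """True iff *unit* is not a whole-number power of a shorter string.

    ``ACTAACTAACTA`` is rejected (it is ``(ACTA)_3``); ``CAG`` passes.
    Only proper divisors of the unit length need checking (for a
    12-mer: sub-periods 1, 2, 3, 4 and 6).
    """
    if not unit:
        raise ValueError("empty unit is not a valid window")
    return smallest_period(unit) == len(unit)


def smallest_period(unit: str) -> int:
    """Length of the shortest string whose power equals *unit*.

    Equals ``len(unit)`` when the unit is primitive.
    """
    if not unit:
        raise ValueError("empty unit is not a valid window")
    n = len(unit)
    for d in range(1, n // 2 + 1):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return d
    return n


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Byte-encode a sequence and mark the positions that are A/C/G/T."""
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    valid = np.isin(arr, _ACGT_CODES)
    return arr, valid


def _match_array(arr: np.ndarray, valid: np.ndarray, period: int) -> np.ndarray:
    """Adjacent-window agreement: position i agrees with position i+period.

    Any position outside {A,C,G,T} never matches, so runs break at Ns,
    ambiguity codes and (under the respect-case policy) soft-masked
    lowercase bases.
    """
    return (arr[:-period] == arr[period:]) & valid[:-period] & valid[period:]


def _true_runs(mask: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield (start, length) of each maximal run of True in *mask*."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for a, b in zip(edges[0::2], edges[1::2]):
        yield int(a), int(b - a)


def find_runs_for_period(
    record: SequenceRecord, period: int, min_copies: int
) -> list[tuple[int, int]]:
    """Maximal runs of >= *min_copies* exact copies of a primitive unit.

    Returns ``(beg, copy_number)`` pairs (1-based beg).  Each maximal
    periodic region contributes one run at its leftmost phase, which
    carries the largest achievable copy count for that region.  Runs
    whose unit is a power of a shorter string are discarded — they are
    captured at the smaller period.  Periods longer than half the
    sequence return an empty list.
    """
    if period < 1:
        raise ValueError("period must be positive")
    n = record.length
    if 2 * period > n:
        return []
    arr, valid = _encode(record.seq)
    out: list[tuple[int, int]] = []
    for a, run_len in _true_runs(_match_array(arr, valid, period)):
        copies = (run_len + period) // period
        if copies < min_copies:
            continue
        unit = record.seq[a : a + period]
        if is_primitive(unit):
            out.append((a + 1, copies))
    return out


def window_comparison_count(record: SequenceRecord, period: int) -> int:
    """Number of adjacent-window base comparisons one scan pass performs.

    Executes the scan for *period* and reports the comparisons made;
    the pass touches each eligible position once, so the count grows
    linearly in sequence length.
    """
    if period < 1:
        raise ValueError("period must be positive")
    n = record.length
    if period >= n:
        return 0
    arr, valid = _encode(record.seq)
    return int(_match_array(arr, valid, period).size)


def _cluster_overlaps(records: Sequence[RepeatRecord]) -> Iterator[list[RepeatRecord]]:
    """Group records into connected components of interval overlap."""
    ordered = sorted(records, key=lambda r: (r.beg, r.end))
    cluster: list[RepeatRecord] = []
    reach = -1
    for rec in ordered:
        if cluster and rec.beg > reach:
            yield cluster
            cluster = []
        cluster.append(rec)
        reach = max(reach, rec.end)
    if cluster:
        yield cluster


def resolve_overlaps(
    candidates: Sequence[RepeatRecord], params: DetectionParams | None = None
) -> list[RepeatRecord]:
    """Resolve frame-shift overlaps: the largest copy number wins.

    Among same-period candidates whose intervals overlap exactly one
    survives — the one with most copies, ties broken by smaller beg,
    then lexicographically smaller unit.  Overlapping records of
    *different* periods are all retained under the default policy
    (staggered repeats of different unit lengths are distinct loci);
    with ``cross_period_overlaps="resolve"`` the same rule applies
    across periods, with the smaller period as first tie-breaker.

    Idempotent and insensitive to input order.
    """
    if not candidates:
        return []
    contigs = {r.contig for r in candidates}
    if len(contigs) > 1:
        raise ValueError(f"candidates span multiple contigs: {sorted(contigs)}")
    params = params or DetectionParams()

    if params.cross_period_overlaps == "keep":
        groups: dict[int, list[RepeatRecord]] = {}
        for rec in candidates:
            groups.setdefault(rec.period, []).append(rec)
        pools = groups.values()
        key = lambda r: (-r.copy_number, r.beg, r.unit)  # noqa: E731
    else:
        pools = [list(candidates)]
        key = lambda r: (-r.copy_number, r.period, r.beg, r.unit)  # noqa: E731

    winners = [
        min(cluster, key=key) for pool in pools for cluster in _cluster_overlaps(pool)
    ]
    return sorted(winners, key=lambda r: (r.beg, r.period))


def extract_flanks(
    record: SequenceRecord, repeat: RepeatRecord, flank_len: int
) -> tuple[str, str]:
    """Up-to-*flank_len* bases upstream and downstream of the repeat.

    Flanks truncate (possibly to empty strings) at contig ends.
    """
    if not (1 <= repeat.beg <= repeat.end <= record.length):
        raise ValueError(
            f"repeat [{repeat.beg}, {repeat.end}] outside contig "
            f"{record.name} of length {record.length}"
        )
    if flank_len < 0:
        raise ValueError("flank_len must be non-negative")
    flank5 = record.seq[max(0, repeat.beg - 1 - flank_len) : repeat.beg - 1]
    flank3 = record.seq[repeat.end : repeat.end + flank_len]
    return flank5, flank3


def _working_record(record: SequenceRecord, params: DetectionParams) -> SequenceRecord:
    if params.case_policy == "fold":
        return SequenceRecord(record.name, record.seq.upper())
    return record


def find_tandem_repeats(
    record: SequenceRecord, params: DetectionParams | None = None
) -> list[RepeatRecord]:
    """Detect all exact tandem repeats in one sequence.

    For each period in ``[min_period, max_period]`` the scanner emits
    maximal primitive runs meeting ``min_copies``, overlaps are
    resolved, and flanks attached.  Output is sorted by
    ``(beg, period)`` and fully deterministic.
    """
    params = params or DetectionParams()
    work = _working_record(record, params)
    n = work.length
    if n == 0:
        return []
    arr, valid = _encode(work.seq)

    candidates: list[RepeatRecord] = []
    for period in range(params.min_period, min(params.max_period, n // 2) + 1):
        per_period: list[RepeatRecord] = []
        for a, run_len in _true_runs(_match_array(arr, valid, period)):
            copies = (run_len + period) // period
            if copies < params.min_copies:
                continue
            unit = work.seq[a : a + period]
            if not is_primitive(unit):
                continue
            beg, end = a + 1, a + period * copies
            per_period.append(
                RepeatRecord(
                    contig=work.name,
                    period=period,
                    unit=unit,
                    copy_number=copies,
                    beg=beg,
                    end=end,
                    repeat_seq=work.seq[a : end],
                )
            )
        # same-period frame-shift overlaps are resolved unconditionally
        candidates.extend(resolve_overlaps(per_period, params))

    if params.cross_period_overlaps == "resolve":
        candidates = resolve_overlaps(candidates, params)

    out = []
    for rec in candidates:
        flank5, flank3 = extract_flanks(work, rec, params.flank_len)
        out.append(replace(rec, flank5=flank5, flank3=flank3))
    return sorted(out, key=lambda r: (r.beg, r.period))


# --------------------------------------------------------------------------
# Independent brute-force reference scanner (test oracle).


def _bf_copies_at(seq: str, start: int, period: int) -> int:
    """Complete adjacent copies of the window at *start* (0-based).

    Zero when the window is short or contains a non-ACGT character
    (such windows never match anything, themselves included).
    """
    unit = seq[start : start + period]
    if len(unit) < period or not set(unit) <= _ACGT:
        return 0
    copies = 1
    pos = start + period
    while seq[pos : pos + period] == unit:
        copies += 1
        pos += period
    return copies


def brute_force_oracle(
    record: SequenceRecord, params: DetectionParams | None = None
) -> list[RepeatRecord]:
    """Direct O(n^2 * C) re-derivation of `find_tandem_repeats`.

    For every (start, period) pair the adjacent copies of the window
    are counted one comparison at a time.  A run is kept when it meets
    the copy threshold, its unit is primitive, and it is not dominated
    by the run one position to its left (which covers it with at least
    as many copies — this discards the inferior phases of a periodic
    region).  The identical overlap-resolution rule then applies.
    Intended for test-scale sequences (<= ~1,000 bases).
    """
    params = params or DetectionParams()
    work = _working_record(record, params)
    seq, n = work.seq, work.length
    if n == 0:
        return []

    candidates: list[RepeatRecord] = []
    for period in range(params.min_period, min(params.max_period, n // 2) + 1):
        per_period: list[RepeatRecord] = []
        for start in range(0, n - 2 * period + 1):
            copies = _bf_copies_at(seq, start, period)
            if copies < params.min_copies:
                continue
            unit = seq[start : start + period]
            if not is_primitive(unit):
                continue
            if start > 0 and _bf_copies_at(seq, start - 1, period) >= copies:
                continue  # inferior phase of the same periodic region
            per_period.append(
                RepeatRecord(
                    contig=work.name,
                    period=period,
                    unit=unit,
                    copy_number=copies,
                    beg=start + 1,
                    end=start + period * copies,
                    repeat_seq=seq[start : start + period * copies],
                )
            )
        candidates.extend(resolve_overlaps(per_period, params))

    if params.cross_period_overlaps == "resolve":
        candidates = resolve_overlaps(candidates, params)

    out = []
    for rec in candidates:
        flank5, flank3 = extract_flanks(work, rec, params.flank_len)
        out.append(replace(rec, flank5=flank5, flank3=flank3))
    return sorted(out, key=lambda r: (r.beg, r.period))
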