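# Methods

## Detection model

The object of detection is the *exact* tandem repeat: a run of `k`
adjacent, identical copies of a primitive unit of length `p` (the
period). "Exact" is taken literally — one mismatch, insertion or
deletion ends a run, and a stutter inside a long repeat therefore
yields two adjacent reported loci rather than one. This is a deliberate
trade: exactness makes the locus definition unambiguous and the scan
linear-time, at the cost of under-reporting degenerate repeats that
approximate-matching tools (e.g. Tandem Repeats Finder) would merge.

For a fixed period `p` the scanner computes the agreement vector
`m[i] = (S[i] == S[i+p])` over the whole sequence (a vectorised form of
the sliding-window equality test). A maximal stretch of `L` consecutive
agreements starting at `a` is a periodic region of `L + p` bases; it
holds `⌊(L + p)/p⌋` complete copies, and the leftmost phase `a` attains
that maximum, so each region is reported once, at its leftmost phase,
with complete copies only (a trailing partial copy is not extended).
Any position outside `{A, C, G, T}` never agrees with anything, which
breaks runs at `N`s, ambiguity codes, and — under the respect-case
policy — soft-masked lowercase bases.

**Primitivity.** A candidate unit is discarded if it equals a
whole-number power of a shorter string (checked over the proper
divisors of `p`); such runs are exactly the ones already captured at
the smaller period. Rotations of a primitive word are primitive, so
phase choice cannot change the verdict.

**Maximality.** Because regions are maximal in the agreement vector,
the period-length window immediately before a reported run differs
from the unit (or falls off the contig / contains a non-ACGT
character), and likewise after it. This is asserted property-style in
the tests.

**Overlap resolution.** Frame shifting can still produce overlapping
candidates of one period (two maximal regions less than `p` bases
apart). Overlapping same-period candidates are grouped by transitive
interval overlap and exactly one survives per group: largest copy
number, then smallest begin, then lexicographically smallest unit —
the last two tie-breaks are this package's choice, made for
determinism. Overlaps *between* periods are kept by default, since
per-period tallies treat each unit length as an independent locus
class and staggered multi-period repeats are real; a strict mode
(`cross_period_overlaps="resolve"`) applies the same rule across
periods with the smaller period as first tie-breaker.

**Units and coordinates.** A run's unit is its first period-length
window — no rotation or reverse-complement normalisation, so `AAT` and
`ATT` are distinct unit classes. All reported coordinates are 1-based
inclusive; BED output converts to 0-based half-open.

**Defaults.** `min_period = 3` (mono- and dinucleotide microsatellites
are out of the target class), `min_copies = 10`, `flank_len = 500`
(primer-design context), `max_period = 54` (the longest unit length
observed in the zebrafish Zv8 survey; configurable upward). Input case
is folded to uppercase by default so soft-masking cannot break
exactness.

**Oracle.** `brute_force_oracle` re-derives the output with none of
the fast path's machinery: for every `(start, period)` it counts
adjacent copies by direct string comparison, keeps primitive runs that
meet the threshold and are not dominated by the run one position to
the left (which removes inferior phases of the same region), and
applies the identical resolution rule. Equality of the two paths is
checked on hundreds of seeded random sequences and under Hypothesis.

## Translation analysis

A unit with `p ≡ 0 (mod 3)` preserves reading frame inside a coding
region. Treating the infinite run as circular, there are exactly six
peptide products — rotations of the unit at offsets 0/1/2, translated
with the standard nuclear genetic code (stops printed `*`), and the
same for the reverse complement. Each product is only defined up to
rotation, so all comparisons use the lexicographically smallest
rotation (`canonical_rotation`). Published tables print translations at
arbitrary phases; rotation-invariant comparison is what makes them
reproducible.

Consensus patterns use fixed residues, bracketed alternatives
(`[E|V]`, bar optional) and `.` as a wildcard. A cyclic peptide matches
if any rotation satisfies every position; a unit matches if any of its
six products does. Group tallies sum locus counts over matching units.

The curated family tables (`tandemscan.zv8`) carry the catalogued
length-18/24/27/30 units with their published translations and locus
counts. Seven published cells are internally inconsistent — a peptide
whose residue count cannot arise from the unit length, letter
transpositions, and one row printing a rotation of another of its own
frames while omitting the true sixth frame. These are catalogued in
`TRANSLATION_ERRATA` with the peptide the genetic code yields;
consistency tests compare computed translations against the corrected
cells and verify that every erratum is demonstrably a transcription
error. The length-24 consensus is used in its 8-residue table form
`PGP.QLHA` (position 4 relaxed to a wildcard so the `PGPRQLHA` variant
matches); the 9-residue form printed elsewhere is impossible for a
24-mer.

## Genic classification

A repeat interval is assigned exactly one category per the precedence:
wholly inside an exon → exonic (sub-typed against the CDS interval,
with strand deciding which untranslated side is 5′); wholly inside a
transcript but intersecting no exon → intronic; otherwise overlapping
any exon/intron or transcript boundary → boundary_overlap; else within
1,000 bp of a transcript end → near_gene (distance reported); else
intergenic. When several transcripts apply, the highest-precedence
category wins; ties go to the closer transcript (near-gene) or the
smaller transcript span (otherwise). Design choices where the
published counts leave the rule open: an exon-contained interval that
straddles a CDS edge is counted `exonic_cds` (it covers coding bases);
exon-contained intervals in CDS-less transcripts get their own
`exonic_noncoding` category rather than a UTR label; the 1,000-bp
near-gene distance is measured strand-agnostically from the repeat
edge to the nearest transcript end. Lookup is via a per-contig
interval tree over transcripts padded by the near-gene halo, so
classification is independent of gene-list order.

## Positional distribution

Each linkage group is split into `n_bins = 20` equal segments (5% of
the group length each); a repeat falls in bin
`⌊(beg − 1)·n_bins / L⌋ + 1` by its begin position — half-open
segments, with the final base folding into the last bin. The uniform
null is tested with `χ² = Σ (O − E)²/E`, `E = total/n_bins`, on
`n_bins − 1` degrees of freedom, no continuity correction; critical
values come from `scipy.stats.chi2.ppf` (30.14 / 36.19 at 19 df for
p = 0.95 / 0.99). Stratification by base length (3, 4, 5, >5) is a CLI
flag. `simulated_rejection_rate` checks calibration and power by
multinomial simulation: under the null the rejection rate at the 0.95
critical value sits near 5%; under a telomere-bias model (a 50/50
mixture of uniform placement and placement in the outer 5% + 5% of the
group) rejection is near-certain for n ≥ 500 — the qualitative pattern
of telomeric repeat enrichment, reproduced as a power property.

## Synthetic genomes

`generate_genome` emulates the study conditions at desk scale:
contigs of i.i.d. background with composition A:T:G:C =
0.3:0.3:0.2:0.2 (tandem-repeat-dense fish sequence is A+T rich), into
which primitive units are planted as exact runs at non-overlapping
positions with at least 10 background bases between loci. The
background is rejection-sampled until it contains no accidental repeat
meeting the detection thresholds — this check runs on the background
*before* planting, so detector-vs-truth comparisons stay independent —
and the single base on each side of every planted run is forced to
mismatch the unit, making maximality hold by construction. The truth
table is therefore exhaustive: recall and precision are both
measurable, and both are asserted to be 100% on 100 planted repeats
spanning periods 3–54. Test problem sizes (contigs of 15–20 kb, a few
contigs per genome) were chosen as the smallest scale at which every
period class in 3–54 can be planted comfortably; the scan itself is
linear-time and has been exercised to 1 Mb in the comparison-count
test. What these genomes do **not** emulate: compositional
heterogeneity, near-miss (inexact) repeats, and the correlated repeat
landscape of real assemblies — passing tests demonstrate algorithmic
correctness, not robustness of the exact-match definition on
real data.

## Numerical and degenerate-input conventions

Empty sequences yield empty results; an empty unit is an error. A
period greater than half the sequence cannot repeat and returns no
runs. `chi_square_uniform` on an all-zero table is an error (the test
is undefined), as is a begin position outside `[1, L]`. Repeat tables
round-trip losslessly through TSV including empty flank fields; the
GFF3 and BED12 readers normalise to 1-based inclusive coordinates and
skip (with a warning) records whose exons fall outside their
transcript. All randomness flows through explicit integer seeds; equal
inputs and flags give byte-identical outputs, independent of the
`--threads` setting (contigs are processed independently and collected
in input order).

## Known limitations

Inexact repeats are split or truncated by design. Reverse-complement
unit classes are not merged. Multi-isoform annotation is reduced to a
single category by the precedence rule rather than reported per
isoform. The near-linear scan is per period; total work still scales
with the size of the period range.
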