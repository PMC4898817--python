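# Methods

## Coordinate model

All internal coordinates are 0-based half-open intervals with an explicit
strand; GFF3's 1-based inclusive convention is converted at the I/O
boundary only. "Contained in a window" means interval containment
(`win.start <= read.start` and `read.end <= win.end`) on the same
chromosome and strand; boundary positions are inclusive in these interval
terms.

## Window derivation

For a mature arm at [s, e) with slack k (default 3) and moR extent m
(default 35), on the plus strand:

- miR window `[s − k, e + k)`;
- 5p moR window `[s − m, s + k + 1)` — m nt upstream of the miR's first
  base through k nt past it;
- 3p moR window `[e − k − 1, e + m)` — the mirror image on the 3' side.

On the minus strand the same definitions apply in transcript orientation
(the 5'-terminal base of a minus-strand miR is its genomic end − 1), which
makes minus-strand windows the exact coordinate reflection of plus-strand
ones (property-tested). The phrase "k nt 3' of the first base" is read as
including the first base plus k further bases, so both moR windows have
length m + k + 1 = 39 nt and each same-arm miR/moR pair overlaps by exactly
2k + 1 = 7 nt. Consequently no read of length ≥ `min_insert` (14 nt, the
shortest insert kept) can be contained in both a miR and a moR window; the
constructor of `QuantParams` enforces `2·mir_slack + 1 < min_insert` so the
exclusivity law survives re-parameterization. Windows are clipped at
position 0 but deliberately not trimmed to the pri-miR interval, since they
are defined relative to the mature miRs alone.

Arm assignment prefers explicit `-5p`/`-3p` name suffixes and falls back to
transcript-orientation order (5'-most mature = 5p) when any child is
unnamed.

## Read assignment and counting

Locus assignment uses gap distance between the read interval and the
pri-miR hairpin interval, boundary-inclusive at exactly `locus_distance`
(50 nt): a read ending exactly 50 nt before a hairpin is assigned, 51 nt is
not. Same-strand mapping is required for both assignment and
classification; antisense reads are never counted. A read with several
alignment records pools the candidate loci of all of them and is allotted
evenly (weight 1/n) across the union — the even-allotment rule extended to
the only multi-assignment case aligned input can present. Classification
precedence is miR before moR; given the exclusivity law this matters only
for sub-minimum-length inputs.

Reads assigned to a locus but contained in no window (loop reads, partial
overlaps) contribute to neither the counts nor the RPMR denominator. RPMR
divides each weighted count by the per-library total over all four
categories and loci, divided by 10⁶, so per-library RPMR sums to 10⁶
exactly whenever any read is counted.

Adapter trimming is exact-substring: the read is cut at the leftmost
occurrence of the adapter's first `min_overlap` (6) bases, which subsumes
both full-adapter and terminal partial-adapter matches; no error tolerance.
This is a deliberately minimal, reproducible contract — alignments may be
supplied directly, bypassing trimming entirely.

## Seed windows and scanning

A candidate seed is any 7-mer window of the small RNA (starts 1..L−6,
1-based); start 2 is the canonical seed (nucleotides 2–8). A seed match is
the exact DNA reverse complement of the window on the UTR sense strand: no
7mer-A1/8mer subtypes, no context scoring, no conservation filter (those
require multi-genome resources and are out of scope). A gene is a hit iff
it has ≥ 1 occurrence; multiplicity and offsets are reported. One UTR per
gene is required; callers with multiple transcripts should pre-select
(recommended: longest UTR).

## Enrichment statistic

DE classes use strict inequalities: DOWN iff FC < 0, |FC| > 1.3 and adj. p
< 0.002 (UP symmetric); a record at exactly the cutoff is UNCHANGED. Fold
changes follow the signed-magnitude convention (|FC| ≥ 1, minus = down);
ratio-style tables are auto-converted with a warning. Genes absent from
the table, or flagged undetected, are NOT_DETECTED and excluded from the
binomial's n.

The tail probability is the exact one-sided upper tail
P(X ≥ k_down | n_detected, p₀), summed in log space (log-gamma binomial
coefficients combined by log-sum-exp) so that tails near 10⁻¹⁶ and beyond
retain full relative accuracy; the suite verifies ≤ 10⁻¹² relative error
against exact rational summation for n ≤ 200 and cross-checks
`scipy.stats.binom.sf`. The null rate p₀ defaults to the fraction of
detected genes that are DOWN array-wide — the natural "by chance" rate for
this design — and can be overridden (`--null`). Degenerate cases: k = 0
returns 1; p₀ = 0 returns 0 for k > 0; p₀ = 1 returns 1. Windows are
ranked by tail probability with ties broken by larger k_down then smaller
window start. No multiple-testing correction is applied to the ranking
itself; a Bonferroni column over the K tested windows is emitted as
supplementary output.

Overlap analysis records per-gene window membership among the selected
windows' down-regulated targets; "exactly k windows" tiers partition that
union, and genes in ≥ 2 windows form the candidate-target set.

## Synthetic data

Generators are pure functions of an integer seed; each draws from
`numpy.random.default_rng([seed, stream])` with a fixed per-generator
stream id (annotation 11, reads 12, UTRs 13, DE 14), so outputs are
byte-identical across runs and platforms and the four generators never
perturb one another.

**Annotation.** Hairpins are mature5p + loop (10–20 nt) + mature3p
(matures 20–23 nt), random strand, placed left-to-right with ≥ 200 nt
between hairpin intervals. When `multi_locus_fraction` > 0, about a
quarter of loci are instead laid out as plus-strand *close pairs* with a
60-nt inter-hairpin gap — the geometry real clustered miRs present — so
that reads between them fall within 50 nt of both; with the default
`multi_locus_fraction = 0` all loci are ≥ 200 nt apart.

**Reads.** Each read draws a category from `category_mix`, then an
interval uniformly among placements entirely inside the corresponding
window of a uniformly chosen locus (lengths 18–26 clipped to the window);
background reads stay ≥ 100 nt from every hairpin. Multi-locus reads are
placed inside the left pair-member's 3p-moR window, which guarantees
exactly two candidate loci. The default mix (45/25/6/3% miR5p/miR3p/
moR5p/moR3p, 21% background) echoes a real small-RNA library: miRs
dominate, moRs are rare but quantifiable, and ~79% of reads are
region-assigned. By construction the classifier must reproduce the truth
label of every single-locus read exactly, which the suite asserts.

**UTRs and DE tables.** UTRs are i.i.d.-uniform DNA (default 2000 genes,
200–800 nt); a `plant_rate` fraction (default 3%) receive one exact seed
match written over 7 nt at a uniform offset (substitution rather than
insertion, keeping lengths config-driven). DE records draw |FC| from
(1.5, 4.0) and adj. p from (10⁻⁸, 10⁻³) for regulated genes, |FC| ≤ 1.25
and adj. p ≥ 0.01 for unchanged ones — ranges strictly inside/outside the
default cutoffs, so the thresholder recovers the intended class exactly.
Planted genes are DOWN with probability 0.5 versus 0.05 background, genes
are detected with probability 0.9; these defaults define the recovery
experiment (planted window ranked first in ≥ 95/100 seeded replicates)
and its null-calibration companion (tail ~ Uniform under equal down
rates, KS α = 0.01).

What the simulations do **not** model: sequencing error and quality
scores, isomiR end heterogeneity, hairpin thermodynamics, base-composition
bias in UTRs, and correlated expression noise. Passing recovery tests
therefore demonstrates correctness of the counting/scanning/testing
machinery under the stated generative assumptions, not performance on real
libraries.

## Problem sizes and determinism

Default test-time sizes — 10k reads × 20 loci for the pipeline-vs-oracle
equality, 100 + 200 replicates of 2000 genes for recovery and null
calibration — were chosen as the smallest scales at which the sampling
error bounds in the tests are meaningful. Hypothesis property tests run
derandomized; all simulation tests use fixed seeds.

## Known limitations

- The mature moR-21 sequence is represented by a synthetic placeholder
  constrained to its two known termini; analyses depending on its central
  bases (e.g. bulge-complementarity warnings) are illustrative only.
- Whether the original 50-nt locus rule measured distance to the hairpin
  or to the mature miRs, and whether it required same-strand mapping, is
  not documented; this package measures gap distance to the hairpin
  interval and requires strand agreement, both parameterized.
- The enrichment null p₀ is an estimate from the same table being tested;
  at very small detected-gene counts the tail is only approximately
  calibrated (visible as discreteness in the KS check).
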