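# Methods

This note documents the models, conventions and numerical choices behind
minisatkit, and what the synthetic-data tests do and do not establish
about real data.

## Sequence model

All sequence operations act on strict A/C/G/T strings; lowercase is
uppercased and ambiguity codes (including N) are rejected, because every
metric is an exact count with no sensible extension to ambiguous bases.
A minisatellite is a `NucleotideMotif` (the consensus unit, 10–100 nt,
given on its G-rich strand by convention) or a `TandemArray` (motif ×
copies, orientation G or C relative to the distal telomere; orientation C
is the reverse complement). Motifs outside 10–100 nt warn rather than
error, so the same code paths serve microsatellite-sized test fixtures.

## Composition metrics

GC content is (#G+#C)/L; GC bias is #G/(#G+#C) on the given strand;
the seed-dinucleotide bias counts overlapping TG/GG/GT on the given strand
versus CA/CC/AC (their reverse-complement images) and reports
forward/(forward+reverse). Counting is linear — no wraparound across the
tandem junction — which reproduces all published per-motif values;
junction dinucleotides are captured naturally when profiling a
concatenated array. Display rounding is nearest integer percent, ties away
from zero. Undefined biases (no G/C at all; no qualifying dinucleotide on
either strand) are NaN, never 0 or 0.5: a missing value and a balanced
value are different findings.

## G-quadruplex scanner

A hit is `n_tracts` (default 4) consecutive *maximal* G-runs of at least
`tract_min_g` (default 3) G, within `window_max` nt (default 30), all
inter-tract loops in [`loop_min`, `loop_max`]. `loop_max` is derived, not
set: with the other loops at their minimum,
`window_max − n_tracts·tract_min_g − (n_tracts−1)·loop_min + loop_min`
(= 16 at defaults). Three deliberate rules:

* **Maximal tracts.** `GGGGGG` is one tract of six, never two tracts of
  three (splitting would imply a 0-nt loop, which `loop_min = 1` forbids).
* **Minimal qualifying span.** The window test measures from the
  `tract_min_g`-long suffix of the first tract to the same-length prefix
  of the last, so an extended flanking G-run cannot disqualify an
  otherwise identical core motif.
* **Greedy non-overlap.** Hits are taken leftmost-first and scanning
  resumes strictly after a hit's last tract. Because candidate windows are
  consecutive-run sets, taking the leftmost candidate is the
  earliest-finishing-interval rule, which attains the maximum-cardinality
  disjoint selection; the test suite verifies this against a brute-force
  dynamic program on 500 random and tandem sequences up to 2 kb.

Counts are non-decreasing in `window_max` (candidate sets nest), asserted
as a property. Catalog annotation scans both strands per window
(30/40/50/100) and labels records G, C, GC or none; the genome study's
single-strand-label convention is under-determined for both-strand cases,
so both are reported. Coordinates are 0-based half-open internally,
1-based inclusive in TSV output.

## Fluctuation analysis

The Lea–Coulson median estimator solves r₀/m − ln m = 1.24 (r₀ = median
resistant count; midpoint of the central pair for even C) by bracketed
Brent root-finding on (1e-6, 1e6) at 1e-9 relative tolerance; the
left-hand side is strictly decreasing so the root is unique. The rate is
m/N_t with N_t a single per-experiment viable count (a per-culture vector
is averaged with a warning, matching the assay's design); a plating
fraction multiplies N_t. The 95% CI uses the Rosche–Foster dispersion
σ_ln m = 1.225·m^(−0.315)/√C with limits exp(ln m ± 1.96σ)/N_t — the
convention of the FALCOR calculator, adopted here as the field's default
since the estimator itself does not fix a CI. With zero mutants everywhere
the point estimate is 0 and only an upper bound is reported, taken from
the Poisson zero class across the C cultures (m_up = −ln 0.025/C); no
published convention exists for this degenerate case. Partial-plating
likelihood corrections and the MSS maximum-likelihood estimator are out of
scope.

The simulator draws the number of events per culture as Poisson(m = μN_t)
and each surviving clone's size as min(N_t, ⌊1/u⌋), u ~ U(0,1) — the
clone-size law under deterministic exponential growth — reproducing the
heavy-tailed "jackpot" distribution (variance ≫ mean). It omits phenotypic
lag, differential mutant fitness, and post-plating growth; recovery tests
therefore validate the estimator under its own model assumptions, not
against those biological complications.

## Hypothesis tests

Fisher's exact test is hand-written: hypergeometric point probabilities in
log-gamma space, two-sided p as the sum of all tables (fixed margins)
whose point probability is ≤ the observed one with a 1+1e-7 floating-point
guard, compensated summation via `fsum`. This is the point-probability
rule of standard statistical software; it reproduces the published
rearrangement-frequency p-values (8.8e-10, 3.55e-3) to within their
printed rounding, which the doubling-one-tail rule does not. Tests verify
it against an exact-rational enumeration and against scipy.

Mann–Whitney uses the exact null when both groups have n ≤ 8 and no ties,
otherwise the tie-corrected normal approximation (scipy backend). Spearman
uses average ranks; for n ≤ 9 the p-value enumerates all n! pairings of
one rank vector (vectorized), beyond that the t approximation. Constant
input makes ρ undefined and is flagged as NaN, not coerced.

The enrichment test treats the catalog itself as the trial population:
χ² with 1 df against the split (f·total, (1−f)·total), no continuity
correction; one-tailed p is half the two-tailed p when observed exceeds
expected, 1 minus half otherwise (0.5 at exact equality). A log₁₀ p is
carried alongside for the regimes where the survival function underflows.

**Calibration design.** Without continuity correction the rule is slightly
anticonservative, and with a discrete binomial count its exact size
depends on the catalog size: at 400 records and f = 0.10 the exact type-I
error is 0.0601, at 500 records 0.0465. Calibration replicates therefore
use 500-record catalogs, where the rule's true size is below the nominal
5%, and 2000 replicates so the Monte-Carlo error of the measured rejection
rate is small against the acceptance band. The exact attainable level of
the n = 8 Spearman permutation test (0.0458) is likewise computed
analytically from the enumerated null rather than estimated.

## Junction analysis

The yeast telomeric repeat is irregular; the minimal grammar adopted is
one or more repeats of T·G^k, k ∈ {1,2,3}, on the G-rich strand, with
partial leading/trailing repeats permitted. This makes the parsing
relation suffix-closed (any suffix of a telomeric string is telomeric),
which the junction parser exploits: the junction is the end of the maximal
motif-templated prefix (maximized over motif phases; ties resolve to the
rightmost motif-templated position), the suffix must parse under the
grammar, and the shared span walks left from the junction while bases both
match the motif template and leave a telomere-parsing suffix. Up to
`max_snvs` mismatches (default 0) are tolerated in the prefix, recorded as
SNVs within a 30-nt pre-junction window; a mismatch terminates the shared
span. Short prefixes can be phase-ambiguous — a different phase of the
motif may parse at least as far as the generating one — so generator
round-trip tests require ≥ 99% exact recovery and independently verify
that every failure is such an ambiguity.

The CEB1 G-quadruplex block used for the seed-overlap statistic is motif
nt 1–17 (the 5' G-rich block GGGGGGAGGGAGGGTGG), a configuration value:
it is the unique contiguous region consistent with the published 60%
seed-overlap figure, but is not printed as coordinates anywhere, so it
must remain overridable. Residual-motif estimation inverts
(fragment − flank − mean telomere)/motif length with defaults flank 50 bp,
telomere 300 bp (wild type) or 400 bp (pif1Δ); negative remainders clamp
to 0 with a warning. Cdc13 sites are searched on the given strand only,
either as the exact 11-mer GTGTGGGTGTG or as the critical GTGT prefix
opening an 11-nt window with ≥ 9 bases in {T,G} — the relaxed mode exists
because tandem context and near-consensus sites are known to bind but no
published criterion defines them.

## Catalog geometry

Arms are 1-based inclusive intervals with a declared centromeric side;
the normalized position of a record's midpoint is
|midpoint − centromeric end| / (arm length − 1), 0 at the centromere and
1 at the telomere. Records outside every annotated arm (centromere gaps,
unannotated acrocentric p-arms) are excluded with a logged count. GC-rich
means strictly > 50%. Records straddling the terminal-fraction boundary
are assigned by midpoint. Duplicate removal collapses same-chromosome,
same-motif-size overlapping records to the longest array (leftmost on
ties) — one defensible reading of "overlapping duplicates", isolated
behind a single function and verified idempotent.

## Synthetic data

Each generator derives an independent RNG stream from (seed, generator
name), so outputs are byte-identical under a fixed seed and adding a
generator never shifts another's stream. The catalog generator places
records along arms with density ∝ 1 + βx in normalized position — linear
because its terminal-fraction integral is closed-form,
(f + β(1−(1−f)²)/2)/(1+β/2), giving analytic recovery targets; the real
genome's bias shape is unknown and nothing downstream depends on this
choice. GC content is a two-component truncated-normal mixture (poor mean
35%, rich mean 60%, rich weight 25%) kept consistent with the >50%
classification; GC-rich records draw Poisson(2) G4 counts, GC-poor none,
and an optional coupling term adds β per G4 hit so stratification tests
have a known monotone signal. Arrays apply i.i.d. point mutations at a
configurable per-base rate; junction reads concatenate an array prefix
with a grammar-generated telomere of normal-distributed length (default
sd 75 bp around the model mean). None of the generators emulate real
base-composition heterogeneity, sequencing error, or TRF scoring — so
passing tests demonstrate internal correctness and statistical
calibration, not robustness to those real-data features.

## Problem sizes

The default test and acceptance runs use: 500 sequences ≤ 2 kb for the
scanner oracle; 200 simulated assays of 50 cultures (plus one 10,000-culture
run for the zero class) for estimator recovery; 2000 catalogs of 500
records for enrichment calibration and one 20,000-record catalog for bias
recovery; 1,000 junction reads for round-trip recovery. These sizes put
Monte-Carlo error comfortably inside each asserted tolerance while keeping
the full suite around ten seconds.

## Known limitations

Genome-scale catalog counts cannot be recomputed without the reference
genome and the original tandem-repeat-finder run; only the file formats
and the operations on catalogs are testable here. The Fisher
implementation enumerates the full support and is intended for the
table sizes of colony assays (margins up to a few thousand), not for
genome-scale contingency tables. The junction parser assumes reads begin
inside the array; adapter or flanking sequence must be trimmed upstream.
The scanner predicts sequence potential only — no thermodynamic scoring or
structure prediction.
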