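# Methods

This note documents the models, parameter choices and numerical
conventions behind `sporescan`, and what the synthetic data can and
cannot establish about real hybrid-spore aCGH.

## The measurement model

A dual-species panel tiles all 16 collinear chromosome pairs of the two
parental species with species-specific probes at ~2 kb spacing
(configurable; positions are jittered ±25% of the spacing by default so
segment probe counts vary as on a real array). A spore's probe reads a
log10 ratio drawn from Normal(μ_present, σ) when the probed locus is
inherited from that probe's species — or the chromosome is aneuploid —
and Normal(μ_absent, σ) otherwise. Defaults:

| parameter | default | rationale |
|---|---|---|
| μ_present | 0.30 | log10 of a 2:1 test:reference ratio under an equimolar two-species reference |
| μ_absent | −1.0 | residual cross-hybridization well below threshold |
| σ (noise_sd) | 0.15 | puts the −0.05 decision threshold ≈2.3σ from the present mode (≈1% one-sided flip rate) and ≈6σ from the absent mode |

The noise is i.i.d. Gaussian per probe. Real arrays have spatially
correlated noise, dye bias, GC-dependent intensity and probe-specific
affinities; none of that is simulated, so passing tests demonstrate the
*procedure's* correctness and calibration, not robustness to structured
artifacts.

## Hybrid meiosis

Per gamete and chromosome, the crossover count is Poisson with mean
proportional to chromosome length, normalized so the genome-wide mean
equals `crossover_mean_per_genome`; positions are uniform; the starting
parent is a fair coin and parental origin alternates across crossovers.
No obligate crossover and no interference are imposed — hybrid meioses
show many chromosomes with zero events, and the per-chromosome
distribution is not otherwise constrained by published data (this is the
package's assumption, not an established fact). Whole-chromosome
nondisjunction is modeled as disomy across species (the spore keeps both
homeologs) with a per-chromosome probability; segmental aneuploidy is
not simulated, matching how aneuploidy is scored (chromosome scope
only).

Two named regimes reproduce the published cohorts' averages: wild type
(58 spores, 2.66 crossovers and 2.29 aneuploidies per spore) and
mismatch-repair deficient (48 spores, 17.83 and 0.29).

Planted incompatibilities are lists of (chromosome, position) loci with
one or more lethal joint-origin patterns and a penetrance; an aneuploid
locus carries both origins and satisfies either requirement. Cohorts are
assembled by rejection sampling of gametes (attempt cap 10^6, default);
all randomness flows from a single seed via `numpy` `SeedSequence`
spawning, making outputs bit-identical given (params, specs, seed).

## Genotype calling

* Binarization: 0 below −0.05, 1 at or above it. The boundary value is
  called present by convention (the two strict inequalities of the
  historical rule leave it undefined).
* Whole-chromosome absence: fraction of 0-calls ≥ 0.80.
* Region detection: the declarative rule — regions of ≥10 probes with
  >70% one value — is instantiated deterministically as follows. A
  10-probe window slides at stride 1; a window is committed to a value
  when that value exceeds the purity fraction. Committed windows of one
  value (including same-value windows separated only by uncommitted
  ones) merge into runs, so any pure stretch of ≥10 probes is detected
  regardless of its offset — a disjoint-block variant was rejected
  because detection then depended on block alignment. Each border
  between opposite-value runs is placed inside the uncommitted zone
  between them at the cut minimizing disagreement with the flanking
  majorities (ties → middle cut, rounded left). On a clean step this is
  the exact step location; re-running the detector on its own
  reconstruction reproduces the regions.
* Breakpoints are inter-probe boundary indices (0-based, half-open
  regions); reported bp coordinates are the midpoint between the
  flanking probes.
* Aneuploidy: a chromosome is aneuploid iff neither species' copy is
  absent and both have presence fraction ≥ 0.80. Sub-chromosomal double
  presence (cer + par presence fractions > 1.2 without the full call)
  logs a warning and is not called.

Resolution limits follow from the rule itself: a crossover within ~10
probes of a telomere, or two crossovers within ~10 probes of each other,
produces a region too small to commit and goes uncalled; a chromosome
with <20% minority material has its minority track silenced by the
absence rule. Called crossover counts therefore run below truth for
cohorts with many telomere-proximal events; the planted-recovery tests
quantify fidelity on detectable (interior, well-separated) events, where
recovery is exact without noise and within ±5 probes in ≥95% of cases at
default noise.

## Segmentation and scoring

Breakpoints are pooled per (genome, chromosome) across all spores;
pooled locations closer than one probe spacing (default 2 kb) merge to
their cluster midpoint — near-identical locations from different spores
are the same event seen at probe resolution. Each genome is segmented
independently (as in the original analysis, whose two genomes yielded
slightly different segment counts). Segment scores are the majority of
the spore's binarized probe calls inside the segment; an exact tie is
recorded as missing and excluded pairwise downstream rather than
imputed. Aneuploid chromosomes score 2 for all their segments in both
genomes' matrices.

## Pairwise scan

Spores scoring 2 or missing at either segment are excluded from all four
cells, and the marginals nA, nB, N are computed over the remaining
informative spores (a flag allows normalizing by the cohort total
instead, reproducing analyses that kept the full denominator). Cells
with zero expectation contribute zero when the observation is also zero;
an observation against a zero expectation yields an infinite statistic.
The 3-df p-value follows the historical convention; the 1-df p-value
(appropriate for marginal-conditioned tables) is reported alongside, and
the FDR ranks by the statistic itself, so the df choice does not affect
significance calls. "Greater than x" is implemented as ≥ x in both the
numerator and denominator of the FDR for estimator stability. The
permutation null shuffles every segment's score vector independently
across spores, preserving each segment's marginal multiset; this also
destroys intrachromosomal structure, which is acceptable because the FDR
is applied to interchromosomal pairs. Pair order is lexicographic by
(chromosome, start) of both segments. An intrachromosomal distance scan
reports per-pair midpoint distance versus statistic and the minimum
unlinked distance (the smallest observed distance beyond the most
distant pair with FDR below threshold) — the linkage horizon inside
which dependencies cannot be distinguished from physical linkage.

## Three-locus scan

Triples are restricted to three distinct chromosomes by default,
consistent with the interchromosomal rationale of the pairwise scan
(flag to disable). The inner loop runs on per-segment spore bitmasks
(Python big integers, one presence and one informative bit per spore),
so full enumeration covers millions of triples in seconds; beyond
`max_triples` (default 10^7) a seeded uniform sample is scored and the
count reported as a rate with a Clopper–Pearson interval. No per-triple
significance is attached — at realistic cohort sizes empty categories
arise by chance (for 8 equal cells the empty-cell probability at n = 106
is ≈5×10⁻⁶ per triple but the number of triples is large, and real
segments are far from equal-cell) — only the cohort-level excess over
the permutation baseline is reported.

## Bias tests

Transmission bias uses only spores that are non-aneuploid, breakpoint-free
on both species' tracks, and unambiguous (exactly one species' copy
absent) for the chromosome. Exact binomial tails (scipy's regularized
incomplete beta, verified against big-integer summation to 12
significant digits for n ≤ 200) are authoritative; the
continuity-uncorrected normal approximation is reported alongside
because the historically printed p-value for the 30-vs-9 chromosome-4
count (0.0004) matches it, while the exact tail is 5.3×10⁻⁴. The
aneuploidy-deficit null allocates the cohort's T events uniformly
(p = 1/16 per chromosome); a length-weighted null is available behind a
flag. Both published tallies of the chromosome-4 event count (0 on one
species' array, 1 on the other) are computed and reported; with T = 133
events the Bonferroni-corrected tails are 0.0030 and 0.0295.

## Problem sizes used in tests and the acceptance script

The simulation experiments run on a reduced study genome — 8 chromosomes
totalling ~2.2 Mb, probes every ~4 kb, cohorts of 100–150 viable spores,
crossover means 0.6–1.0 per gamete so the pooled segmentation stays
under 150 segments — with 200 permutations and 20 seeds. These sizes
keep planted-pair recovery, null calibration and the triple scan fast
while preserving the statistical regime of the full-size analysis
(segment counts per chromosome, informative-spore numbers and the FDR
granularity scale together). The full-size genome (16 chromosomes,
~12 Mb, 2 kb spacing) is the library default.

## Known limitations

* Dataset-derived figures of the original study (segment totals, pair
  and triple counts, the ~180 kb linkage horizon, specific chromosome
  pairs) depend on its deposited raw data and are not reproduced;
  the constructions that produce them are covered by property-based
  tests instead.
* The nine-category (aneuploidy-inclusive) pairwise tally is exposed as
  a descriptive table only; no test is attached, as the category count
  outstrips the information in cohorts of this size.
* Mismatch-repair biology is parameterized phenomenologically (two
  regimes), not modeled; mitochondrial genotypes and mating preference
  are out of scope.
* The FDR estimator is a ratio of exceedance counts and is reported
  above 1 unclipped (clipped only for display); it is undefined at
  statistics no observed pair reaches.
* Segment quantization blurs dependency classes: a viable spore whose
  crossover falls inside a locus-containing segment, with the locus on
  the minority side of the cut, votes into a mixed cell. Even a fully
  penetrant planted two-way pair is then read as one_way (with an
  essentially unchanged statistic and FDR). The expected number of such
  straddling spores is roughly invariant to cohort size and
  recombination rate, so a planted pair's strict two_way classification
  succeeds in ~90–95% of simulated cohorts rather than always; the pair
  remains top-ranked at FDR < 0.01 regardless. The same effect applies
  to real data: an empty-cell criterion is conservative at segment
  resolution.
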