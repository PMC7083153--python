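# Methods

This note describes the statistical procedures implemented in
`ldscape`, the assumptions behind them, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Genotype model and quality control

Genotypes are unphased diploid alt-allele dosages in {0, 1, 2} with a
missing code; half-calls (`./1`) are treated as missing because their
dosage is undefined.  Coordinates are 1-based and inclusive throughout
(VCF convention); every internal distance is a difference of positions
in bp.  The only 0-based conversion in the package happens in the
optional BED export of ROH segments.

The QC chain runs in a fixed order: INFO-annotation hard filters
(variants removed when QD < 2, MQ < 40, FS > 60, MQRankSum < −12.5 or
ReadPosRankSum < −8; a matrix without annotations passes unchanged),
then sample call-rate filtering (default minimum 0.50 — reduced-
representation libraries can fail outright, producing samples with few
or no reads), then variant filters: MAF strictly greater than 0.05 and
call rate at least 0.85.  Allele frequencies are computed after sample
removal so they describe the analysed cohort.  The chain is idempotent,
and retained counts are monotone in every threshold.  A separate
scaffold filter (≥ 50 SNPs and length > 10 Mb) applies only to the
LD/Ne stages: short scaffolds cannot contribute the long-range pairs
those stages need, while ROH and F_HOM use the full filtered SNP set.

## Two-locus haplotype frequencies (EM)

r² and D′ are defined on haplotype frequencies, which unphased
genotypes do not expose directly.  Under Hardy–Weinberg random mating
the only phase-ambiguous individuals at a biallelic pair are double
heterozygotes, so maximum-likelihood frequencies follow from a small EM
iteration: given current frequencies, each double heterozygote
contributes cis (AB/ab) with probability
`P_AB·P_ab / (P_AB·P_ab + P_Ab·P_aB)`, and the weighted haplotype
counts are renormalised.  Iteration stops when the largest frequency
change falls below 1e-10 (at most 1000 sweeps).  Initialisation is at
linkage equilibrium plus a 1e-8 tilt toward cis: the exact LE point is
a stationary saddle of the likelihood for perfectly symmetric data
(for example, every individual doubly heterozygous), and without the
tilt EM would return the saddle instead of a maximum-likelihood
solution — for such symmetric data the maximum is not unique (both
complete-LD phases tie), and the tilt selects one of them.  Pairs are
computed on pairwise-complete individuals; a pair is "undefined" (and
excluded from summaries, with a logged count) when a locus is
monomorphic among those individuals or fewer than two remain.

The EM is vectorised over batches of pairs (3×3 genotype-count tables),
which keeps genome-wide decay scans in plain numpy.  A composite
genotypic correlation (Rogers–Huff style), which needs no random-mating
assumption, is available as `estimator="composite"`.

Summary tables (adjacent-pair, all-pair and decay) report the mean of
|D′|: D′ is signed per pair, but its sign depends only on the arbitrary
ref/alt labelling, so the signed mean is ≈ 0 by construction and the
magnitude is the conventional summary.  r² is label-invariant.

Decay tables use half-open bins (lower, upper]: a pair at exactly
10 kb falls in the first 10-kb bin.  Three canonical schemes are
emitted (100 kb / 10 kb, 1 Mb / 100 kb, 10 Mb / 1 Mb), with per-bin
pair counts and mean ± SD of r² and |D′| pooled over scaffolds.  The
panel-density helper divides a genome size by the lower edge of the
first bin whose mean r² drops below a threshold (the "beyond d kb"
convention), e.g. 2.4 Gb / 40 kb = 60,000 markers.

## Effective population size from LD

The Sved relationship links equilibrium LD at recombination fraction
`c` to effective size: `E[r²] ≈ 1/(α + 4·Ne·c) + 1/(2n)`, where `α` is
1 (no mutation correction) or 2 and `1/(2n)` is the inflation from
estimating r² in `n` diploids.  LD at `c` reflects the population
roughly `t = 1/(2c)` generations ago, so each target generation maps to
a window of physical distances through a uniform genetic map (default
1 cM/Mb — no linkage map exists for most species this package targets;
the value is configurable).  Pairs whose `c` lies within ±20% of
`1/(2t)` are pooled across scaffolds (the relative window keeps bin
occupancy stable on sparse panels), the sample correction is
subtracted, and

```
Ne(t) = (1 / (4·c̄)) · (1 / mean_r²_adj − α)
```

with `c̄` the mean `c` of the pooled pairs.  Estimates with
non-positive adjusted r² are flagged unavailable; windows with fewer
than 10 pairs are flagged low-confidence.  The present-day value comes
from an ordinary least-squares fit of log(Ne) on log(t) evaluated at
t = 1 — a deliberately simple, monotone extrapolation whose
coefficients are reported alongside the value.

Two caveats matter when interpreting the trajectory.  First, the Sved
form is an approximation; at small `4·Ne·c` diffusion theory
(Ohta–Kimura) gives `E[r²]` closer to `1/(2 + 4·Ne·c)`, so `α` shifts
the deeper-time estimates systematically and the trajectory's *shape*
is more trustworthy than its level.  Second, allele-frequency
ascertainment matters: rare variants are young and carry little
long-range LD, so a panel with many low-MAF markers depresses mean r²
at small `c` and inflates ancient Ne.  The package's own validation
therefore runs on common-variant panels (see below), and trajectories
from MAF-skewed panels should be read as upper bounds at large `t`.

## Runs of homozygosity and inbreeding

The scanner slides a 20-SNP window one SNP at a time along each sample
and contig.  A window is homozygous-compatible when its heterozygote
count is at most `floor(error_rate × 20)` (0 at the default 1% error
rate) and its missing fraction at most 5%.  Maximal unions of
overlapping compatible windows become candidate runs; a run is emitted
when its physical span reaches the smallest length class (default
500 kb) and its total heterozygote count stays within
`floor(error_rate × n_snps)` — the same allowance logic applied at run
scale.  Coordinates span the first to last SNP of the run: lengths are
marker-supported and conservative, with no extension into flanking
unmarked sequence.  With a zero error rate and no missingness the
scanner reduces exactly to a maximal-homozygous-stretch search, which
is how it is tested.

Per individual, `F_ROH(≥L)` is the summed length of that individual's
segments at or above L divided by the marker-covered genome length
(per-contig first-to-last-SNP spans summed; configurable to an external
value such as an assembly-based 1.75 Gb).  `F_ROH` is exactly
non-increasing in L for every individual.  `F_HOM` is the
method-of-moments excess-homozygosity coefficient

```
F_HOM = (O_hom − E_hom) / (m − E_hom),
E_hom = Σ_i [1 − 2·p_i·(1 − p_i) · 2n_i/(2n_i − 1)]
```

over the individual's non-missing variants (cohort alt frequency `p_i`,
genotyped count `n_i`; variants with `n_i < 2` excluded).  The
small-sample factor makes the expectation unbiased at finite cohort
size; the coefficient is negative for individuals with an excess of
heterozygotes.  Class summaries report per-individual counts, mean
lengths, the cumulative share of segments per class, and the Pearson
correlation of `F_ROH(≥L)` with `F_HOM` per class.

## The synthetic-data generator

`simulate_population` is a forward Wright–Fisher simulation of `2·Ne`
haploid genomes: every generation each gamete draws a random parent and
recombines its two haplotypes with Poisson crossovers (default 1e-8
per bp ≈ 1 cM/Mb), and sites mutate recurrently and symmetrically at a
scaled rate `site_theta = 4·Ne·μ = 0.2` per candidate site.  The
mutation term is essential: without an input of new variation, drift
over the 4·Ne-generation burn-in fixes the large majority of sites and
the survivors' frequency spectrum is dictated by drift alone, so
neither the configured density nor the configured spectrum could be
honoured.  With it, the burn-in (at the oldest epoch size) reaches a
genuine mutation–drift–recombination equilibrium before the configured
Ne trajectory plays forward to the present.

Candidate sites are oversampled fourfold; at sampling time the sites
segregating in the drawn cohort form a pool whose minor-allele
frequencies are matched against draws from the target spectrum (an
L-shaped `0.5·Beta(a,1)` law whose mean is exactly the configured
`target_maf_mean`) by monotone nearest-rank assignment.  This
reproduces the ascertainment a genotyping pipeline applies and hits the
configured mean MAF to within ±0.03 at the defaults, while LD — the
object of study — arises mechanically from drift and recombination and
follows finite-population expectations.  Missingness and symmetric
hom↔het genotype error are applied last, with masks recorded in the
truth set.  All randomness flows through one integer-seeded generator;
a fixed seed reproduces the output byte-for-byte.

Defaults emulate a GBS panel on a draft mustelid assembly: 260
diploids, the bundled 46-scaffold panel (719.22 Mb), ~18.5 SNPs/Mb,
mean MAF 0.185, a population declining from Ne ≈ 1000 at 200
generations ago to ≈ 116 at 5, 5% missingness and 0.5% genotype error.
Validation experiments use smaller purpose-built configurations, noted
below.

What the generator does *not* emulate: sequencing depth and
allele-specific dropout (missingness is uniform), linked selection,
migration and population structure, gene conversion, variable
recombination along the genome, and reference/assembly artefacts.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated population model, not robustness to every
property of real GBS data.

`implant_roh` copies a sample's first haplotype over its second inside
given tracts, making the tract exactly autozygous before any noise;
`make_ld_fixture` draws genotype pairs from an exact two-locus
haplotype law (or deterministic rounded counts with like-with-like
pairing in `exact` mode, which leaves phase unambiguous);
`simulate_hwe_cohort` produces i.i.d. Hardy–Weinberg cohorts, with
haplotypes on request so tracts can be implanted into a known-outbred
background.

## Validation experiment design

The recovery experiments (in `tests/` and `scripts/acceptance.py`) fix
their conditions as follows, for reasons recorded here once:

- **Ne recovery** (constant Ne = 100, 50 diploids, 20 replicate 12-Mb
  chromosomes, targets t = 10 and 50; and a two-epoch 1000 → 100 crash
  at 50 generations ago probed at t = 200 vs t = 5): panels use common
  variants (target MAF 0.4) and the standard MAF > 0.05 filter.  With
  an L-shaped spectrum the rare-variant ascertainment depresses
  long-range mean r² well below any `1/(α + 4·Ne·c)` curve, which is a
  property of the panel, not of the estimator being validated; with
  common variants the observed decay matches the α = 1 Sved curve
  closely and the inversion recovers the truth within ±30% at the
  stated sizes.
- **ROH recovery** (20 replicates of 20-sample cohorts, markers every
  50 kb, tracts of 1.2–4 Mb implanted in half the cohort): detected
  boundaries are compared against the tract's *homozygous closure* —
  the tract extended over flanking markers that are homozygous by
  chance — since no detector can distinguish chance homozygosity
  abutting a tract from the tract itself.  Backgrounds use common
  variants (MAF 0.35–0.5): per-site homozygosity near one half makes a
  ≥ 1 Mb chance run (≥ 21 consecutive homozygous markers) vanishingly
  rare, so "no false segments" is a meaningful assertion, whereas with
  a rare-allele-heavy spectrum chance runs are expected by arithmetic
  (per-site homozygosity ≈ 0.74 gives ~2·10⁻³ per window) — a real
  property of low-information markers worth knowing when interpreting
  ROH from GBS panels.
- **F_HOM calibration**: a 500 × 5,000 i.i.d. Hardy–Weinberg cohort
  must centre F_HOM at 0 within ±0.01, and a fully homozygous
  individual scores exactly 1.

## Numerical conventions and degenerate inputs

- EM tolerance 1e-10, cap 1000 iterations; batch pairs converge
  independently.
- Undefined-LD pairs (monomorphic in the pairwise-complete subset,
  `Dmax = 0`, or a zero allele frequency) are excluded from all means
  and counted in logs, never silently zeroed.
- Ne estimates are rounded to whole individuals; `c` is capped at 0.5.
- Empty decay bins keep their row with a zero pair count and missing
  means; header-only TSVs are valid outputs for empty results.
- Floats in TSV outputs carry 6 significant digits; re-reading a
  written table reproduces values to that precision.
- Scaffolds with fewer SNPs than one ROH window, or fewer than two
  SNPs for LD, are skipped with warnings rather than errors.

## Known limitations

- The Sved inversion gives point estimates only; replicate spread in
  simulations is the only uncertainty measure provided.
- The uniform cM/Mb map ignores recombination heterogeneity; Ne levels
  scale inversely with the assumed map density.
- ROH lengths are marker-supported; sparse panels underestimate tract
  lengths, and scaffold-level assemblies truncate long tracts at
  scaffold boundaries.
- F_HOM uses cohort allele frequencies and is therefore relative to
  the sampled population, not to an external base population.
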