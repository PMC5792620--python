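# Methods

`museum-popgen` implements a temporal population-genomics analysis for
SNP matrices obtained from degraded (museum) and fresh specimens, e.g. by
hybridization capture of RAD-derived probes (hyRAD). It begins at a
multi-sample VCF with per-genotype depths and ends at three products: a
filtered genotype matrix, per-population diversity statistics with
resampling inference, and a scored set of population-decline scenarios.
This note records the models, estimators, defaults and the design choices
made where more than one defensible option existed.

## Data model

A `GenotypeMatrix` holds diploid calls as counts of non-reference copies
(0/1/2, −1 missing) with per-call read depth (DP) and per-site Phred
quality (QUAL, stored rounded to one decimal so a matrix round-trips
bit-identically through uncompressed VCF 4.2 via pysam). Missing calls
carry DP 0. The population map assigns each sample a population label,
location and collection year; when labels are absent they are derived by
grouping samples from the same location whose collection years fall
within less than 10 years of each other (greedy clustering of sorted
years), the convention used for temporal series of museum material.
Samples from groups below the minimum size (default 4) stay in
individual-level analyses but are excluded from population-level ones.

## Filter cascade

Eight site stages run in a fixed order, then one sample pass:

1. QUAL < 30 removed;
2. indels removed;
3. only biallelic SNPs kept;
4. calls with DP < 6 set to missing (depth is a per-genotype property, so
   masking precedes all site-level missingness accounting);
5. sites missing in > 50% of samples removed;
6. sites with minor allele count < 6 removed, counting gene copies over
   all non-missing diploid calls; a tie at exactly 6 is kept;
7. sites with QUAL < 0.25 × site total DP removed (high depth inflates
   QUAL; a low QUAL/DP ratio flags artefacts). Site *total* DP is the
   default statistic; mean per-call DP is available by configuration;
8. putative paralogs removed: sites whose mean per-genotyped-sample depth
   exceeds the across-site mean by more than 3 SD. The cut is iterated to
   convergence rather than applied once: a single cut leaves a truncated
   depth distribution whose own mean + 3 SD can flag additional sites, so
   one-shot filtering is not idempotent, and idempotence of the cascade
   is a property we commit to (re-filtering a filtered VCF is a no-op).

Stage counts telescope exactly (each site is removed at exactly one
stage), and the order is frozen by a regression test: swapping stages 4
and 6 changes results whenever a minor-allele carrier sits on a low-depth
call.

Samples missing at > 80% of retained sites are then dropped, in a single
pass. For population-level statistics a further within-population filter
retains a SNP only if its missing fraction is ≤ 70% (strict inequality
drops) in *every* analysis population; requiring the bound in at least
one population instead is a configuration switch (`within_pop_mode`).

## Diversity statistics

All averages weight loci equally; loci with fewer than two genotyped
individuals in a population are skipped for that population.

* **Observed heterozygosity** — per individual: heterozygous calls /
  non-missing calls; per population: per-locus heterozygote fraction
  averaged over loci (not pooled over genotypes).
* **Gene diversity (expected heterozygosity)** — the small-sample
  estimator `Hs = ñ/(ñ−1) · (1 − Σp̂² − Ho/(2ñ))` with ñ genotyped
  individuals, p̂ the sample allele frequencies and Ho the observed
  heterozygote fraction. This is the estimator used by the standard
  hierarchical-F-statistics packages; the uncorrected `1 − Σp̂²` is easy
  to obtain from the per-locus output if wanted.
* **Rarefied allelic richness** — `A_r = Σ_i [1 − C(N−N_i, g)/C(N, g)]`
  for N genotyped gene copies with allele counts N_i, evaluated in exact
  integer arithmetic (`fractions.Fraction`); a monomorphic-in-sample
  locus contributes exactly 1. The rarefaction size g defaults to the
  smallest genotyped copy count over all population × locus cells with at
  least one genotyped individual (rarefaction to the smallest sample); a
  per-locus-minimum variant (`g="per-locus"`) rarefies each locus to its
  own smallest per-population count. A float (log-gamma) evaluation of
  the same formula is used inside permutation loops for speed; the two
  agree to numerical precision.
* **Private alleles** — raw presence/absence counts over loci genotyped
  in both populations, reported with the private allele's frequency in
  its own population. Raw counting is the default because integer counts
  are what temporal comparisons of this kind report; a rarefied
  expectation (P(present in g copies of A) × P(absent in g copies of B),
  summed) is available via `rarefaction_g` for size-standardized
  comparisons.
* **Weir–Cockerham θ (F_ST)** — per-locus variance components a (among
  populations), b (among individuals within populations), c (within
  individuals) for two populations of unequal size, combined as
  `θ = Σa / Σ(a+b+c)` over loci with a non-zero denominator. Negative
  estimates are reported as-is; clamping at zero discards information
  about sampling noise near zero differentiation. The test suite checks
  the components against an independently coded ANOVA (sums-of-squares)
  derivation to 1e-12.
* **MAF spectra** — per-locus alternate-allele frequency among
  non-missing calls, folded to [0, 0.5].

## Resampling inference

All Monte-Carlo p-values use +1 smoothing, `p = (count+1)/(B+1)`, and are
bit-reproducible given (seed, B).

* **Permutation tests** (default B = 10,000) are two-sided on the mean
  difference. For statistics that are not per-individual values (gene
  diversity, allelic richness, θ), individuals are permuted between the
  two populations and the per-population statistic recomputed, preserving
  within-individual dependence; per-locus values are never shuffled. An
  exact-enumeration mode covers small samples.
* **Hardy–Weinberg exact tests** are Monte-Carlo: the observed gene
  copies are reshuffled into diploids B times (default 1,000) and a
  resample counts as at least as extreme when its Levene conditional
  probability does not exceed the observed configuration's
  (exact-test convention; a heterozygote-count distance criterion is a
  switch). The screen runs only in populations with n > 7 — smaller
  samples cannot detect HWE deviation — and loci with Storey q < 0.05 in
  any screened population are excluded from downstream analyses.
* **Multiplicity**: Benjamini–Hochberg step-up for pairwise tests and
  scenario batches; Storey q-values (π̂₀ from the p > λ tail, λ = 0.5 by
  default, polynomial smoothing over a λ grid when one is supplied) for
  the HWE screen.
* **Mann–Whitney U** compares individual observed heterozygosity between
  historical (year < 1955, configurable) and contemporary samples, with
  midranks for ties; W is the first group's U statistic (the R
  `wilcox.test` convention — half-integer W signals midranks in play).
* **Bootstrapped Kolmogorov–Smirnov**: the classical two-sample sup-CDF
  distance D (both ECDFs evaluated on the pooled support, ties allowed),
  with the null distribution of D built by resampling both sample sizes
  with replacement from the pooled sample (default 1,000 draws). The
  bootstrap exists because folded MAF spectra live on a small lattice
  with heavy ties, where the asymptotic KS null is invalid. The bootstrap
  null is itself an approximation: its rejection rate at nominal 0.05 is
  calibrated (band checks in the test suite) but the full p distribution
  under the null is only approximately uniform, which is why the
  meta-level uniformity test runs at a modest replicate count.

## Decline scenarios

A scenario declines from N0 to Nf diploids over T = 10 generations
(generation time one year) in one of three families: linear,
constant-rate exponential `N_t = N0 (Nf/N0)^{t/T}`, and a curved
exponential `N_t = N0 + (Nf−N0)(e^{st/T}−1)/(e^s−1)` whose shape s sets
slow-then-fast (s > 0) or fast-then-slow (s < 0) decline. Sizes are
rounded, clamped at ≥ 2, and hit Nf exactly at t = T. The shipped default
grid (5 initial sizes × 2 final sizes × 3 families = 30 scenarios) is a
plausible stand-in spanning mild to severe bottlenecks; scenario sets are
configuration data (YAML), not constants of the method.

The early population's observed MAFs are treated as true initial
frequencies (optionally re-drawn per scenario from the early sample's
binomial uncertainty, `bootstrap_start_n`). Each locus drifts
independently, `p_t ~ Binomial(2N_t, p_{t−1})/(2N_t)`, absorption
allowed; one Wright–Fisher replicate per scenario produces the single
simulated distribution that is compared — after folding, and by default
after binomial resampling down to the later sample's size — with the
observed later MAFs by the bootstrapped KS test, and the scenario batch
is BH-adjusted.

Two points about that comparison, both verified by the test suite:
sampling the simulated distribution down to the later sample's size keeps
the two ECDFs commensurate (comparing a population-level frequency vector
against a tiny empirical sample inflates D for every scenario, true one
included); and at a later sample of n = 7 the binomial lattice noise
(SD ≈ √(p(1−p)/14)) is of the same order as ten generations of severe
drift, so scenario discrimination through such a sample is intrinsically
weak. The self-consistency calibration therefore runs on frequency
vectors (`resample_to_n_late=False`): there the generating scenario is
retained and a severe alternative (1000 → 10) rejected in essentially all
replicates at 328 loci.

## Synthetic data

The generator emulates what variant calling returns from capture data on
museum material, at the call level (read-level simulation, capture bias
and postmortem damage profiles are out of scope):

* founder allele frequencies Beta(0.5, 0.5) (mass on rare alleles, the
  informative regime for richness statistics), drifted through an
  explicit diploid size history by the same Wright–Fisher engine the
  decline module uses (one shared code path);
* Hardy–Weinberg genotype draws per individual at each era's true
  frequency;
* per-sample missing rates drawn per class — museum (era year < 2000) vs
  fresh — from clipped normals; defaults 0.42 ± 0.10 and 0.26 ± 0.08;
* allelic dropout: each surviving true heterozygote is recorded as a
  random homozygote with probability 0.10 (low-template DNA inflates
  homozygosity — the signature artefact of degraded material);
* spurious heterozygotes: homozygotes flip to heterozygous with
  probability 0.30. This rate is deliberately high: it is the mechanism
  by which the generator reproduces the empirically observed regime where
  population H_obs exceeds H_exp in every population, a pattern real
  temporal capture datasets show without a settled cause;
* depth: negative binomial per called genotype (mean 17, dispersion 8,
  i.e. overdispersed capture coverage); missing calls DP 0;
* QUAL: 0.45 × site total DP with multiplicative Gaussian noise
  (SD 0.25) — monotone in depth on average, noisy enough that the
  QUAL < DP/4 filter fires in both directions;
* decoy records (2-bp deletions, triallelic SNPs; 10% by default) so the
  indel/biallelic stages have work to do.

The hyrad-like preset samples one drifting deme (3000 → 300,
exponentially, 1919–2005, one generation per year) at four eras, into six
analysis populations (n = 5, 7, 4, 4, 15, 18) plus three undersized
historical groups — 62 samples, 29 museum. Under default degradation the
filtered matrix lands at ≈ 0.65 completeness and ≈ 17× mean depth,
within the documented brackets [0.55, 0.70] and [12, 18]. The preset has
*no spatial structure* (all locations share one trajectory) and a *real
temporal decline*; passing tests on it therefore demonstrate recovery of
temporal drift and degradation effects, not robustness to population
structure, migration or selection.

## Numerical and procedural choices

* Filter order follows the conventional listing order of VCF filtering
  pipelines for capture data; it is asserted, not inferred.
* Rarefaction and private-allele arithmetic is exact (integer binomials);
  permutation loops use a log-gamma float path.
* θ excludes loci lacking two genotyped individuals in either population
  and loci with zero total variance.
* Degenerate inputs: monomorphic loci give HWE p = 1 and H_exp = 0;
  identical permutation groups give p = 1; empty filter output is legal
  (reports say so); all-missing samples are rejected where a statistic
  would be undefined.
* Determinism: every stochastic stage draws its seed from the run-level
  generator; reports record the seed and a configuration hash, and
  re-running a configuration reproduces every table byte-for-byte.

## Problem sizes used by the checks

The test suite and the acceptance script run entirely on generated data,
at sizes chosen to make Monte-Carlo tolerances meaningful while staying
desk-scale: 328 loci for scenario calibration (the scale of a filtered
temporal SNP matrix after within-population filtering), 20,000 loci for
drift-variance checks, 2,000 replicates for rejection-rate calibrations,
100 replicates for scenario discrimination, 10,000 permutations /
1,000 bootstrap draws in the full pipeline run. The pipeline null-change
and signature checks in the unit suite use smaller renditions (8–50
seeded runs) of the same experiments.

## Known limitations

* Genotype-level error model only; no read-level or damage-pattern
  simulation, no capture-bias model.
* Biallelic loci only in diversity statistics; multiallelic records are
  filter fodder.
* No migration, selection, or spatial structure in the demographic
  engine; scenarios are single-deme.
* The real-data reproduction requires the archived deposit
  (doi 10.5281/zenodo.1037125) to be placed locally; it is not bundled.
* The bootstrapped KS p is tail-calibrated rather than exactly uniform;
  at very small later samples (n ≈ 7) scenario discrimination through
  resampled MAFs is weak by construction (see above).
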