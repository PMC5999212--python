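# Methods

This note documents the models and procedures implemented in `hatchscan`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.  It also states what the
synthetic-data generator does and does not emulate, so that a passing test
suite is read with the right scope in mind.

## Study design being emulated

The pipeline targets a supportive-breeding design for anadromous Chinook
salmon: a wild founder population (`P1`) gives rise to two hatchery lines
propagated in parallel for four generations.  The *integrated* line (`INT`)
practices managed gene flow — its broodstock is drawn from wild-born fish
each generation — while the *segregated* line (`SEG`) is closed, using only
hatchery-origin returnees.  Adults are phenotyped for six fitness-related
traits (age at maturity, return timing, spawn timing, fork length, weight,
and daily growth coefficient) and genotyped at thousands of biallelic RAD
loci.  The analytical questions are (i) which loci associate with the six
traits, and (ii) whether divergence at those loci across generations is
limited in the integrated line relative to the segregated line.

## Synthetic-data generator

The generator (`hatchscan.simulate`) is an allele-frequency-level forward
Wright-Fisher simulator:

* **Founders.** Allele frequencies are Beta(α, β) draws (default
  Beta(0.8, 0.8), a U-shaped spectrum typical of SNP discovery panels);
  founder genotypes are Hardy-Weinberg draws from those frequencies.
* **Lines.** The segregated line is a closed Wright-Fisher population:
  per locus and generation, frequencies are binomially resampled with
  2·Ne_seg gametes (default Ne 60).  Loci under domestication selection
  experience viability selection first, with multiplicative genotype
  fitnesses (1, 1+s/2, 1+s) — the simplest scheme giving directional
  frequency change.  The integrated line draws a fraction *m* (default 1.0,
  i.e. fully wild-born broodstock) of its parents from a persistent wild
  pool of size Ne_wild (default 1000) that drifts from the founder
  frequencies; the remainder comes from the previous hatchery generation
  (Ne_int, default 150).  Selection acts in the segregated line only.
* **Samples.** Each line × generation population contributes
  `samples_per_population` individuals drawn Hardy-Weinberg from the
  current line frequencies.  Loci are unlinked; sampled individuals carry
  no pedigree structure.  Map positions are therefore free parameters:
  `place_loci` positions chosen loci on a map interval when a scenario
  needs a dense selected block.
* **Phenotypes.** Each trait is additive over its causal loci plus
  line/sex/year fixed effects plus Gaussian noise scaled so the realized
  narrow-sense heritability matches the target.  Two effect-size modes
  exist: `gaussian` per-allele effects (realistic, variance concentrates in
  common-allele/large-effect loci) and `standardized` effects (each causal
  locus contributes an equal share h²/n_causal — the calibrated design used
  for power studies, where "recovering k of n causal loci" is only
  meaningful if the loci are comparable).  Age at maturity is ordinal
  {3, 4, 5}, thresholded at the 12.5%/87.5% quantiles of its latent value
  so ~75% of adults mature at age four, matching the study system.  Weight
  is allometric: log w = log a + 3·log(fork length) + 0.02·z, i.e. a 2%
  residual CV of weight at length; the daily growth coefficient and the
  holding-period weight columns are generated so that
  DGC = 100·(final^⅓ − initial^⅓)/days holds exactly.
* **Read depths.** Total depth per (individual, locus) is negative
  binomial (default mean 40, dispersion 10); heterozygotes split reads
  Binomial(total, ½); homozygotes put Binomial(total, 0.001) reads on the
  absent allele.
* **Alignments.** Proxy-genome alignments are constructed with one contig
  per mapped locus and each aligned unmapped locus placed at a controlled
  gap from a random donor, so anchoring ground truth is exact.  Planted
  fractions sit beyond 100 kb or below mapping quality 10 and must not be
  recovered.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure (loci are exchangeable given their frequencies), family
structure and the 3×3 factorial mating design, genotyping batch effects,
null alleles, and paralogous RAD loci beyond what the HWE filter is tested
on.  Passing tests therefore demonstrate correctness of the statistical
machinery and its calibration under drift, selection and confounding — not
robustness to LD, pedigree or assay artefacts in real RAD data.

All randomness flows from a single integer seed through fixed per-stage
streams; identical configurations are bit-reproducible.

## Genotype calling and QC

A genotype is called heterozygous when both alleles have depth ≥ 2 and the
combined depth exceeds 10.  The rule defines only the heterozygote; our
completion is: homozygote for the majority allele when the minority depth
is ≤ 1 and the total is ≥ 10, missing otherwise.  This is deliberately
conservative — an ambiguous depth split (e.g. 3/7) becomes missing rather
than an invented homozygote.

The cascade order is: MAF screen (retain a locus if MAF ≥ 0.05 in at least
one population; missing calls excluded from denominators), removal of
individuals with ≥ 50% missing calls, removal of loci called in fewer than
50% of the individuals of *any* population, imputation, and finally an exact
Hardy-Weinberg filter removing loci out of equilibrium (p < 0.05, the
configurable default) in two or more populations — a guard against
genotyping artefacts and residual paralogs from the salmonid whole-genome
duplication.

The HWE test is Levene's conditional exact test: all heterozygote counts
compatible with the observed allele counts are enumerated and the p-value
sums the probabilities of configurations no more probable than the observed
one.  It is validated against an exact-rational enumeration oracle for
every table with n ≤ 50.

Imputation fills each missing dosage from the population-conditional
genotype frequencies at the locus (maximum-likelihood multinomial
estimates), drawing from the posterior by default or taking its mode in
deterministic mode; loci uncalled in a population fall back to global
frequencies.  This replaces haplotype-cluster imputation, which needs LD
that the generator does not produce; the property it must preserve — the
per-locus allele-frequency spectrum (correlation before/after ≥ 0.99 at
≤ 10% missingness) — is the property the original workflow verified.

## Map anchoring

Unmapped loci inherit the linkage-map position of the nearest mapped locus
on the same contig of the same proxy genome, provided both alignments have
mapping quality ≥ 10 and the interval gap is ≤ 100 kb.  Distance is the
symmetric interval gap (0 when overlapping); coordinates are 0-based
half-open throughout.  Ties break toward the lexicographically smallest
donor id, making assignments deterministic.  When two proxy genomes assign
the same locus, agreement on chromosome keeps the closer donor's position;
disagreement drops the locus (logged).  Cross-genome chaining is not
allowed: the donor must qualify on the same genome as the query.

## Random-forest association

The chain per trait: confounder correction → ntree stability tuning →
importance averaging over three forests → top-fraction screening →
backward purging.

**Correction.** Phenotypes and every locus dosage column are replaced by
OLS residuals against hatchery line, sex, age, year and the individuals'
PC1 coordinate from the centered imputed dosage matrix (founders excluded
throughout — the design is paired across the two hatchery lines; the PCA is
computed on the analyzed individuals).  For age at maturity the phenotype
stays categorical and genotypes are corrected with every factor except age.
Aliased design columns are dropped with a warning.  Residual orthogonality
to the design is asserted to 1e-8.

**Forests.** Regression forests use mtry = p/3 and a minimum leaf of 5
(the reference implementation's regression defaults); classification
forests use sqrt(p) and balanced class weighting per bootstrap
(`balanced_subsample`), our stand-in for per-tree downsampling to the
smallest class, which the underlying library does not expose.  "Percent
variation explained" is out-of-bag R² × 100 (1 − OOB-MSE/Var(y)), negative
values allowed; the age metric is the out-of-bag classification error %.

**Importance** is out-of-bag permutation importance, z-scored over trees
(each feature's mean per-tree error increase divided by its standard error
across trees) — the default importance of the R `randomForest` package
that this workflow descends from.  Two implementation facts matter and
were established empirically during development.  First, the importance
must be evaluated on each tree's out-of-bag samples: a training-set variant
rewards loci that memorize the sample.  Second, the z-scoring is essential
for honest screening: ranking by the raw mean error increase concentrates
the top of the list on the most strongly (spuriously) correlated noise
loci, and downstream subsets then appear to explain 10–16% of a pure-noise
phenotype; with the z-scored ranking the same experiment selects loci
indistinguishable from random.  For speed the per-tree evaluation is capped
at 64 out-of-bag samples (the per-tree subsampling noise averages out over
trees), and only features a tree actually splits on are permuted (others
cannot change its predictions).

**Tuning.** The smallest candidate ntree whose replicate forests' locus
importances correlate pairwise above 0.8 is accepted; if none qualifies the
largest is used with a warning.  Desk-scale grids (~100 trees) replace the
hundreds of thousands of trees a full-size dataset needs; the grid is
configurable.

**Screening and purging.** Three forests are regrown on the top fractions
of loci (default grid 0.5–5%; analyses here use grids chosen so candidate
sets are a few dozen loci); the best fraction × 1.5 seeds backward purging,
which removes the least-important locus one at a time, regrowing three
forests per step, and selects the set along the trajectory with the best
metric.  The *reported* metric of the selected set is re-estimated with
fresh forests grown only on that set: the trajectory maximum itself is the
best of ~dozens of noisy values and systematically optimistic.

**A caution on the null behaviour of purging.**  Backward purging greedily
maximizes an in-dataset out-of-bag metric.  On a pure-noise phenotype
(h² = 0, n = 400, p = 1000–2000) the selected sets still report several
percent "variation explained" (typically 2–11% here), and the reference R
implementation of the same procedure behaves the same way (5–9% in our
experiments).  This optimism is a property of the published method, not of
this implementation; predictor-set performance values should be read
accordingly, and the corresponding acceptance test documents the effect by
failing its ≤ 5% bound on a minority of seeds.

## Divergence and outlier detection

**Weir-Cockerham θ** (1984, two populations, diploid) is computed per locus
from genotype counts with its variance components a, b, c returned, so
windowed and multi-locus estimates aggregate as ratios of summed components
(never means of per-locus ratios).  θ may be negative at weakly diverged
loci with finite samples; fixed differences give θ = 1.

**Temporal test.** The observed statistic is the Weir-Cockerham-form FST
between the allele-count samples at two generations (the haploid-form
estimator, since the null is simulated at the allele-frequency level).  The
null conditions on the sample-estimated starting frequency: per simulation,
binomial sampling noise is applied at generation 0, the frequency is
propagated t generations of binomial(2Ne) drift, a second binomial sample
is drawn, and the statistic recomputed.  p = (1 + #{null ≥ obs})/(1 + S).
Loci whose starting sample is fixed return p = 1.  Ne per line is a
required input (defaults 150 integrated / 60 segregated — plausible for a
program of this size; the drift null is only as good as this input).
Calibration: neutral matched-Ne simulation gives rejection ≈ 0.05 at
α = 0.05 (asserted within [0.03, 0.07]).

**Windows.** Smoothed FST along a chromosome uses a Gaussian kernel over
map distance (σ = 2.5 cM, evaluated every 1 cM by default; both
configurable), smoothing the *components*: Σwᵢaᵢ / Σwᵢ(aᵢ+bᵢ+cᵢ).  The
evaluation grid is anchored at the first locus, making smoothing
shift-equivariant.  The neutral envelope resamples, per evaluation point,
the contributing loci's components from the genomewide pool (same kernel
weights), 400–500 times, taking the 2.5/97.5 percentiles; outlier regions
are maximal runs of points above the upper bound.  Only the upper bound
calls regions (elevated divergence); no multiple-testing correction is
applied beyond the envelope itself, though Benjamini-Hochberg adjustment of
temporal-test p-values is available and off by default.  A scan compares
every line × generation against the founders and runs the temporal test per
line with t = generation.  External outlier calls (e.g. from a Bayesian
FST scan, which this package deliberately does not reimplement) can be
merged as `method="external"`.

## Phenotype models and integration

Line differences per trait are modeled as y ~ line + sex + line:sex
(Gaussian identity), with age at maturity as a Poisson GLM (log link) and
weight as log w ~ line + sex + line:sex + log(fork length) on the log scale
(the allometric model; the fork-length coefficient recovers the simulated
exponent 3).  The reference level is integrated females.  By default the F3
generation is analyzed and, except for age, only age-4 fish.  Empty
interaction cells are handled by dropping aliased terms with a flag.

PCA trajectories project *all* line × generation groups together on the
dosage matrix restricted to a trait's predictor loci; per-generation
INT–SEG centroid distances with bootstrap SEs turn the usual visual
judgment of overlap into a number.  The overlap report cross-tabulates
trait-associated loci against outlier calls three ways — exact identity,
map proximity within 1.0 cM (configurable; reported per row), and
containment in outlier regions — with deterministic row ordering.  Unmapped
trait loci can only match by identity.

## Problem sizes used by the test suite and acceptance script

Simulations are sized for a single CPU: the forest-recovery study runs at
1000 loci × 400 analyzed individuals with screening fractions chosen to
keep candidate sets at 30/45 loci (the candidate-set sizes, not the
fraction labels, drive both power and the purge's behaviour — the same
absolute sizes were used when validating at 2000 loci); calibration studies
use 800–1000 loci with 50 individuals per population; the end-to-end
scenario uses 500 loci and 100 individuals per population over 10 seeds.
The acceptance script repeats the same computations at 3–5 seeds per
quantity.

## Known limitations

* No linkage: region-level power comes from planting multiple selected
  loci in a map interval, not from hitchhiking.
* The drift null and the integrated line's migration model assume the
  user-supplied Ne values; neither is estimated from data.
* The purge's reported %variation explained retains the in-dataset
  selection optimism discussed above.
* The imputer preserves frequencies, not haplotypes; it is not a
  substitute for LD-aware imputation on real data.
* Sampling-plan subtleties of temporal sampling (whether sampled
  individuals return to the population) are not modeled; samples are
  drawn with replacement from the line's frequency state.
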