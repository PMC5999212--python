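# hatchscan

Trait association and drift-aware outlier scanning for paired hatchery
lines of Chinook salmon (*Oncorhynchus tshawytscha*), built around a
synthetic-data generator that emulates the study design end to end.

## The problem

Supportive-breeding programmes for Pacific salmon rear fish in hatcheries
and release them to the wild.  Two management strategies coexist: an
*integrated* line whose broodstock is drawn from wild-born fish each
generation (managed gene flow), and a *segregated* line closed to wild
input.  The scientific question is whether managed gene flow limits
genetic change at loci underlying fitness traits — return timing, spawn
timing, fork length, weight, age at maturity and daily growth coefficient
(DGC = 100·(final weight^⅓ − initial weight^⅓)/days).

`hatchscan` implements the full analysis chain for this design:

* **simulate** — forward Wright-Fisher generator: shared founders, an
  integrated line replenished from a wild pool, a closed segregated line
  with optional viability selection (fitnesses 1, 1+s/2, 1+s), polygenic
  traits with line/sex/year confounding, negative-binomial RAD read
  depths, and proxy-genome alignments with known anchoring ground truth.
* **genoqc** — depth-based genotype calling (heterozygote iff both
  alleles ≥ 2 reads and total > 10) and the QC cascade: per-population MAF
  ≥ 0.05 screen, missing-individual and per-population call-rate filters,
  population-conditional imputation, and a Levene exact Hardy-Weinberg
  filter across populations.
* **mapanchor** — linkage-map positions for unmapped loci via the nearest
  mapped locus within 100 kb (mapping quality ≥ 10) on proxy genome
  alignments, with cross-genome reconciliation.
* **rfassoc** — confounder-corrected random-forest association:
  residualize phenotypes and genotypes against line/sex/age/year/PC1,
  tune forest size by importance stability (>0.8 between replicate
  forests), average out-of-bag permutation importances (z-scored over
  trees), screen top fractions, and backward-purge to the predictor set
  maximizing out-of-bag %variation explained (or minimizing out-of-bag
  classification error for age).
* **popgen** — Weir–Cockerham θ = a/(a+b+c) with variance components, the
  temporal drift-simulation outlier test (p-value against binomial(2Ne)
  drift from the sample-estimated starting frequency), and Gaussian-kernel
  smoothed sliding-window FST with a locus-resampling 95% neutral
  envelope; runs above the envelope are outlier regions.
* **integrate** — line-difference models (y ~ line + sex + line:sex;
  Poisson log link for age; log w ~ … + log fork length for weight), PCA
  trajectories of trait-associated loci across generations, and the
  trait-locus × outlier overlap report.

See `docs/methods.md` for the models, assumptions, defaults and
limitations.

## Worked example

The `analysis/` scripts run the whole study on a synthetic scenario in
which the ten causal loci of spawn timing experience domestication
selection (s = 0.5) in the segregated line only:

```sh
python analysis/01_simulate_study.py   # genotypes, depths, phenotypes, map
python analysis/02_genotype_qc.py      # calling + QC cascade
python analysis/03_anchor_map.py       # map anchoring
python analysis/04_rf_association.py   # RF association, six traits
python analysis/05_outlier_scan.py     # FST tracks, F_TEMP, regions
python analysis/06_integrate.py        # line models, PCA, overlap
```

Output from a run with the default seed (17):

```
caller concordance with simulated truth: 0.9993 (1.544% calls missing)
QC cascade: 1000 loci in -> 86 removed by MAF, 0 by call rate, 29 by HWE -> 885 out
imputation allele-frequency correlation: 1.0000
planted recoverable assignments found: 100.0% of 231
planted violations (>100 kb or mapq<10) wrongly assigned: 0 of 88

     trait  n_individuals  n_predictors  n_mapped                 metric_kind  metric_value
       age            600            40        34    oob_classification_error     24.611111
return_day            600             7         6 percent_variation_explained     17.544785
 spawn_day            600            15        13 percent_variation_explained     27.025213
 length_cm            600             6         4 percent_variation_explained     14.334405
 weight_kg            600            13        12 percent_variation_explained     11.252273
       dgc            600            11         8 percent_variation_explained     17.923116
spawn-timing predictors recover 6/10 simulated causal loci

156 outlier regions and 310 temporal outlier loci across all line x generation comparisons
  INT: 76 regions, 141 temporal outlier loci
  SEG: 80 regions, 169 temporal outlier loci
overlap report: 67 rows
  spawn-timing overlap rows in INT: 1
  spawn-timing overlap rows in SEG: 6
```

Reading the numbers: the depth-based caller reproduces 99.9% of the true
genotypes; QC discards rare and Hardy-Weinberg-violating loci; every
anchorable unmapped locus is recovered and no planted violation slips
through.  The forests find predictor sets for all six traits — for spawn
timing they recover 6 of the 10 simulated causal loci and explain ~27% of
the trait variation out of bag.  The outlier scan flags more temporal
outliers in the segregated line, and the overlap report concentrates
spawn-timing loci near segregated-line outliers (6 rows vs 1) — the
qualitative signature of domestication selection that managed gene flow is
meant to suppress.

A `hatchscan` command-line interface wraps the same steps
(`hatchscan simulate|genoqc|mapanchor|rfassoc|popgen|integrate --help`).

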