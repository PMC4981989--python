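# Methods

`cnvgwas` measures copy-number genotypes at catalogued copy-number-variable
regions (CNVRs) from SNP-array intensity data, harmonizes the genotypes
across cohorts typed on different platforms, and tests them for association
with quantitative lung-function traits (FEV1, FVC, FEV1/FVC).  This note
describes the statistical model at each stage, the tunable parameters and
their defaults, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter for reproducibility.

## Copy-number calling model

At each CNVR the probe-level Log R Ratio (LRR) values inside the region
boundary are averaged to a single summary per sample; only samples with
complete in-region probe data enter the summary.  The per-sample summaries
are modelled as a univariate Gaussian mixture,

    x_i ~ sum_k  pi_k  N(mu_k, sigma_k^2),      k = 0..K-1,

where each component is one copy-number class.  Components are relabelled by
ascending mean, so class labels are *relative* copy states: the caller never
anchors class k to an absolute copy number, and downstream association is
invariant to that choice (an affine relabelling rescales the slope but
leaves its sign and P-value unchanged — tested explicitly).

Fitting is maximum likelihood by EM: convergence when the relative
log-likelihood change is below 1e-8 or after 500 iterations; component
variances floored at 1e-6 (LRR^2); best of 10 restarts on a deterministic
seed ladder.  Restart 0 starts from K-quantile means with a pooled-variance
guess.  The remaining restarts seed the means from data points with
distance-weighted (k-means++-style) sampling and moment-match each
component's weight and variance from the nearest-mean partition.  The
distance-weighted restarts are essential: quantile starts cannot reach a
rare, well-separated class (e.g. a handful of homozygous deletions near
LRR -3), and when EM never visits that optimum, model selection compensates
with spurious extra components inside the diploid cluster.

The number of classes K is chosen by minimum BIC over K = 1..k_max
(default 6; ties favour smaller K).  A CNVR counts as *polymorphic* in a
cohort when the selected K >= 2 and every class has expected count
pi_k * n >= 3 (`min_expected`, configurable).  Posterior class probabilities
gamma_ik give the MAP class, the call confidence max_k gamma_ik, and the
continuous copy-number **dose** d_i = sum_k k * gamma_ik in [0, K-1], which
carries calling uncertainty into regression.

## Sample quality control

Three filters run before calling, in order:

1. **Replicates** — declared duplicate sample ids; first occurrence kept.
2. **Intensity noise** — per-sample SD of autosomal LRR values (population
   SD, missing probes ignored, >= 100 probes required); samples above the
   threshold (default 0.30 LRR units) are removed.  The pipeline computes
   the metric on probes *outside* the CNVR catalogue whenever at least 100
   such probes exist: on dense arrays the in-CNVR fraction is negligible,
   but on sparse manifests genuinely copy-variable probes would inflate the
   metric for carriers and bias their removal.
3. **Ancestry outliers** — principal components of the SNP dosage matrix
   (monomorphic SNPs dropped; each SNP centred at 2p and scaled by
   sqrt(2p(1-p))).  Samples with |score - mean| strictly greater than 6 SD
   on any of the first 4 components are removed, in a single pass using
   all-sample statistics (an iterative mode is available by flag).  A
   sample exactly at the boundary is retained.

## Cross-cohort harmonization

Cohorts are clustered independently, then anchored to a designated
best-performing **reference cohort**: for every CNVR, cohorts whose freely
selected K differs from the reference are re-clustered with K fixed to the
reference value (fits with any class expecting fewer than 3 samples are
flagged low quality; fewer than 5K samples makes the region uncallable).
Class-frequency compatibility with the reference is then tested by a
Pearson chi-square on the 2 x K table of MAP-class counts (no continuity
correction; classes with expected count below 1 are pooled with the
adjacent class first).  A cohort contributes a CNVR to meta-analysis iff
the test's P >= alpha (default 0.05); the reference always contributes
where it called the region.  CNVR type is assigned from the fitted mixture:
the modal class anchors the diploid state, classes below it in mean are
losses and above are gains; losses only = deletion, gains only =
amplification, both sides or K > 3 = multiallelic.  The modal-anchor rule
is this package's construction.

## Association and meta-analysis

Traits are adjusted in a first stage by least squares on intercept, age,
age^2, sex, height, height^2 and the first 4 ancestry PCs (complete cases;
constant or collinear columns dropped with a warning).  The residuals are
regressed on the copy-number dose: OLS with the slope's t-test for
unrelated cohorts, GEE with an exchangeable working correlation and robust
sandwich standard errors for family-structured cohorts (independence
available by flag; with singleton clusters the GEE slope equals OLS, which
is asserted in tests).  Discovery results are combined across cohorts by
fixed-effect inverse-variance weighting (all cohorts analysed in litres /
ratio units).

Replication of suggestive signals (P < 0.001, strict) goes through tag
SNPs: within 1 Mb of the CNVR start/end, the SNP with the highest squared
Pearson correlation r^2 between its dosage and the copy-number dose (ties
to the lowest position); a CNVR is tagged when r^2 > 0.7 (strict).  External
study effects are sign-aligned to the allele positively correlated with
increasing copy number, then combined by IVW for FEV1 and FEV1/FVC and by
sqrt(N)-weighted Stouffer Z for FVC (one replication resource analysed FVC
untransformed, so effect scales differ and only P-values and signs are
comparable).  The sqrt(N) weighting is the field-standard choice; the
signed z for a two-sided P is sign * Phi^-1(1 - P/2).  The replication
significance threshold is 0.05 divided by the number of tagged CNVR-trait
tests.  The rank-based inverse-normal transform used by replication
phenotypes maps rank r of n to Phi^-1((r - 3/8)/(n + 1/4)) (Blom offset;
ties share average ranks); discovery traits are not rank-transformed by
default.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable without any external data:

- **Genotypes.** Biallelic CNVRs draw two Hardy-Weinberg alleles at
  frequency q; K=3 classes are the variant-allele counts with frequencies
  ((1-q)^2, 2q(1-q), q^2), K=2 merges the non-homozygous states.
  Multiallelic (K=4) regions are the truncated sum of two independent
  biallelic variants — the simplest generative model with > 3 classes.
- **Intensities.** Class c of a region maps to a copy number (deletion
  2..0, amplification 2..4, multiallelic 1..4) with expected LRR
  log2(copy/2), copy 0 floored at 0.25 to keep the expectation finite.
  Each probe adds independent Gaussian noise at the cohort's platform SD;
  probe density and noise differ per cohort, and one cohort is written in
  a summed X+Y intensity dialect, a stand-in implemented as an affine
  transform of LRR (real X+Y normalization is platform-specific and not
  modelled; the reader median-centres per probe so both dialects share a
  location convention).  Background diploid probes outside the catalogue
  support the noise metric.
- **Phenotypes.** Adult-plausible spirometry: covariate models for FEV1,
  FVC and FEV1/FVC in age, age^2, sex, height, height^2 with residual SDs
  0.40 L, 0.50 L and 0.07; spiked CNV effects add beta per true copy
  class.  One cohort has sibships (default: half the samples, sizes 2-4)
  whose members share a family effect giving residual intraclass
  correlation 0.5.
- **Tag SNPs.** Each SNP allele copies the CNV variant allele with
  probability sqrt(target r^2), else redraws at frequency q, giving
  genotype-level squared correlation equal to the target in expectation
  (realized r^2 within +-0.05 for n >= 2000).
- **Determinism.** All randomness flows from one seed through spawned
  generator streams; identical configs give byte-identical datasets.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real arrays: probe-level fluorescence and genomic-wave
artefacts, batch/plate effects, sex chromosomes, linkage disequilibrium
between the PCA SNPs, population stratification unless explicitly
configured, and measurement error in covariates.

### Problem sizes in the test suites

The integration study (`small_study_config`) uses two cohorts of 300 and
250 samples (the first with families), five CNVRs at 6-8 probes each, and a
spiked FVC effect of 0.5 x the residual SD per copy class; class selection
runs with k_max = 4, matching the largest class count in that catalogue.
These sizes keep a full simulate-to-meta-analysis run to a few seconds
while leaving the spiked signal's expected |z| near 7, far above the null
CNVRs.  Fixture allele frequencies (q = 0.2-0.4) keep the rarest
Hardy-Weinberg class at >= ~10 expected carriers at these n — the regime a
common CNV occupies on a full-size cohort, where even a 1% class retains
tens of carriers; rarer classes would be dropped by the minimum-class-count
rule or produce unstable few-carrier regressions, which is correct
behaviour but not useful as a recovery fixture.

## Numerical choices and degenerate inputs

- Variance floor 1e-6 and posterior normalization guarantee finite,
  normalized responsibilities; EM log-likelihood is non-decreasing (the
  suite asserts every iteration across 1000 random fixtures).
- Constant intensity summaries with K > 1 return the single-component fit
  flagged degenerate rather than failing.
- Zero dose variance yields "no result" (direction "."), not an error;
  fewer than 30 samples is an error.
- Coordinates are 0-based half-open (BED); probe-in-region is
  start <= pos < end; 1-based inclusive catalogues convert on read.
- All tabular output is TSV with "NA" missing values, 6-significant-digit
  floats and a header comment carrying version, config hash and seed;
  reruns of the same configuration are byte-identical.

## Known limitations

- Absolute copy anchoring is not attempted; reported classes and doses are
  relative.  This suffices for association but not for reporting integer
  copy numbers.
- The chi-square compatibility test assumes independent cohorts and large
  counts; the adjacent-pooling rule handles sparse classes but very small
  cohorts may still be under-powered to detect frequency shifts.
- GEE robust standard errors are asymptotic in the number of families;
  with few clusters the test is mildly anti-conservative.
- The X+Y dialect is a location-shift stand-in; no claim is made that it
  reproduces real summed-intensity noise characteristics.
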