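# cnvgwas

Multi-cohort copy-number-variant (CNV) genotyping from SNP-array intensity
data, with association testing against quantitative lung-function traits.

SNP genotyping arrays measure a Log R Ratio (LRR) per probe whose
expectation tracks DNA copy number, so existing GWAS intensity data can be
re-used to genotype known copy-number-variable regions (CNVRs) — but each
cohort sits on its own platform with its own probe density and noise, and
the resulting genotypes must be made compatible before they can be
meta-analysed.  `cnvgwas` implements that pipeline end to end for
researchers running array-based CNV association studies:

1. **Sample QC** — replicate removal, per-sample intensity-noise filtering,
   ancestry principal-component outlier exclusion (|score| > 6 SD on any of
   the first 4 PCs).
2. **Calling** — per CNVR, the in-region probe LRRs are averaged to one
   value per sample and clustered with an EM Gaussian mixture
   `x_i ~ Σ_k π_k N(μ_k, σ_k²)`; BIC selects the number of classes K.  Each
   sample gets a MAP class, posterior vector γ_i and a continuous copy-number
   dose `d_i = Σ_k k·γ_ik` that propagates calling uncertainty.
3. **Harmonization** — every cohort is anchored to a best-performing
   reference cohort: mismatched class counts trigger fixed-K re-clustering,
   and a Pearson χ² test on the 2×K class-count table decides whether a
   cohort's class frequencies are compatible enough to enter meta-analysis.
4. **Association** — traits (FEV1, FVC, FEV1/FVC) are adjusted for age,
   age², sex, height, height² and 4 ancestry PCs; residuals are regressed
   on dose (OLS, or GEE with exchangeable working correlation and robust SEs
   for family cohorts), then combined across cohorts by inverse-variance
   weighting.
5. **Replication** — CNVRs tagged by a SNP at r² > 0.7 within 1 Mb are
   looked up in external GWAS summary statistics, sign-aligned to the
   copy-increasing allele, and meta-analysed (IVW for FEV1 and FEV1/FVC,
   √N-weighted Stouffer Z for FVC) against a Bonferroni threshold for the
   number of tagged tests.

A first-class synthetic-data module generates multi-cohort studies with the
same statistical structure (Hardy-Weinberg CNV classes, platform-specific
noise, family structure, covariate-driven spirometry, tag SNPs at a target
r²), so the entire pipeline is testable without any external data.

## Worked example

Simulate a two-cohort study with one spiked effect (a 3-class deletion,
CNVR2.1, adds 0.25 L of FVC per copy class) and run the whole pipeline:

```python
from cnvgwas import simulate_multi_cohort_study, small_study_config
from cnvgwas.pipeline import cohort_inputs_from_sim, run_study

ds = simulate_multi_cohort_study(small_study_config(seed=1))
res = run_study(cohort_inputs_from_sim(ds), ds.regions,
                reference="A", seed=3, k_max=4)
print(res.top_hits(3)[["region_id", "trait", "n", "beta", "se",
                       "pvalue", "direction"]].to_string(index=False))
tag = res.tags["CNVR2.1"]
print(f"tag SNP for CNVR2.1: {tag.snp}, r^2 = {tag.r2:.3f}")
```

```
region_id trait   n      beta       se       pvalue direction
  CNVR2.1   FVC 550  0.247820 0.032718 3.609519e-14        ++
  CNVR3.1  FEV1 550 -0.146753 0.067166 2.889485e-02        --
  CNVR8.1   FVC 550 -0.048603 0.024419 4.655046e-02        --
tag SNP for CNVR2.1: rs_CNVR2.1, r^2 = 0.908
```

The spiked CNVR tops the meta-analysis with its effect recovered
(0.248 ± 0.033 L per class against a true 0.25), consistent direction in
both cohorts, and a tag SNP at r² = 0.91; the remaining rows are null CNVRs
at unremarkable P-values.

The meta-analysis operations also work directly on external summary rows —
for example combining three replication studies' P-values and signs with
√N weights:

```python
from cnvgwas import stouffer_meta
z = stouffer_meta([(0.017, "+", 48201), (0.0037, "+", 48943),
                   (0.79, "-", 49727)])
print(z.summary())
```

```
Z-score meta (3 studies): Z=2.8879 P=0.003878 [++-]
```

meaning the combined evidence across 146,871 individuals is P ≈ 0.0039 with
two of three studies agreeing in direction.

## Command line

Every stage is also a subcommand over the same library code:

```bash
cnvgwas simulate --config sim.yaml --out-dir data/ --seed 4
cnvgwas qc --intensities A_intensities.tsv --genotypes A_snps.tsv --out qc.tsv
cnvgwas call --intensities A_intensities.tsv --probes A_probes.tsv \
             --regions regions.bed --out-prefix A
cnvgwas harmonize --calls A_calls.tsv --calls B_calls.tsv --reference A --out harm.tsv
cnvgwas assoc --phenotypes A_phenotypes.tsv --calls A_calls.tsv --trait FVC \
              --family-col family_id --out assoc_A.tsv
cnvgwas meta --assoc assoc_A.tsv --assoc assoc_B.tsv --out meta.tsv
cnvgwas pipeline --config pipeline.yaml   # all stages from one YAML
```

Formats are plain TSV (intensities, phenotypes, calls, results), BED
(CNVR catalogue, 0-based half-open) and VCF or TSV (SNP dosages).  Every
output carries a header comment with the package version, a configuration
hash and the seed; identical configurations reproduce byte-identical files.

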