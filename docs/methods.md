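# Methods

`neanderscan` identifies Neandertal-introgressed SNPs (aSNPs) in phased
modern haplotype panels and tests them for case-control disease
association. This note records the models, the defaults and why they
are what they are, the numerical choices, and what the synthetic-data
validation does and does not demonstrate.

## The aSNP model

A biallelic SNV is an aSNP *candidate* when four conditions hold:

1. **(a) sharing** — one of its alleles is carried by the archaic
   (Neandertal) genome and segregates in at least one non-African
   population;
2. **(b) outgroup absence** — that allele is absent from the African
   outgroup panel (alleles that predate the out-of-Africa migration are
   expected in Africa; alleles delivered by later Neandertal admixture
   are not);
3. **(c) archaic homozygosity** — the archaic individual is homozygous
   for the allele, which guards against archaic sequencing error and
   within-Neandertal polymorphism;
4. **(d) tract length** — the haplotype carrying the allele is longer
   than incomplete lineage sorting (ILS) can plausibly explain.

Criteria (a)–(c) are site-wise Boolean filters (`apply_site_criteria`).
A site with a missing archaic call is never a candidate; absence from
Africa additionally requires at least one called African allele, since
with no calls the absence cannot be established.

## The ILS segment-length test

Criterion (d) is decided on per-haplotype *segments*: maximal runs of
consecutive candidate sites at which a haplotype carries the archaic
allele. A run is broken by a candidate site where the haplotype carries
the non-archaic allele; a missing call neither breaks nor extends a run.
The segment interval spans the first to the last marker.

Under ILS, a shared segment has been eroded by recombination for the
full archaic–modern divergence, `G_div` generations summed over the two
branches. With local recombination rate `r` (cM/Mb; `r_bp = r * 1e-8`
crossovers/bp/generation), the expected surviving length is

```
E[L] = 1 / (r_bp * G_div)
```

and the survival probability of a segment of observed length `l` is the
exponential (memoryless) tail

```
p = exp(-l / E[L]).
```

Segment p-values are corrected with the Benjamini–Hochberg step-up over
all segments in the run (the family is genome-wide per run); haplotype
segments with adjusted P < 0.05 are declared introgressed, and an aSNP
is any candidate lying on at least one such segment (support on a
single haplotype suffices). `r` is the piecewise-linear mean rate over
the segment from a HapMap-format map, or a constant; queries outside
the map range use the boundary cumulative cM (zero-rate extension)
rather than extrapolating. A zero local rate makes a segment
untestable: it receives `p = 1` and is logged.

Defaults: archaic–modern divergence 550 ky, generation time 29 y, hence
`G_div = 2 * 550e3 / 29 ≈ 37 931`. These are package defaults, exposed
in `ILSModelConfig`, not measured quantities. `min_markers_per_segment
= 2` because a single-marker segment has zero length and `p = 1`
regardless; dropping such segments just avoids inflating the BH family.
When two maps are supplied in conservative mode, the larger of the two
expected lengths is used (harder to reject ILS). A Gamma-tail
alternative was considered and left out: the exponential tail is the
memoryless limit consistent with the expected-length formulation, and
the config hook (`tail_model`) marks where a heavier tail would plug
in.

Segment construction itself is deliberately the simplest testable
reading (runs of consecutive candidate markers) and is isolated behind
`build_segments` so a haplotype-based alternative can replace it
without touching the rest.

## Sample and variant QC

The funnel runs in a fixed order: variant call rate (< 0.9 removed) →
sample call rate (< 0.75) → heterozygosity (> 3 SD from the mean,
two-sided — both tails signal artefacts even though only the upper is
usually quoted) → relatedness (PI_HAT > 0.2; the lower-call-rate member
of a pair is dropped) → PCA outliers (> 6 SD on any of the top 8
components, flag-and-recompute iterated once) → Hardy–Weinberg
(Pearson χ², 1 df, P < 1e-6; tested in controls only when status is
supplied, so true case-enriched signals are not removed) → imputation
INFO score (< 0.7 removed; sites without the field are retained as
directly genotyped). All boundary comparisons are strict (`< threshold`
removes), matching the stated rules.

PI_HAT is the PLINK-style method-of-moments estimator: observed IBS
counts corrected by panel allele frequencies into P(IBD=0/1/2), with
negative components clamped to zero before normalisation and
`PI_HAT = P(IBD=2) + P(IBD=1)/2`. No small-sample correction factors
are applied; at the panel sizes this package targets the estimator is
validated by simulation (duplicates ≥ 0.95, unrelated ≈ 0,
parent–offspring ≈ 0.5).

PCA standardises dosages by `sqrt(2p(1-p))` after mean imputation of
missing calls, takes the SVD, and truncates `k` to the matrix rank with
a warning when necessary.

## Association and multiple testing

Per-SNP covariate-adjusted logistic regression is fitted by
Newton/IRLS: convergence when the largest score component falls below
1e-8 or after 25 iterations; standard errors from the observed
information; Wald two-sided P; `OR = exp(beta)` with a 95% CI of
`exp(beta ± 1.959964 * SE)`. A fit whose coefficients pass |beta| > 15
is flagged as (quasi-)separated with a warning — never silently
reported. Rank-deficient designs raise an error naming the offending
columns. Discovery-style analyses adjust for age, sex and the top eight
genotype PCs; replication-style analyses for age, sex and study
country. `logistic_scan` is the same model vectorised across SNPs
(shared covariates, batched Newton updates with an active set), used
for genome-scale null-calibration runs.

LD is the squared Pearson correlation of dosages (composite r²); with
phased input, haplotype vectors give the classical `D' = |D|/D_max` as
well. Monomorphic sites are undefined and treated as r² = 0 for
pruning, with a log entry.

Reporting pruning is greedy by ascending Wald P (ties by position):
each kept SNP removes every remaining SNP with r² > 0.5, which realises
"keep the lowest-P SNP per LD block" without needing an explicit block
definition. The Bonferroni family size `m` is counted by a
position-ordered greedy at r² < 0.8 and the threshold is `0.05 / m`,
reported to three significant figures. With the independent counts of
the three published study designs this arithmetic gives 2.55e-6
(19 623 tests), 2.30e-6 (21 780) and 2.28e-6 (21 965); note the source
also prints 2.30e-6 once for the 19 623-test design — the package
reproduces the `0.05/m` arithmetic.

The genomic inflation factor is `lambda = median(chi2) / 0.45494` (the
1-df null median), accepting either χ² statistics or p-values; fewer
than 100 tests triggers a warning.

For summary-statistics studies (no genotypes), a SNP passes the
concordance rule when every study reports P < 0.05 and all betas share
a sign for the same effect allele; mismatched effect alleles raise
rather than silently flipping. OR and beta interconvert by natural log
throughout.

## The synthetic-data generator

The simulator emulates exactly the signal the caller exploits, at the
stated study conditions: per non-African haplotype, introgressed tracts
are laid down by an alternating gap/tract renewal process with
exponential tract lengths of mean `1/(r_bp * G_adm)` and stationary
covered fraction `p_adm` (defaults: `p_adm = 0.02`, within the reported
1–3% Neandertal ancestry; `G_adm = 1900 ≈ 55 ky / 29 y`). ILS tract
loci are laid down once at the genome level with mean length
`1/(r_bp * G_div)` and assigned to haplotypes of **all** populations at
a per-locus carrier frequency drawn U(0.05, 0.30); with probability
`pi_afr_loss = 0.3` a locus is absent from every African haplotype.
This creates the two ILS sub-cases the caller must handle: loci
retained in Africa are rejected by criterion (b) at the site level,
loci lost from Africa pass (a)–(c) and are caught only by the length
test. An optional second non-African population takes
`p_adm * p_adm2_scale` (default scale 1.14, mimicking the elevated
East-Asian Neandertal ancestry).

Archaic marker sites are drawn Poisson(`mu_arch` per bp, default 1e-3)
on the union of all tracts; a haplotype carries the derived allele at a
marker exactly when one of its tracts covers it, and the archaic
pseudo-genome is homozygous derived there. Markers are fixed derived on
tracts (no within-tract mutation loss), which keeps truth-based
evaluation exact; genotype error and missingness are separate knobs
(default 0). Background SNPs are Poisson(`mu_bg`) with one shared
frequency U(0.05, 0.95) across populations and an archaic genome
homozygous for the ancestral (reference) allele; the generator
guarantees the ancestral allele survives in the sampled African
outgroup, since the finite outgroup sample would otherwise occasionally
lose it by drift and manufacture sites that pass criteria (a)–(c)
without any archaic history.

Phenotypes follow the generative mirror of the fitted model:
`status ~ Bernoulli(expit(beta0 + sum(beta_g * dosage) + beta_age *
(age - 60) + beta_sex * sex))`, with age centred so `beta0` alone sets
prevalence. Case-control ascertainment (`sample_case_control`) shifts
only the intercept, so ORs remain estimable. Effects large enough to
saturate the case probabilities trigger a quasi-separation warning at
generation time.

What the simulator does **not** emulate: coalescent genealogy and drift
(introgressed tracts are independent across haplotypes rather than
descending from shared admixture-era ancestors, so simulated aSNP
frequencies are concentrated near `p_adm` instead of following a drift
spectrum), selection, demography, mutation loss on tracts, and
phase/genotyping error unless explicitly switched on. Passing tests
therefore demonstrate the correctness of the calling and testing
machinery under the length-signal model — not calling performance on
real 1000 Genomes panels, where LD structure, frequency spectra and map
error are richer.

## Validation study sizes

The calibration and performance studies are sized for desk-scale
reproducibility, chosen to give the statistics adequate support:

* **Tract calibration** — 80 Mb, 20 non-African diploids: ≥ 500
  independent length draws of each origin. Introgressed tracts are
  independent per haplotype; ILS loci are shared across carriers, so
  each distinct locus is counted once — carrier copies of one locus are
  not independent draws, and counting them would overstate the
  effective sample size several-fold. At ~1700 loci the exponential
  mean has ~2.4% sd, giving a 10% tolerance ~4σ of margin.
* **Caller performance** — the default panel (10 Mb, 50 diploids per
  population, 1 cM/Mb): precision ≥ 0.8 and sensitivity ≥ 0.5 against
  truth, plus a monotone loss of sensitivity as `G_div` is moved toward
  `G_adm` (37 900 → 8 000 → 3 200), where the two length scales merge.
* **Null control** — one cohort of 40 Mb × 2000 non-African diploids
  with marker density thinned to 2e-4/bp, scanned against 100
  independent null phenotype draws. The sample size makes the typical
  aSNP minor-allele count ≈ 160, where the Wald χ² median is calibrated
  (it inflates noticeably below minor-allele counts of ~50); thinning
  markers only removes duplicated tests within tracts. The inflation
  factor is computed over the pooled scan statistics of all 100 draws —
  the per-draw median over a correlated genomic field of this length
  has a sampling sd of ~0.06 and is not individually meaningful — and
  family-wise control is asserted as ≥ 95 of 100 draws with no
  Bonferroni-significant aSNP.

## Numerical choices and degenerate inputs

* All internal coordinates are 0-based half-open; VCF (1-based) and BED
  conversions happen only in `io_formats`.
* `ils_pvalue` clamps at the smallest positive double so p stays in
  (0, 1] even for extreme segments; the strict-monotonicity property
  holds up to the float underflow horizon (`l/E[L] ≈ 700`).
* BH uses a stable mergesort and restores input order exactly.
* HWE on a monomorphic table returns (χ² = 0, P = 1) by convention.
* Heterozygosity filtering with < 3 samples or zero SD removes nothing
  and says so in the report.
* `local_rate` rejects empty intervals; degenerate (single-marker)
  segments never reach it under the default marker minimum.
* Logistic fits mean-impute missing dosages; monomorphic dosages are
  skipped by the pipeline scan and logged.
* Fixed seeds make `simulate_panel`/`simulate_phenotypes` and the whole
  pipeline bit-reproducible; identical config + seed yields
  byte-identical TSV output.

## Known limitations

* Exact ILS probability constants (one- vs two-branch bookkeeping, tail
  family) vary across the literature; the defaults here are documented
  package choices, and `ILSModelConfig` exposes every one of them.
* The segment builder requires phased modern haplotypes; unphased or
  pseudo-phased data are out of scope.
* Summary-mode Bonferroni uses the number of looked-up SNPs as the
  family size, since LD is not computable from summary statistics
  alone.
* The two-maps conservative mode is an interpretation (take the
  harder-to-reject expected length); the original combination rule is
  not documented in the source material.
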