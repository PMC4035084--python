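# Methods notes

## Scope and data model

The package analyses a cohort of subjects with (i) genotypes at a catalog of
validated BMI risk SNPs — as hard calls, proxy-marker hard calls, or
imputation-probability triples — (ii) CNV interval calls from several
callers, and (iii) phenotypes/covariates (height, weight, sex, age, alcohol
and nicotine dependence, ancestry-informative principal components). All
intervals are 0-based half-open everywhere (VCF positions converted on
read/write), which makes length and overlap arithmetic exact. Real cohorts
of this kind live behind controlled access, so the package ships a
generator that emulates the statistical structure the estimators assume;
every pipeline stage is exercised end to end on synthetic cohorts.

## Synthetic cohort generator

**Genotypes.** Biallelic SNPs under Hardy–Weinberg equilibrium at catalog
frequencies, loci in linkage equilibrium: the risk-allele dosage is
Binomial(2, f). The default catalog has 32 SNPs with per-allele effects
uniform on [0.06, 0.39] kg/m² and frequencies uniform on (0.1, 0.9); one
SNP is flagged as lacking an adequate proxy marker, so proxy scores cover
31 loci.

**Imputation-probability blur.** A genotype-probability triple is drawn
from a Dirichlet centered on the mixture `(1−w)·e_g + w·π`, where `e_g` is
the true-genotype vertex and `π` the HWE genotype distribution, with fixed
concentration κ = 50. The quality metric is the imputation *info* statistic
`var(dosage) / 2f(1−f)`, for which the model admits a closed form:
`(1−w)² + E_g[within-triple dosage variance] / ((κ+1)·2f(1−f))`. The mixture weight
`w` is root-found (Brent) so the analytic info equals the requested quality;
quality = 1 is special-cased to exactly degenerate triples, so
probability-based scores collapse to their hard-call counterparts exactly —
a useful equivalence oracle. The default quality is 0.95, typical of
well-imputed common variants (scores in practice are restricted to info
above 0.8). Note the statistic is calibrated, not the correlation with
truth; at κ = 50 the within-triple noise term is small, so the attenuation
of downstream regression slopes is well under 1% of the score's variance
share.

**Proxy markers.** Each of the two haplotype alleles is copied from the
true locus and flipped independently with probability ε, root-found so the
squared allelic correlation with the true allele equals the target r²
(default 0.8; ε = 0 reproduces the original dosages). This models a single
tag SNP in LD, not haplotype structure.

**CNV callers.** Each subject carries each planted locus independently at
its frequency. Three synthetic caller profiles mimic array-CNV software: a
caller detects a carried event with sensitivity 0.92–0.95, jitters both
boundaries with Gaussian noise (150–300 bp SD), and draws a Log Bayes
Factor for callers that emit one — true calls around 35 ± 12, spurious
around 12 ± 6, so the LBF ≥ 10 filter removes mostly-spurious calls; one
caller emits no confidence metric and passes the filter flagged, mirroring
real tool heterogeneity. Spurious calls arrive Poisson (0.25–0.35 per
subject) uniformly outside planted loci with log-normal lengths (median
50 kb). The default region catalog holds 84 loci: a 21-kb deletion at
carrier frequency 16.9% (the only locus with a BMI effect), a 66-kb
duplication at 1.2%, a 1635-kb deletion at 7.7%, and 81 rare effect-free
loci at 0.05–0.8%.

**Phenotype model and variance calibration.** BMI is

```
BMI = μ + c_cov·(L − E L) + c_g·(G − E G) + c_cnv·(C − E C) + ε
```

with `G = Σ β_i g_i` the additive genetic value, `L` the covariate linear
predictor, `C` the CNV carrier term and ε Gaussian. Scalings are solved
analytically so each component's share of total variance equals its target
fraction in expectation: the genetic raw variance is `Σ 2f_i(1−f_i)β_i²`
under HWE/LE; the covariate predictor variance is computed from the exact
joint moments of the covariate generator (including the sex→AD/ND
covariances induced by sex-dependent dependence rates); the CNV raw
variance is `Σ e_l² q_l(1−q_l)`. When the score fraction is positive the
genetic component keeps its natural scale (the catalog βs in kg/m² per
allele), which pins the total variance at `V_g / fraction` and solves the
noise variance from the remaining share; with the default fractions
(covariates 8.3%, score 3.1%, CNV 0.1%) this lands the BMI SD near
5.1 kg/m², realistic for an adult cohort. When the score fraction is zero
the `residual_sd` field (default 5.3 kg/m²) anchors the scale instead.
Default cohort size is 2348 with a 1850/498 two-level ancestry split; the
ancestry indicator loads on PC1 and can optionally shift allele
frequencies (off by default, keeping the calibration exact). The intercept
default 27.63 kg/m² sets the cohort mean.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: LD beyond single proxy pairs, haplotype
blocks, the right-skew of real BMI (the Gaussian residual gives ~1% class-
III prevalence at the default design versus ~4.5% in a comparable real
cohort, so morbid-obesity ROC analyses here rest on fewer cases),
array-probe intensity artifacts, genomic waves, batch effects, and
ancestry-differentiated allele frequencies under the default settings.

## Pipeline conventions and numerical choices

* **QC**: exclusion bounds are strict inequalities (height outside
  (1.4, 2.0) m, weight outside (38, 166) kg, BMI outside (14.5, 60)), so
  boundary values are retained; the first triggering rule is logged per
  removal; BMI is always recomputed from height/weight, and a supplied BMI
  differing by > 0.1 kg/m² is logged. Bodyweight classes nest and the
  cumulative indicators (≥ 25/30/35/40) are what the logistic models
  predict.
* **Score denominators**: hard-call methods average per counted allele
  (2n), probability methods per SNP (n). Both are selectable; association
  statistics are invariant to the choice, so the convention only fixes the
  descriptive scale of the score.
* **Allele harmonization**: catalog risk/other alleles must match VCF
  REF/ALT in either orientation; A/T and C/G SNPs are strand-ambiguous and
  are dropped with a warning unless explicitly allowed.
* **Missing genotypes** are imputed at dosage 2f from the *analysis
  sample's* allele frequency (computed over non-missing subjects), not the
  catalog frequency; an all-missing subject gets a missing score.
* **Consensus**: grouping is by connected components of the pairwise
  ≥ 50%-reciprocal-overlap relation within (sample, chromosome, state);
  a component emits an event iff ≥ 2 distinct callers appear in it. This is
  deterministic and invariant to caller/call order, and removing a caller
  can never grow the consensus set. The consensus interval is the
  intersection of supporters (conservative); the envelope (union) is what
  the ≥ 100-kb score filter measures, since larger outer boundaries track
  probe support. A chained component with an empty joint intersection is
  logged and skipped.
* **Catalog matching** is reciprocal (≥ 40% of both the event and the
  catalog interval) with state equality; one-way-only passes are logged.
  Best overlap wins (the smaller of the two fractions), ties break to the
  smaller catalog interval, then the lexicographically first label.
  Carrier coding is binary per region per subject; deletions and
  duplications are separate regions.
* **Exclusion regions** use any-overlap (≥ 1 bp): abutting events under
  half-open coordinates are retained.
* **Burden**: event frequency is defined genome-wide by clustering
  consensus events across subjects with the same reciprocal-overlap rule;
  rare means distinct-carrier frequency < 1%.
* **Regression**: predictors enter in a fixed configured order (covariates
  → score → CNV terms) — no automatic variable deletion; predictors are
  mean-centered (recorded for back-transformation); candidate interactions
  are screened one at a time and accepted jointly at α = 0.002. Logistic
  fits retry with BFGS when Newton meets a singular Hessian; the CLI's
  prediction stage skips outcomes with fewer events per class than the
  largest model's parameter count and drops carrier columns absent from
  either outcome class (which would separate the likelihood).
* **AUC machinery**: midrank placements give the Mann–Whitney AUC and the
  DeLong-type variance in O(N log N); Wald 95% CIs; the paired test uses
  the placement covariance between curves. Identical score vectors (zero
  variance of the difference) return p = 1 at Δ = 0. %ΔAUC uses the
  previous (smaller) model's AUC as denominator. The paired DeLong-type
  test replaces external ROC-comparison services: same null hypothesis and
  asymptotics, reproducible offline.

## Problem sizes

Defaults are the cohort-scale conditions the package is designed around:
n = 2348 subjects, 32 catalog SNPs, 84 CNV regions, three callers. The
parameter-recovery analyses in `scripts/acceptance.py` and the acceptance
tests use 50 such cohorts (median estimates), 200 binormal ROC replicates
with 106/2242 cases/controls, and 400-replicate null calibrations; the
variance-calibration invariant is checked on a single 10⁵-subject cohort.

## Known limitations

Single-file VCF/TSV readers (no tabix-indexed region queries); no genome
build handling beyond a config annotation (catalog coordinates are taken
verbatim); no LD-aware scoring (no clumping/pruning) and no cross-ancestry
weight recalibration; the interaction scan tests products of observed
columns only; rare-CNV inference on synthetic data inherits the generator's
independence assumptions.
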