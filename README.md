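# snpcnv

Integrated analysis of common SNPs and copy-number variants (CNVs) for body
mass index (BMI) and obesity: genetic risk sum scores, multi-caller CNV
consensus calling, combined covariate + SNP + CNV regression models, and
ROC-based obesity risk prediction — with a calibrated synthetic-cohort
generator so the whole pipeline runs and is testable without any
access-restricted genotype data.

## Who this is for

Statistical geneticists and methodologists studying how much of the
phenotypic variance in BMI is captured by (i) an aggregate score over
validated common risk SNPs, (ii) literature-reported common and rare CNVs,
and (iii) their combination, and whether those components add discriminative
value for clinical obesity classification.

## The models

**SNP genetic risk sum score (GRSS).** For subject *s* over *n* catalog SNPs,

```
GRSS_s = ( Σ_i β_i · p_si ) / D
```

where `p_si ∈ [0, 2]` is the expected risk-allele count (an integer from
hard calls or proxy markers, or the probability-weighted dosage
`P(het) + 2·P(hom-risk)` from imputation), `β_i = 1` for *count* scores or
the published per-allele effect size (kg/m² per allele) for *weighted*
scores, and `D` normalises per counted allele (`2n`, hard-call methods) or
per SNP (`n`, probability methods). Six methods are built: {count, weighted}
× {proxy, imputed hard-call, imputed probability}. Missing genotypes are
imputed at the expected dosage `2f` from the sample allele frequency.
Downstream inference is invariant to `D` and to common rescaling of the
weights. Two score methods are compared by
`z = (ES_a − ES_b) / √(SE_a² + SE_b²)`.

**CNV consensus and aggregate scores.** Per-caller calls are filtered at
Log Bayes Factor ≥ 10 (callers without the metric are retained and flagged),
integrated into consensus events requiring ≥ 2 distinct callers at ≥ 50%
reciprocal overlap (connected components of the pairwise-pass relation;
interval = intersection, envelope = union), cleansed of artifact-prone
regions (any 1-bp overlap with the exclusion BED), and matched to a
literature catalog of BMI/obesity CNV regions at ≥ 40% reciprocal overlap
with matching state. Regions with carrier frequency ≥ 1% are common, else
rare. Aggregates: per-class catalog-region counts (CNV-GRSS), a ≥ 100-kb
restricted variant, and the genome-wide rare-event burden.

**Association and prediction.** OLS models of BMI on centered covariates
(sex, age, alcohol/nicotine dependence, ancestry-informative PCs), then the
GRSS and CNV carrier terms; covariate × predictor interactions are screened
one at a time at a Bonferroni threshold of 0.002; nested models are compared
by F-test and incremental R². Logistic models of the nested predictor sets
yield predicted probabilities whose discrimination of the cumulative
bodyweight classes (BMI ≥ 25/30/35/40) is measured by the Mann–Whitney AUC,
with placement-based (DeLong-type) variances for confidence intervals and
paired curve-difference tests, reported as ΔAUC and %ΔAUC against the
previous model.

## Worked example

```
snpcnv --seed 7 --out-dir demo simulate   # 2348 subjects, 32 SNPs, 84 CNV regions
snpcnv --seed 7 --out-dir demo qc
snpcnv --seed 7 --out-dir demo score
snpcnv --seed 7 --out-dir demo cnv
snpcnv --seed 7 --out-dir demo associate
snpcnv --seed 7 --out-dir demo predict
snpcnv --seed 7 --out-dir demo report
```

The `associate` stage prints

```
Model 1 R2=0.1024; Model 2 R2=0.1355; F(2,2315)=44.27, p=1.35e-19
```

— the covariate-only model explains 10.2% of BMI variance in this cohort;
adding the weighted probability GRSS and the common-deletion carrier term
raises it to 13.5%, a significant improvement by the nested F-test. (The
generator assigns covariates 8.3%, the score 3.1% and the deletion 0.1% of
variance in expectation; single-cohort estimates scatter around those
targets.) The `predict` stage prints the Table-style ROC report, e.g. for
the overweight outcome:

```
   outcome                 model      auc   ci_low  ci_high  ...  delta_auc  pct_delta_auc  p_delta_auc
overweight         1. Covariates 0.645857 0.621594 0.670120  ...        NaN            NaN          NaN
overweight 2. Model 1 + SNP-GRSS 0.681337 0.658079 0.704595  ...   0.035479       5.493392     0.000022
overweight      3. Model 2 + CNV 0.683716 0.660589 0.706843  ...   0.002379       0.349184     0.252611
```

— the SNP score significantly improves discrimination over covariates alone
(ΔAUC 0.035, p = 2×10⁻⁵); the CNV terms add little for this outcome. The
`report` stage condenses the run:

```
{
 "model1_r2": 0.1024,
 "model2_r2": 0.1355,
 "incremental_r2": 0.0331,
 "max_auc": 0.8075,
 "cnv": {"consensus_events": 1407, "assigned_events": 1407,
         "n_common_regions": 5, "n_rare_regions": 79}
}
```

Every stage writes its resolved configuration (including the seed) next to
its outputs; re-running with the same seed reproduces every file byte for
byte.

## Layout

```
src/snpcnv/
  io.py           formats (VCF/BED/TSV), run config, logging
  simulate.py     synthetic cohort generator (the study-structure emulator)
  qc.py           BMI computation, exclusion rules, bodyweight classes
  grss.py         the six SNP risk scores and effect-size comparison
  cnv.py          consensus, filtering, catalog match, CNV scores, burden
  association.py  OLS/logistic fits, interaction scan, nested tests, chi-square
  prediction.py   AUC, DeLong-type CIs and paired ROC comparisons
  cli.py          the `snpcnv` subcommands chaining the stages
docs/methods.md   model assumptions, calibration, numerical choices
```
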