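# cpeparch

Tools for studying the genetic architecture of **persistent C-peptide
secretion in type 1 diabetes**. Many people with clinically diagnosed type 1
diabetes retain measurable endogenous insulin secretion — detectable serum
C-peptide — for decades, and the degree of persistence depends on age at
onset, diabetes duration, and genetics. This package implements, as a tested
reusable pipeline, the analysis components such a study needs:

- **LD-adjusted genotypic risk scores from GWAS summary statistics.**
  Diabetes-associated SNPs are filtered (p < 1e-5, MAF >= 0.02, imputation
  info >= 0.7) and partitioned into locus-specific regions (single-linkage
  chains with < 1 Mb gaps containing a lead SNP with p < 1e-6) plus a
  residual genome-wide set. Within each region the univariate coefficient
  vector *b* is premultiplied by the Moore–Penrose generalized inverse of the
  SNP correlation matrix *R* estimated in a reference panel, *w = R⁺b*,
  approximating the multivariate regression weights; per-individual scores
  are dosage dot-products, scaled to unit SD per locus and standardized
  against an external reference cohort genome-wide. The HLA region can be
  excluded (e.g. from the type 2 diabetes score).
- **HLA serotype scoring.** Imputed DRB1/DQB1 four-digit alleles are grouped
  (DR3: DRB1\*0301–0304; DR4: DRB1\*0401–0413; DQ8: DQB1\*0302–0305) into six
  serotype genotypes (DR3/DR4-DQ8, DR3/DR3, DR4-DQ8/DR4-DQ8, DR4-DQ8/X,
  DR3/X, X/X) with configurable risk weights, and the HLA-region polygenic
  score is residualized on the serotype score ("HLA residual" score).
- **Cohort analysis.** log10 transform of C-peptide with censoring to zero
  below the 3 pmol/l detection limit; autoantibody positivity (GAD > 11,
  IA2 > 7.5 WHO units/ml, ZnT8 > 65 up to age 30 at sampling and > 9.1
  above); the "possible type 2" rule (C-peptide > 600 pmol/l and all
  antibodies negative); prevalence cross-tabulations with margins; the
  centred interaction regression of log C-peptide on glucose, √(age at
  onset), sex, duration, BMI and the genotypic scores; and a 2-D LOESS
  surface of geometric-mean C-peptide over (onset, duration).
- **Linear mixed models.** VanRaden genomic relationship matrix, REML SNP
  heritability h² = σ²g/(σ²g+σ²e) profiled on the GRM eigenbasis, and
  efficient-score association scans (1-df chi-square at the fitted null, no
  per-SNP refitting), with a Manhattan-plot helper.
- **A synthetic-data generator** producing reference panel, external
  case-control GWAS, cohort with full-sib pairs, HLA calls and phenotypes
  with recorded ground truth, so every estimator is covered by
  parameter-recovery tests (individual-level data of the motivating cohort
  are not publicly deposited).

The fit/transform-shaped pieces are exposed as sklearn-style estimators
(`GenotypicScore`, `LinearMixedModel`, `CPeptideRegression`) over thin
functional wrappers.

## Worked example

```python
import numpy as np
from cpeparch import (SyntheticConfig, simulate_study, filter_snps,
                      designate_loci, build_score_table,
                      prevalence_by_onset_duration, compute_grm, reml_fit)

cfg = SyntheticConfig(seed=42, n_cohort=1000, h2_cpep=0.26)
study = simulate_study(cfg)

filtered = filter_snps(study.sumstats_t1, study.snp_meta)
loci, residual = designate_loci(filtered)
print(f"type 1 loci: {len(loci)}, residual SNPs: {len(residual)}")

scores = build_score_table(study.sumstats_t1, loci, residual,
                           study.reference, study.cohort)
r = np.corrcoef(scores["genomewide_score"],
                study.cohort.dosages @ study.truth.causal_t1)[0, 1]
print(f"genome-wide score vs true genetic risk: r = {r:.2f}")

table = prevalence_by_onset_duration(study.phenotypes).with_margins()
print(table.to_frame(formatted=True).iloc[:, [0, 3, 4]])

grm = compute_grm(study.cohort.dosages)
ph = study.phenotypes
X = np.column_stack([np.ones(len(ph)), ph["duration"],
                     np.sqrt(ph["age_onset"]),
                     (ph["sex"] == "female").astype(float)])
est = reml_fit(ph["true_log10_cpep"].to_numpy(), X, grm)
print(f"REML h2 = {est.h2:.2f} (SE {est.se:.2f});"
      f" generating h2 = {study.truth.h2_realized:.2f}")
```

prints

```
type 1 loci: 4, residual SNPs: 0
genome-wide score vs true genetic risk: r = 0.97
age_onset       0 to 15   35 or more           All
duration
0 to 5         100% 5/5     100% 4/4    100% 21/21
5 to 10       70% 31/44   100% 41/41   89% 134/150
10 to 15      56% 31/55   100% 49/49   83% 150/180
15 or more   34% 67/200   58% 90/154   45% 293/649
All         44% 134/304  74% 184/248  60% 598/1000
REML h2 = 0.22 (SE 0.04); generating h2 = 0.26
```

The score built purely from simulated summary statistics tracks the true
genetic risk (r = 0.97); detectable C-peptide falls with duration and rises
with age at onset, as in real cohorts; and the mixed model recovers the
generating heritability within its standard error.

A command-line interface mirrors the pipeline stages:

```sh
cpeparch simulate --seed 1 --out study/
cpeparch score-build --sumstats study/sumstats_t2.tsv --meta study/snp_meta.tsv \
    --exclude-region 6:25000000-34000000 --out loci_t2/
cpeparch score-apply --sumstats study/sumstats_t2.tsv --loci loci_t2/ \
    --ref-vcf study/reference.vcf --cohort-vcf study/cohort.vcf --out scores.tsv
cpeparch hla-score --serotypes study/hla_calls.tsv \
    --weights config/serotype_weights_synthetic.yaml --out serotypes.tsv
cpeparch cohort-analyze --phenotypes study/phenotypes.tsv --out analysis/
cpeparch lmm-fit --phenotypes study/phenotypes.tsv --pheno-col true_log10_cpep \
    --covariates duration --vcf study/cohort.vcf --out h2.json
```

The shipped serotype weight file is a clearly labelled synthetic placeholder;
supply published weights for real analyses.

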