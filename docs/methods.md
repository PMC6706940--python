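# Methods

This note documents the statistical models the package implements, the
conventions chosen where more than one was defensible, and what the
synthetic-data generator does and does not emulate.

## Genotypic scores from summary statistics

**Filtering.** Summary-statistic records are kept when p < 1e-5 (strict, the
threshold itself is excluded), MAF >= 0.02 and imputation info >= 0.7
(records are dropped when *below* these cutoffs). A record without MAF/info
metadata is a hard error naming the SNPs, never a silent drop.

**Locus designation.** Filtered SNPs are sorted per chromosome and chained
by single linkage: a gap of >= 1 Mb between consecutive SNPs starts a new
cluster (equivalently, clusters are the connected components of the
"distance < 1 Mb on the same chromosome" graph — the test suite checks this
equivalence against an all-pairs union-find oracle). A cluster becomes a
locus only if it contains a lead SNP with p < 1e-6; all other filtered SNPs
form the residual genome-wide set. The locus/residual split is always a
partition of the filtered SNPs, and clustering is input-order invariant.
Raising the gap can only merge clusters, never split them.

**Coordinates** are 1-based; exclusion intervals (e.g. the extended HLA
region, chr6:25–34 Mb, removed from the type 2 genome-wide score) are closed
at both ends, following VCF convention.

**Allele harmonization.** Summary statistics are matched to genotype data on
chromosome + position + allele pair; when effect and other allele are
swapped the coefficient sign is flipped; strand-ambiguous A/T and C/G SNPs
and allele mismatches are dropped with a warning. This is the conservative
standard when strand information is unavailable.

**LD adjustment.** For each SNP set, w = R⁺ b, where R is the sample Pearson
correlation matrix of reference-panel dosages (pairwise-complete when
dosages are missing) and R⁺ its generalized inverse computed by symmetric
eigendecomposition with a relative eigenvalue cutoff of 1e-6 times the
largest eigenvalue. The cutoff makes the operation deterministic and
well-defined on rank-deficient panels (perfectly duplicated SNPs share the
weight: for two copies with equal betas each gets b/2). Constant SNPs in the
panel receive weight zero with a warning. On full-rank instances with
b = R w_true the procedure recovers w_true to machine precision; this is the
sense in which the weights approximate multivariate regression coefficients.
Recovery degrades, by design of the cutoff, when R is nearly singular — the
truncated directions are exactly those the reference panel cannot estimate.

**Scores.** score_i = Σ_j dosage_ij · w_j, with missing dosages mean-imputed
from the cohort allele frequency. Dosages are used as-is (no rounding to
hard calls). Locus scores are divided by their sample SD (ddof = 1) in the
analysis cohort — whether the original platform used cohort or panel SD is
not documented, so the cohort convention is used and exposed as an argument.
The genome-wide score is the sum of locus scores and the residual score
*before* any standardization, then centred and scaled by the mean/SD of an
external reference cohort (emulating standardization against a large
population biobank).

## HLA serotypes

DRB1\*0301–0304 count as DR3, DRB1\*0401–0413 as DR4, DQB1\*0302–0305 as
DQ8 (four-digit codes compared as integers). Because imputed per-locus
calls are effectively unphased, DR4-DQ8 status is evaluated at genotype
level: the number of DR4-DQ8 haplotype copies claimed is
min(#DR4, #DQ8) by default (`strict_dq8=True`); the relaxed alternative
(#DR4 copies whenever any DQ8 is present) is available because the published
grouping does not pin down the two-DR4/one-DQ8 corner case. Group
assignment: two DR3 alleles → DR3/DR3 (regardless of DQB1); one DR3 plus a
DR4-DQ8 copy → DR3/DR4-DQ8; two DR4-DQ8 copies → DR4-DQ8/DR4-DQ8; one →
DR4-DQ8/X; a lone DR3 → DR3/X; otherwise X/X. A DR4 allele without DQ8
support never counts as DR4-DQ8. The map is total, deterministic and
invariant to allele order; the tests enumerate it exhaustively against an
independent rule oracle.

Serotype group weights are configuration (YAML): the published weights are
not redistributed with this package, and the shipped file is a synthetic
placeholder that only preserves the qualitative risk ordering. The
"HLA residual" score is the OLS residual of the HLA-region polygenic score
on (1, serotype score); it has mean zero and is numerically orthogonal to
the serotype score, isolating HLA-region effects not explained by classical
serotype.

## Cohort analysis

**Transforms.** C-peptide (pmol/l) is analysed as log10, with values below
the assay lower limit of detection (default 3 pmol/l) set to 0 on the log
scale. This censor-to-zero convention follows the motivating analysis; note
it makes OLS a biased estimator of the uncensored generative model when the
censored fraction is large (see *Synthetic data* below). Age at onset enters
models through its square root.

**Antibody positivity** uses the assay 97.5th reference percentiles: GAD 11
and IA2 7.5 WHO units/ml; ZnT8 65 up to age 30 at sampling and 9.1 above 30.
Titres strictly above threshold are positive. An individual is
**possible type 2** when C-peptide is strictly greater than 600 pmol/l and
all three antibodies are negative; everyone else is definite type 1.
Records with missing titres are flagged and left unclassified, never
silently assigned.

**Tabulation.** Onset bins [0,15), [15,25), [25,35), [35,∞) and duration
bins [0,5), [5,10), [10,15), [15,∞) are half-open left-closed (the printed
labels "0 to 15"/"15 to 25" overlap, so a convention had to be chosen);
C-peptide bins are right-closed as printed: [0,30], (30,200], (200,600],
(600,7000]. Percentages are rounded half away from zero to integers,
matching the printed style. "All" margins are sums of the stratum
numerators/denominators and are asserted consistent on every construction.

**Regression.** OLS of log10 C-peptide on: plasma glucose > 5 mmol/l
(indicator), √onset, female sex, duration, the two standardized genome-wide
scores, BMI, and the interactions of √onset with sex, duration, both scores
and BMI. Every covariate is mean-centred *before* interactions are formed,
so each main effect is the predicted effect at the mean of the other
covariates, and interaction estimates are invariant to location shifts of
the covariates (tested). Glucose is dichotomized at 5 mmol/l by default
(8 mmol/l, mentioned elsewhere as an alternative, is available via
`glucose_cut`). A rank-deficient design raises an error naming the collinear
terms. Possible-type-2 individuals are excluded by default when antibody
data allow classification.

**LOESS surface.** Geometric-mean C-peptide over the (onset, duration) plane
is a degree-2 local polynomial fit of log10 C-peptide with tricube weights
over the nearest `span` (default 0.25) fraction of points, distances
Euclidean on unit-SD-standardized predictors, evaluated on a grid and
back-transformed by 10^fit. No installed Python package provides 2-D local
polynomial regression, so it is implemented here and validated by local
polynomial exactness (constant and planar data are reproduced exactly) and
by monotonicity on monotone truth. A span too small for the polynomial
degree is an error.

## Linear mixed models

**GRM.** VanRaden form: columns of the dosage matrix are centred at 2p̂ and
scaled by √(2p̂(1−p̂)) at the sample allele frequency; K = ZZᵀ/m over the m
polymorphic SNPs (monomorphic SNPs are skipped with a warning). K is
validated symmetric and PSD up to −1e-8 × the largest eigenvalue; the
eigendecomposition is cached on the GRM object.

**REML.** Model y = Xβ + g + e with g ~ N(0, σ²g K), e ~ N(0, σ²e I).
On the eigenbasis of K the restricted likelihood profiles analytically over
the total variance, leaving a 1-parameter problem in h² = σ²g/(σ²g+σ²e)
solved by bounded Brent search on [0,1] (each evaluation O(n)), followed by
a short Newton polish for interior optima. The restricted likelihood
includes the |XᵀX| term, making it invariant to reparameterisation of the
fixed-effect basis. The standard error of h² comes from the numerical
curvature of the profile restricted likelihood; non-convergence is flagged
on the returned estimate, never silent. With no covariates the criterion
reduces to the marginal likelihood (used by the 2×2 closed-form test).

**Score tests.** Genome-wide association uses the 1-df efficient score at
the fitted null: for SNP g, stat = (gᵀPy)²/(gᵀPg) with
P = V̂⁻¹ − V̂⁻¹X(XᵀV̂⁻¹X)⁻¹XᵀV̂⁻¹, p-values from chi-square(1). The null
model is fitted once; all per-SNP work is matrix algebra on the rotated
data. With an identity GRM the statistic reduces exactly to the ordinary
linear-regression score test (tested to 1e-6). Statistics are invariant to
phenotype shift, and p-values to phenotype scale. Zero-variance SNPs come
back as NaN with a warning. P-values are asymptotic; no saddlepoint
correction is applied (Gaussian trait).

## Synthetic data

The generator emulates the data layers the analysis consumes, with every
generative parameter recorded for recovery tests.

- **Genotypes**: two haplotypes per individual; within a locus each
  haplotype is a stationary two-state Markov chain with P(allele) = MAF and
  transition probabilities chosen so corr(site i, site j) = ld_decay^|i−j|
  exactly (AR(1) LD with a closed-form target). MAF is drawn per locus,
  uniform on `maf_range` (default 0.08–0.5, inside the 0.02 filter floor),
  and shared by the SNPs of that locus — a binary chain cannot hit an
  arbitrary common correlation across unequal marginals. Null/residual SNPs
  are independent with per-SNP MAFs. Loci sit > 1 Mb apart so designation
  is unambiguous; locus 0 plays the HLA region (chr6:32 Mb) and carries
  effects on both diabetes types. Dosages are hard calls in {0,1,2}.
- **Relatedness**: a configurable fraction (default 10%) of cohort
  individuals are full-sib pairs (expected kinship 0.25): both sibs draw one
  of each parent's haplotypes, independently per locus.
- **External GWAS**: an independent sample of configurable size (default
  8000); liability = dosages · causal effects + standard normal noise; cases
  are the top half of liability (liability-threshold case-control design,
  matching the meta-analyses real scores are built from). Per-SNP summary
  statistics are univariate linear regressions of case status on dosage.
  Null SNP p-values are uniform, and power matches the analytic
  chi-square(1) noncentrality with the √(2/π) biserial attenuation of a
  median threshold (both tested).
- **HLA calls** are drawn from a small haplotype table with the classical
  DR3 and DR4-DQ8 haplotypes at elevated frequency, as in a type 1 diabetes
  cohort; HLA is drawn independently of the SNP genotypes and of sib
  structure.
- **Phenotypes**: log10 C-peptide = intercept + centred linear predictor
  with the interaction-model coefficients (defaults are the motivating
  study's published estimates, e.g. +0.11 per √year of onset, −0.03 per year
  of duration) + a small serotype term + a polygenic value built from the
  standardized cohort genotypes and scaled so the genetic share of the
  residual variance equals `h2_cpep` (default 0.26) + Gaussian noise
  (residual SD 0.4). The intercept default 0.6 (median ~4 pmol/l) makes
  roughly half of the simulated values fall below the 3 pmol/l detection
  limit, matching the emulated cohort's overall detectable fraction.
  Age at onset and duration are log-normal with median 21 years and the
  published interquartile spread; glucose is log-normal with ~90% above
  5 mmol/l; antibody titres are log-normal with a duration-declining mean so
  positivity falls with duration. Censored values are stored as 0 with a
  below-detection flag.

**What the generator does not emulate**: realistic human LD maps, haplotype
phasing, population structure and ancestry, genotyping batch effects,
ascertainment of cases by clinical diagnosis, or the joint dependence of
antibody titres on C-peptide (only the duration trend is modelled). Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to these real-data complications.

## Problem sizes and numerical choices

- Recovery of the interaction-regression coefficients is asserted within
  2 SE at n = 5000 in a *low-censoring* configuration (intercept 2.0,
  detection limit effectively zero): with heavy censoring the
  censor-to-zero OLS is intentionally biased relative to the uncensored
  generative model, which is a property of the published transform, not a
  defect of the fit. The zero-noise configuration recovers coefficients to
  1e-8.
- REML recovery uses 50 phenotype replicates (genetic values drawn through
  the GRM factor at h² = 0.5, fresh noise) over one fixed 2000-individual,
  2000-SNP genotype sample with 10% sib pairs; the mean estimate is asserted
  within ±0.05. Genotype-level variation is exercised separately at smaller
  sizes.
- Generalized-inverse cutoff 1e-6 (relative); REML search tolerance 1e-10
  with Newton polish; GRM PSD tolerance −1e-8 relative; orthogonality of the
  HLA residual asserted at 1e-10.
- Determinism: every stochastic routine takes a numpy Generator or derives
  one from `SyntheticConfig.seed` plus a fixed per-role salt, so identical
  configs give bit-identical studies.

## Known limitations

- The score pipeline assumes additive effects within loci; dominance and
  epistasis are not captured (a property of the w = R⁺b approximation).
- Binary-trait (logistic) mixed models, exact small-sample tests and
  proxy-SNP lookup for missing variants are out of scope.
- The LOESS implementation is O(grid × n) per evaluation and intended for
  desk-scale smoothing, not large grids over millions of points.
- Serotype weights must be supplied by the user for real analyses; the
  shipped YAML is synthetic.
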