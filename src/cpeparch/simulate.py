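"""Synthetic study generator with recorded ground truth.

Emulates the data layers the analysis consumes, none of which are publicly
deposited for the real cohort: a genotype reference panel, an external
case-control GWAS from which summary statistics are derived, a study cohort
with relatedness (full-sib pairs), imputed HLA DRB1/DQB1 alleles, and clinical
phenotypes including a detection-limit-censored C-peptide measurement and
islet autoantibody titres.

Genotypes are simulated as two independent haplotypes per individual.  Within
a locus, each haplotype is a stationary two-state Markov chain whose
transition probabilities are chosen so that the correlation between sites at
lag ``k`` is exactly ``ld_decay**k`` (a first-order autoregressive LD
structure with a closed-form target the tests can assert).  SNPs in different
loci, and the scattered null SNPs, are independent.

Every generative parameter is recorded in :class:`SyntheticTruth` so recovery
tests can assert against known values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

#: Generative coefficients of the C-peptide interaction model: regression of
#: log10 C-peptide on mean-centred covariates.  Scores are on the standardized
#: (unit SD) scale; onset enters through its square root.
DEFAULT_CPEPTIDE_COEFFS = {
    "glucose_gt5": 0.0066,
    "sqrt_onset": 0.11,
    "female": -0.074,
    "duration": -0.03,
    "t1_score": -0.04,
    "t2_score": 0.024,
    "bmi": 0.0031,
    "sqrt_onset:female": -0.079,
    "sqrt_onset:duration": -0.0089,
    "sqrt_onset:t1_score": -0.0087,
    "sqrt_onset:t2_score": 0.0042,
    "sqrt_onset:bmi": 0.0044,
}

# (drb1, dqb1, frequency): small haplotype table used to draw HLA alleles.
# Includes the classical DR3 (0301-0201) and DR4-DQ8 (04xx-0302) risk
# haplotypes at elevated frequency, as expected in a type 1 diabetes cohort.
_HLA_HAPLOTYPES = [
    ("0301", "0201", 0.17),
    ("0401", "0302", 0.13),
    ("0404", "0302", 0.04),
    ("0405", "0301", 0.02),
    ("0701", "0202", 0.13),
    ("1501", "0602", 0.12),
    ("1101", "0301", 0.10),
    ("1301", "0603", 0.09),
    ("0101", "0501", 0.10),
    ("0801", "0402", 0.05),
    ("1601", "0502", 0.05),
]

_UNAMBIGUOUS_ALLELE_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Counts must be positive; ``maf_range`` must lie inside [0.02, 0.5] so
    every generated SNP survives the downstream MAF >= 0.02 filter;
    ``ld_decay`` in [0, 1); ``h2_cpep`` in [0, 1] is the target SNP
    heritability of the covariate-adjusted log10 C-peptide (genetic share of
    the residual variance ``resid_sd**2``); ``lod`` is the assay's lower
    limit of detection in pmol/l.
    """

    n_ref: int = 500
    n_gwas: int = 8000
    n_cohort: int = 2000
    n_snps_per_locus: int = 8
    n_loci: int = 8
    n_null_snps: int = 60
    maf_range: tuple = (0.08, 0.5)
    ld_decay: float = 0.7
    h2_cpep: float = 0.26
    beta_table: dict = field(default_factory=lambda: dict(DEFAULT_CPEPTIDE_COEFFS))
    intercept: float = 0.6
    resid_sd: float = 0.4
    lod: float = 3.0
    sib_fraction: float = 0.1
    gwas_prevalence: float = 0.5
    serotype_onset_effect: float = -0.08
    serotype_cpep_effect: float = -0.02
    low_info_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_ref": self.n_ref, "n_gwas": self.n_gwas,
            "n_cohort": self.n_cohort, "n_snps_per_locus": self.n_snps_per_locus,
            "n_loci": self.n_loci,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if self.n_null_snps < 0:
            raise ConfigurationError("n_null_snps must be >= 0")
        lo, hi = self.maf_range
        if not (np.isfinite(lo) and np.isfinite(hi) and 0.02 <= lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within [0.02, 0.5], got {self.maf_range}")
        if not (np.isfinite(self.ld_decay) and 0.0 <= self.ld_decay < 1.0):
            raise ConfigurationError(f"ld_decay must be in [0, 1), got {self.ld_decay}")
        if not (np.isfinite(self.h2_cpep) and 0.0 <= self.h2_cpep <= 1.0):
            raise ConfigurationError(f"h2_cpep must be in [0, 1], got {self.h2_cpep}")
        if not np.isfinite(self.resid_sd) or self.resid_sd < 0:
            raise ConfigurationError("resid_sd must be finite and >= 0")
        if not np.isfinite(self.lod) or self.lod <= 0:
            raise ConfigurationError("lod must be finite and > 0")
        if not (0.0 <= self.sib_fraction < 1.0):
            raise ConfigurationError("sib_fraction must be in [0, 1)")
        if not (0.0 < self.gwas_prevalence < 1.0):
            raise ConfigurationError("gwas_prevalence must be in (0, 1)")
        for k, v in self.beta_table.items():
            if not np.isfinite(v):
                raise ConfigurationError(f"beta_table[{k!r}] is not finite")


@dataclass
class SyntheticTruth:
    """Recorded generative parameters recovery tests assert against."""

    causal_t1: np.ndarray
    causal_t2: np.ndarray
    locus_membership: pd.Series  # snp_id -> locus label ("" for residual/null set)
    regression_truth: dict
    intercept: float
    h2_target: float
    h2_realized: Optional[float] = None


@dataclass
class GenotypeData:
    """Dosage matrix (individuals x SNPs) plus SNP metadata."""

    dosages: np.ndarray
    meta: pd.DataFrame  # snp_id, chrom, pos, effect_allele, other_allele, maf, info, locus
    ids: list
    sib_pairs: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


def _rng_for(config: SyntheticConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(salt)])


def make_snp_map(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the fixed genome: SNP positions, alleles, MAFs, info scores and
    causal effects shared by the reference panel, external GWAS and cohort.

    Locus 0 plays the role of the HLA region (chr6:32Mb) and carries causal
    effects on both diabetes types; the remaining loci are split between a
    type 1 and a type 2 set.  Null SNPs are scattered with >1 Mb spacing so
    locus designation is unambiguous.
    """
    rng = _rng_for(config, 0)
    rows = []
    chrom_cycle = [c for c in range(1, 23) if c != 6]
    for locus in range(config.n_loci):
        maf = rng.uniform(*config.maf_range)
        if locus == 0:
            chrom, base = "6", 32_000_000
        else:
            chrom = str(chrom_cycle[(locus - 1) % len(chrom_cycle)])
            base = 50_000_000 + 12_000_000 * ((locus - 1) // len(chrom_cycle))
        for j in range(config.n_snps_per_locus):
            ea, oa = _UNAMBIGUOUS_ALLELE_PAIRS[rng.integers(len(_UNAMBIGUOUS_ALLELE_PAIRS))]
            rows.append({
                "snp_id": f"rs{locus:02d}{j:03d}",
                "chrom": chrom, "pos": base + 5_000 * j,
                "effect_allele": ea, "other_allele": oa,
                "maf": maf, "locus": f"L{locus:02d}",
            })
    for j in range(config.n_null_snps):
        chrom = str((j % 22) + 1)
        ea, oa = _UNAMBIGUOUS_ALLELE_PAIRS[rng.integers(len(_UNAMBIGUOUS_ALLELE_PAIRS))]
        rows.append({
            "snp_id": f"rsnull{j:03d}",
            "chrom": chrom, "pos": 100_000_000 + 2_000_000 * (j // 22),
            "effect_allele": ea, "other_allele": oa,
            "maf": rng.uniform(*config.maf_range), "locus": "",
        })
    meta = pd.DataFrame(rows)
    m = len(meta)

    info = rng.uniform(0.75, 1.0, size=m)
    low = rng.random(m) < config.low_info_fraction
    info[low] = rng.uniform(0.4, 0.69, size=low.sum())
    meta["info"] = info

    # causal effects on the two liabilities
    causal_t1 = np.zeros(m)
    causal_t2 = np.zeros(m)
    n_t1 = max(1, (config.n_loci + 1) // 2)
    for locus in range(config.n_loci):
        idx = np.flatnonzero(meta["locus"] == f"L{locus:02d}")
        lead = idx[len(idx) // 2]
        lead_beta = rng.uniform(0.3, 0.45) * rng.choice([-1.0, 1.0])
        sec = rng.choice(idx[idx != lead], size=min(2, len(idx) - 1), replace=False)
        on_t1 = locus < n_t1
        on_t2 = (locus >= n_t1) or (locus == 0)  # the HLA-like locus hits both
        for vec, on in ((causal_t1, on_t1), (causal_t2, on_t2)):
            if on:
                vec[lead] = lead_beta if vec is causal_t1 else rng.uniform(0.3, 0.45) * rng.choice([-1.0, 1.0])
                vec[sec] = rng.uniform(0.08, 0.15, size=len(sec)) * rng.choice([-1.0, 1.0], size=len(sec))
        # ensure the lead survives the info filter so the locus stays designatable
        meta.loc[lead, "info"] = max(meta.loc[lead, "info"], 0.9)

    truth = SyntheticTruth(
        causal_t1=causal_t1,
        causal_t2=causal_t2,
        locus_membership=meta.set_index("snp_id")["locus"],
        regression_truth=dict(config.beta_table),
        intercept=config.intercept,
        h2_target=config.h2_cpep,
    )
    return meta, truth


def _haplotype_block(rng: np.random.Generator, n_hap: int, m: int, p: float,
                     r: float) -> np.ndarray:
    """Stationary binary Markov chain: P(h_j=1)=p, corr(h_i, h_j)=r**|i-j|."""
    h = np.empty((n_hap, m), dtype=np.int8)
    h[:, 0] = rng.random(n_hap) < p
    p_stay = p + r * (1.0 - p)   # P(1 | previous 1)
    p_gain = p * (1.0 - r)       # P(1 | previous 0)
    for j in range(1, m):
        pr = np.where(h[:, j - 1] == 1, p_stay, p_gain)
        h[:, j] = rng.random(n_hap) < pr
    return h


def _simulate_haplotypes(config: SyntheticConfig, n_hap: int, meta: pd.DataFrame,
                         rng: np.random.Generator) -> np.ndarray:
    haps = np.empty((n_hap, len(meta)), dtype=np.int8)
    for locus, idx in meta.groupby("locus", sort=False).indices.items():
        idx = np.asarray(idx)
        if locus == "":
            for j in idx:
                haps[:, j] = rng.random(n_hap) < meta["maf"].iloc[j]
        else:
            haps[:, idx] = _haplotype_block(
                rng, n_hap, len(idx), float(meta["maf"].iloc[idx[0]]), config.ld_decay
            )
    return haps


def simulate_genotypes(config: SyntheticConfig, n: int,
                       meta: Optional[pd.DataFrame] = None,
                       rng: Optional[np.random.Generator] = None,
                       sib_fraction: float = 0.0,
                       id_prefix: str = "S") -> GenotypeData:
    """Simulate dosages for ``n`` individuals on the configured SNP map.

    A fraction ``sib_fraction`` of individuals is generated as full-sib pairs
    (expected kinship 0.25): both sibs inherit one of each parent's two
    haplotypes, resampled independently per locus (no recombination within a
    locus).  Returns dosages in {0, 1, 2} as floats plus SNP metadata.
    """
    config.validate()
    if n <= 0:
        raise ConfigurationError(f"n must be > 0, got {n}")
    if meta is None:
        meta, _ = make_snp_map(config)
    if rng is None:
        rng = _rng_for(config, 1)

    n_pairs = int(n * sib_fraction / 2)
    n_unrel = n - 2 * n_pairs
    m = len(meta)

    haps = _simulate_haplotypes(config, 2 * n_unrel + 4 * n_pairs, meta, rng)
    dos = np.empty((n, m), dtype=np.float64)
    dos[:n_unrel] = haps[:2 * n_unrel:2] + haps[1:2 * n_unrel:2]

    sib_pairs = []
    blocks = list(meta.groupby("locus", sort=False).indices.items())
    for p in range(n_pairs):
        base = 2 * n_unrel + 4 * p
        parents = haps[base:base + 4]  # father hap0/1, mother hap0/1
        for c in range(2):
            child = np.empty(m, dtype=np.int8)
            for locus, idx in blocks:
                idx = np.asarray(idx)
                if locus == "":
                    # independent transmission per unlinked SNP
                    pf = rng.integers(0, 2, size=len(idx))
                    pm = rng.integers(0, 2, size=len(idx))
                    child[idx] = parents[pf, idx] + parents[2 + pm, idx]
                else:
                    child[idx] = (parents[rng.integers(0, 2), idx]
                                  + parents[2 + rng.integers(0, 2), idx])
            dos[n_unrel + 2 * p + c] = child
        sib_pairs.append((n_unrel + 2 * p, n_unrel + 2 * p + 1))

    ids = [f"{id_prefix}{i:05d}" for i in range(n)]
    return GenotypeData(dosages=dos, meta=meta.copy(), ids=ids, sib_pairs=sib_pairs)


def simulate_gwas_sumstats(config: SyntheticConfig, truth: SyntheticTruth,
                           meta: Optional[pd.DataFrame] = None,
                           trait: str = "t1",
                           rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate an external case-control GWAS and return per-SNP summary stats.

    Disease liability is linear in the causal dosages plus standard normal
    noise; cases are the top ``gwas_prevalence`` fraction of liability
    (liability-threshold design, matching the case-control meta-analyses the
    real scores are built from).  Each SNP's univariate linear regression of
    case status on dosage yields (beta, se, pvalue).  Monomorphic SNPs are
    excluded with a logged warning.
    """
    if trait not in ("t1", "t2"):
        raise ConfigurationError(f"trait must be 't1' or 't2', got {trait!r}")
    if meta is None:
        meta, _ = make_snp_map(config)
    if rng is None:
        rng = _rng_for(config, 2 if trait == "t1" else 3)

    geno = simulate_genotypes(config, config.n_gwas, meta=meta, rng=rng,
                              id_prefix="G")
    effects = truth.causal_t1 if trait == "t1" else truth.causal_t2
    liability = geno.dosages @ effects + rng.standard_normal(config.n_gwas)
    thr = np.quantile(liability, 1.0 - config.gwas_prevalence)
    y = (liability > thr).astype(float)

    G = geno.dosages
    xm = G.mean(axis=0)
    xc = G - xm
    sxx = (xc ** 2).sum(axis=0)
    poly = sxx > 0
    if not poly.all():
        logger.warning("excluding %d monomorphic SNP(s) from simulated GWAS",
                       (~poly).sum())
    yc = y - y.mean()
    n = len(y)
    beta = np.full(len(meta), np.nan)
    se = np.full(len(meta), np.nan)
    beta[poly] = (xc[:, poly] * yc[:, None]).sum(axis=0) / sxx[poly]
    rss = (yc ** 2).sum() - beta[poly] ** 2 * sxx[poly]
    s2 = rss / (n - 2)
    se[poly] = np.sqrt(s2 / sxx[poly])
    from scipy import stats as sps
    z = beta / se
    pval = 2.0 * sps.norm.sf(np.abs(z))
    # p-values of exactly 0 underflow; clamp into (0, 1]
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    out = meta[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["pvalue"] = pval
    return out[poly].reset_index(drop=True)


def simulate_hla(config: SyntheticConfig, n: int,
                 rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw unphased DRB1/DQB1 allele calls from a small haplotype table."""
    if rng is None:
        rng = _rng_for(config, 4)
    freqs = np.array([f for _, _, f in _HLA_HAPLOTYPES])
    freqs = freqs / freqs.sum()
    picks = rng.choice(len(_HLA_HAPLOTYPES), size=(n, 2), p=freqs)
    drb1 = np.array([[_HLA_HAPLOTYPES[k][0] for k in row] for row in picks])
    dqb1 = np.array([[_HLA_HAPLOTYPES[k][1] for k in row] for row in picks])
    return pd.DataFrame({
        "individual_id": [f"S{i:05d}" for i in range(n)],
        "drb1_1": drb1[:, 0], "drb1_2": drb1[:, 1],
        "dqb1_1": dqb1[:, 0], "dqb1_2": dqb1[:, 1],
    })


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def simulate_phenotypes(config: SyntheticConfig, truth: SyntheticTruth,
                        genotypes: GenotypeData,
                        serotype_scores: np.ndarray,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate clinical phenotypes for the cohort.

    log10 C-peptide = intercept + centred Table-style linear predictor
    (main effects plus sqrt-onset interactions) + serotype term + polygenic
    value scaled to ``h2_cpep`` of the residual variance + Gaussian noise.
    Values whose back-transform falls below ``lod`` are stored as 0 with the
    below-detection flag set.  Autoantibody titres are log-normal with a
    duration-declining mean, so the positive fraction falls with duration.
    """
    config.validate()
    if rng is None:
        rng = _rng_for(config, 5)
    n = genotypes.n
    if len(serotype_scores) != n:
        raise ConfigurationError("serotype_scores length must match genotypes")

    z_sero = _standardize(np.asarray(serotype_scores, dtype=float))

    female = rng.random(n) < 0.5
    ln_onset = rng.normal(math.log(21.0), 0.70, size=n) + config.serotype_onset_effect * z_sero
    age_onset = np.clip(np.exp(ln_onset), 0.5, 70.0)
    duration = np.clip(np.exp(rng.normal(math.log(21.0), 0.70, size=n)), 0.5, 60.0)
    age_sampling = age_onset + duration
    glucose = np.exp(rng.normal(math.log(9.0), 0.45, size=n))
    bmi = rng.normal(26.0, 4.0, size=n)

    g1 = _standardize(genotypes.dosages @ truth.causal_t1)
    g2 = _standardize(genotypes.dosages @ truth.causal_t2)

    def c(x):
        return x - x.mean()

    terms = {
        "glucose_gt5": c((glucose > 5.0).astype(float)),
        "sqrt_onset": c(np.sqrt(age_onset)),
        "female": c(female.astype(float)),
        "duration": c(duration),
        "t1_score": c(g1),
        "t2_score": c(g2),
        "bmi": c(bmi),
    }
    for k in ("female", "duration", "t1_score", "t2_score", "bmi"):
        terms[f"sqrt_onset:{k}"] = terms["sqrt_onset"] * terms[k]

    lin = np.full(n, config.intercept)
    for name, coef in config.beta_table.items():
        if name not in terms:
            raise ConfigurationError(f"unknown beta_table term {name!r}")
        lin = lin + coef * terms[name]
    lin = lin + config.serotype_cpep_effect * z_sero

    var_resid = config.resid_sd ** 2
    if config.h2_cpep > 0 and var_resid > 0:
        u = rng.standard_normal(genotypes.m)
        p = genotypes.meta["maf"].to_numpy()
        Z = (genotypes.dosages - genotypes.dosages.mean(axis=0)) / np.sqrt(2 * p * (1 - p))
        g_raw = Z @ u
        sg = g_raw.std()
        g = (g_raw / sg if sg > 0 else g_raw) * math.sqrt(config.h2_cpep * var_resid)
    else:
        g = np.zeros(n)
    e = rng.standard_normal(n) * math.sqrt((1.0 - config.h2_cpep) * var_resid)

    y = lin + g + e
    ve = e.var()
    vg = g.var()
    truth.h2_realized = vg / (vg + ve) if (vg + ve) > 0 else 0.0

    cpep_true = np.power(10.0, y)
    below = cpep_true < config.lod
    cpeptide = np.where(below, 0.0, cpep_true)

    titres = {}
    for analyte, (a, b, s) in {
        "gad": (1.5, 0.05, 0.8),
        "ia2": (1.3, 0.06, 0.8),
        "znt8": (1.8, 0.05, 0.8),
    }.items():
        titres[analyte] = np.power(10.0, rng.normal(a - b * duration, s))

    return pd.DataFrame({
        "individual_id": genotypes.ids,
        "sex": np.where(female, "female", "male"),
        "age_onset": age_onset,
        "duration": duration,
        "age_sampling": age_sampling,
        "glucose": glucose,
        "bmi": bmi,
        "gad": titres["gad"],
        "ia2": titres["ia2"],
        "znt8": titres["znt8"],
        "cpeptide": cpeptide,
        "cpep_below_lod": below,
        "true_log10_cpep": y,
        "true_genetic": g,
        "true_t1_score": g1,
        "true_t2_score": g2,
    })


@dataclass
class SyntheticStudy:
    """Bundle of all simulated layers plus the recorded truth."""

    config: SyntheticConfig
    snp_meta: pd.DataFrame
    truth: SyntheticTruth
    reference: GenotypeData
    sumstats_t1: pd.DataFrame
    sumstats_t2: pd.DataFrame
    cohort: GenotypeData
    hla: pd.DataFrame
    serotype_scores: np.ndarray
    phenotypes: pd.DataFrame


def simulate_study(config: SyntheticConfig,
                   serotype_weights: Optional[dict] = None) -> SyntheticStudy:
    """Generate the full synthetic study deterministically from the config."""
    from . import hla as hla_mod

    meta, truth = make_snp_map(config)
    reference = simulate_genotypes(config, config.n_ref, meta=meta,
                                   rng=_rng_for(config, 10), id_prefix="R")
    ss1 = simulate_gwas_sumstats(config, truth, meta=meta, trait="t1",
                                 rng=_rng_for(config, 11))
    ss2 = simulate_gwas_sumstats(config, truth, meta=meta, trait="t2",
                                 rng=_rng_for(config, 12))
    cohort = simulate_genotypes(config, config.n_cohort, meta=meta,
                                rng=_rng_for(config, 13),
                                sib_fraction=config.sib_fraction, id_prefix="S")
    hla = simulate_hla(config, config.n_cohort, rng=_rng_for(config, 14))
    weights = serotype_weights or hla_mod.example_weights()
    groups = hla_mod.classify_cohort(hla)
    sero = hla_mod.serotype_score(groups, weights)
    pheno = simulate_phenotypes(config, truth, cohort, sero.to_numpy(),
                                rng=_rng_for(config, 15))
    return SyntheticStudy(config=config, snp_meta=meta, truth=truth,
                          reference=reference, sumstats_t1=ss1, sumstats_t2=ss2,
                          cohort=cohort, hla=hla,
                          serotype_scores=sero.to_numpy(), phenotypes=pheno)
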