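"""LD-adjusted locus-specific genotypic scores from summary statistics.

The vector of univariate per-SNP coefficients from an external GWAS is
premultiplied by the Moore-Penrose generalized inverse of the SNP correlation
matrix estimated in a reference panel, w = R+ b.  The resulting weights
approximate the coefficients a multivariate regression on individual-level
data would give, so that correlated SNPs are not double counted when summed
into a locus score.  Per-individual scores are dosage dot-products; locus
scores are scaled to unit SD in the analysis cohort, genome-wide scores
standardized against an external reference cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import AlignmentError
from .sumstats import LocusDefinition

logger = logging.getLogger(__name__)


@dataclass
class WeightVector:
    """Adjusted per-SNP weights for one locus (or the residual set)."""

    locus_id: str
    snp_ids: list
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snp_ids) != len(self.weights):
            raise AlignmentError("snp_ids and weights differ in length")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weight")


def _pinv_psd(R: np.ndarray, rcond: float) -> np.ndarray:
    """Generalized inverse of a symmetric PSD matrix via eigendecomposition,
    dropping eigenvalues below ``rcond`` times the largest."""
    vals, vecs = linalg.eigh(R)
    cut = rcond * vals.max()
    inv = np.where(vals > cut, 1.0 / np.where(vals > cut, vals, 1.0), 0.0)
    return (vecs * inv) @ vecs.T


def ld_adjust_weights(betas: np.ndarray, ref_genotypes: np.ndarray,
                      rcond: float = 1e-6) -> np.ndarray:
    """Compute w = R+ b from univariate betas and reference-panel dosages.

    ``ref_genotypes`` is individuals x SNPs for the same SNPs, in the same
    order, as ``betas``.  Constant (zero-variance) SNPs get weight 0 with a
    warning; if all SNPs are constant this is an error.
    """
    betas = np.asarray(betas, dtype=float)
    G = np.asarray(ref_genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] != betas.shape[0]:
        raise AlignmentError(
            f"betas ({betas.shape[0]}) and genotype columns ({G.shape}) mismatch")
    if G.shape[0] < 2:
        raise AlignmentError("reference panel needs >= 2 individuals")
    sd = np.nanstd(G, axis=0)
    live = sd > 0
    if not live.any():
        raise AlignmentError("all SNPs constant in the reference panel")
    if not live.all():
        warnings.warn(f"{(~live).sum()} constant SNP(s) receive weight 0",
                      stacklevel=2)
    w = np.zeros_like(betas)
    sub = G[:, live]
    if np.isnan(sub).any():
        R = pd.DataFrame(sub).corr().to_numpy()  # pairwise-complete
    else:
        R = np.corrcoef(sub, rowvar=False)
    R = np.atleast_2d(R)
    w[live] = _pinv_psd(R, rcond) @ betas[live]
    return w


def compute_locus_score(weights: WeightVector, genotypes: np.ndarray,
                        snp_ids: list) -> np.ndarray:
    """score_i = sum_j dosage_ij * w_j over the weight vector's SNPs.

    ``snp_ids`` names the genotype columns; missing dosages (NaN) are
    mean-imputed from the cohort allele frequency.  A weight SNP absent from
    the genotypes is an error listing the missing ids.
    """
    index = {s: j for j, s in enumerate(snp_ids)}
    missing = [s for s in weights.snp_ids if s not in index]
    if missing:
        raise AlignmentError(f"SNPs absent from genotypes: {missing}")
    cols = [index[s] for s in weights.snp_ids]
    G = np.asarray(genotypes, dtype=float)[:, cols]
    if np.isnan(G).any():
        mu = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), mu, G)
    return G @ weights.weights


def scale_scores(scores: np.ndarray, reference: np.ndarray | None = None,
                 center: bool = False) -> np.ndarray:
    """Scale scores to unit SD (locus scores: own cohort SD, no centring) or
    standardize against an external reference cohort (``center=True`` with
    ``reference`` given: subtract reference mean, divide by reference SD)."""
    scores = np.asarray(scores, dtype=float)
    ref = scores if reference is None else np.asarray(reference, dtype=float)
    sd = ref.std(ddof=1)
    if not sd > 0:
        raise AlignmentError("zero-variance reference for scaling")
    if center:
        return (scores - ref.mean()) / sd
    return scores / sd


def combine_scores(locus_scores: pd.DataFrame, residual: np.ndarray) -> np.ndarray:
    """Genome-wide score: elementwise sum of locus scores and the residual
    score, computed before any standardization."""
    residual = np.asarray(residual, dtype=float)
    if len(locus_scores) != len(residual):
        raise AlignmentError("individual sets differ between locus and residual scores")
    return locus_scores.to_numpy(dtype=float).sum(axis=1) + residual


class GenotypicScore(BaseEstimator, TransformerMixin):
    """LD-adjusted genotypic score for one SNP set, sklearn-style.

    Parameters
    ----------
    betas : array of univariate summary-statistic coefficients, aligned to
        the SNP columns passed to :meth:`fit` and :meth:`transform`.
    rcond : relative eigenvalue cutoff of the generalized inverse.

    ``fit(X)`` estimates the SNP correlation matrix from reference-panel
    dosages ``X`` and stores the adjusted weights in ``weights_``;
    ``transform(X)`` returns the per-individual score for cohort dosages.
    """

    def __init__(self, betas=None, rcond: float = 1e-6):
        self.betas = betas
        self.rcond = rcond

    def fit(self, X, y=None):
        if self.betas is None:
            raise ValueError("betas must be set before fit")
        self.weights_ = ld_adjust_weights(np.asarray(self.betas, dtype=float),
                                          X, rcond=self.rcond)
        self.n_features_in_ = len(self.weights_)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise AlignmentError("genotype columns do not match fitted weights")
        if np.isnan(X).any():
            mu = np.nanmean(X, axis=0)
            X = np.where(np.isnan(X), mu, X)
        return X @ self.weights_


def build_score_table(sumstats: pd.DataFrame, loci: list[LocusDefinition],
                      residual: pd.DataFrame, ref_genotypes, cohort_genotypes,
                      standardize_reference: np.ndarray | None = None,
                      rcond: float = 1e-6) -> pd.DataFrame:
    """End-to-end scores for a cohort: per-locus scaled scores, residual
    score, and the genome-wide sum standardized against an external
    reference (the raw genome-wide sum is standardized; the per-locus
    columns are unit-SD in the cohort).

    ``ref_genotypes`` / ``cohort_genotypes`` are :class:`GenotypeData`-like
    objects with ``dosages``, ``meta`` (with snp_id) and ``ids``.
    """
    ss = sumstats.set_index("snp_id")
    ref_ids = list(ref_genotypes.meta["snp_id"])
    coh_ids = list(cohort_genotypes.meta["snp_id"])
    ref_index = {s: j for j, s in enumerate(ref_ids)}

    out = pd.DataFrame(index=pd.Index(cohort_genotypes.ids, name="individual_id"))
    raw_locus = {}
    for locus in loci:
        snps = [s for s in locus.snp_ids if s in ref_index]
        if not snps:
            logger.warning("locus %s has no SNPs in the reference panel; skipped",
                           locus.locus_id)
            continue
        betas = ss.loc[snps, "beta"].to_numpy()
        cols = [ref_index[s] for s in snps]
        w = ld_adjust_weights(betas, ref_genotypes.dosages[:, cols], rcond=rcond)
        wv = WeightVector(locus.locus_id, snps, w)
        raw = compute_locus_score(wv, cohort_genotypes.dosages, coh_ids)
        raw_locus[locus.locus_id] = raw
        out[locus.locus_id] = scale_scores(raw) if raw.std(ddof=1) > 0 else raw

    res_snps = [s for s in residual["snp_id"] if s in ref_index]
    if res_snps:
        betas = ss.loc[res_snps, "beta"].to_numpy()
        cols = [ref_index[s] for s in res_snps]
        w = ld_adjust_weights(betas, ref_genotypes.dosages[:, cols], rcond=rcond)
        wv = WeightVector("residual", res_snps, w)
        res_raw = compute_locus_score(wv, cohort_genotypes.dosages, coh_ids)
    else:
        res_raw = np.zeros(len(out))
    out["residual_score"] = res_raw

    gw = combine_scores(pd.DataFrame(raw_locus, index=out.index), res_raw)
    out["genomewide_score"] = scale_scores(
        gw, reference=standardize_reference, center=True
    ) if standardize_reference is not None else gw
    return out
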