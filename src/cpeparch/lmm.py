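"""Genomic relationship matrix, REML heritability and efficient-score scans.

The model is y = X b + g + e with g ~ N(0, sigma2_g K) for a genomic
relationship matrix K (VanRaden centred/standardized cross-product) and
e ~ N(0, sigma2_e I).  Restricted maximum likelihood is profiled over the
single parameter h2 = sigma2_g / (sigma2_g + sigma2_e) on the eigenbasis of
K, which makes every likelihood evaluation O(n) after one symmetric
eigendecomposition and guarantees a bounded, derivative-free optimisation on
[0, 1].  Genome-wide association is then a 1-df efficient-score test per SNP
at the fitted null covariance — the gradient of the log-likelihood in the
SNP effect evaluated at the null — with p-values from chi-square(1) and no
per-SNP refitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .exceptions import AlignmentError, ConfigurationError

logger = logging.getLogger(__name__)

_PSD_TOL = 1e-8


class GRM:
    """Symmetric genomic relationship matrix with cached eigendecomposition."""

    def __init__(self, values: np.ndarray, ids: Optional[list] = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise AlignmentError("GRM must be square")
        if not np.allclose(values, values.T, atol=1e-10):
            raise AlignmentError("GRM must be symmetric")
        self.values = (values + values.T) / 2.0
        self.ids = list(ids) if ids is not None else [str(i) for i in range(len(values))]
        if len(self.ids) != values.shape[0]:
            raise AlignmentError("ids length does not match GRM dimension")
        self._eig = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eigen(self):
        """(eigenvalues ascending, eigenvectors); validates PSD up to
        -1e-8 x largest eigenvalue and clips small negatives to zero."""
        if self._eig is None:
            vals, vecs = linalg.eigh(self.values)
            vmax = max(vals.max(), 0.0)
            if vals.min() < -_PSD_TOL * max(vmax, 1.0):
                raise AlignmentError(
                    f"GRM is not positive semidefinite (min eigenvalue {vals.min():.3g})")
            self._eig = (np.clip(vals, 0.0, None), vecs)
        return self._eig

    def save(self, prefix) -> None:
        """Write <prefix>.ids.txt (one id per line) and <prefix>.grm.tsv."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{prefix}.ids.txt").write_text("\n".join(self.ids) + "\n")
        np.savetxt(f"{prefix}.grm.tsv", self.values, delimiter="\t", fmt="%.10g")

    @classmethod
    def load(cls, prefix) -> "GRM":
        ids = Path(f"{prefix}.ids.txt").read_text().split()
        values = np.loadtxt(f"{prefix}.grm.tsv", delimiter="\t")
        return cls(np.atleast_2d(values), ids)


def compute_grm(dosages: np.ndarray, ids: Optional[list] = None) -> GRM:
    """VanRaden GRM: K = Z Z' / m with Z the column-standardized dosages,
    standardizing by sqrt(2 p (1-p)) at the sample allele frequency.
    Monomorphic SNPs are skipped with a warning."""
    G = np.asarray(dosages, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise AlignmentError("need >= 2 individuals")
    p = G.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1) & (G.std(axis=0) > 0)
    if not poly.any():
        raise AlignmentError("no polymorphic SNPs")
    if not poly.all():
        logger.warning("skipping %d monomorphic SNP(s) in GRM", int((~poly).sum()))
    Z = (G[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    K = Z @ Z.T / poly.sum()
    return GRM(K, ids)


@dataclass
class HeritabilityEstimate:
    """REML variance components on the h2 = sigma2_g/(sigma2_g+sigma2_e) scale."""

    h2: float
    sigma2_g: float
    sigma2_e: float
    se: float
    converged: bool
    loglik: float

    def __post_init__(self):
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be >= 0")


def _restricted_loglik(h2: float, lam: np.ndarray, yt: np.ndarray,
                       Xt: Optional[np.ndarray]) -> tuple[float, float]:
    """Profile restricted log-likelihood at h2 (total variance profiled out).
    Returns (loglik, sigma2_total_hat).  With no covariates this is the
    marginal (maximum) likelihood."""
    n = len(yt)
    d = h2 * lam + (1.0 - h2)
    d = np.maximum(d, 1e-12)
    logdet_d = float(np.log(d).sum())
    if Xt is None or Xt.shape[1] == 0:
        p = 0
        rss_w = float(np.sum(yt * yt / d))
        logdet_x = 0.0
    else:
        p = Xt.shape[1]
        Xd = Xt / d[:, None]
        XtX = Xt.T @ Xd
        beta = np.linalg.solve(XtX, Xd.T @ yt)
        r = yt - Xt @ beta
        rss_w = float(np.sum(r * r / d))
        sign, logdet_x = np.linalg.slogdet(XtX)
        if sign <= 0:
            raise AlignmentError("rank-deficient covariate matrix")
        # the |X'X| term makes the restricted likelihood invariant to
        # reparameterisation of the fixed-effect basis
        logdet_x -= np.linalg.slogdet(Xt.T @ Xt)[1]
    dof = n - p
    sigma2 = rss_w / dof
    ll = -0.5 * (dof * np.log(sigma2) + logdet_d + logdet_x + dof)
    return ll, sigma2


def reml_fit(y: np.ndarray, X: Optional[np.ndarray], grm: GRM,
             xatol: float = 1e-10) -> HeritabilityEstimate:
    """REML estimate of h2 by bounded scalar optimisation on [0, 1].

    ``X`` is the fixed-covariate design (an intercept is NOT added
    automatically; pass None for no fixed effects).  The standard error comes
    from the numerical curvature of the profile restricted likelihood at the
    optimum.  Non-convergence is flagged, never silent.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != grm.n:
        raise AlignmentError("phenotype length does not match GRM")
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            raise AlignmentError("covariate rows do not match phenotype")
        if len(y) < X.shape[1] + 2:
            raise AlignmentError("need n >= number of covariates + 2")
    lam, U = grm.eigen()
    yt = U.T @ y
    Xt = U.T @ X if X is not None else None

    def neg(h2):
        return -_restricted_loglik(h2, lam, yt, Xt)[0]

    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": xatol})
    converged = bool(res.success)
    if not converged:
        logger.warning("REML optimisation did not converge: %s", res.message)
    h2 = float(np.clip(res.x, 0.0, 1.0))
    # Newton polish on the profile likelihood for interior optima
    for _ in range(3):
        if not 1e-6 < h2 < 1 - 1e-6:
            break
        step = 1e-6
        f0, fp, fm = neg(h2), neg(h2 + step), neg(h2 - step)
        grad = (fp - fm) / (2 * step)
        curv = (fp - 2 * f0 + fm) / step ** 2
        if curv <= 0:
            break
        delta = np.clip(grad / curv, -0.01, 0.01)
        cand = float(np.clip(h2 - delta, 0.0, 1.0))
        if neg(cand) <= f0:
            h2 = cand
    ll, sigma2 = _restricted_loglik(h2, lam, yt, Xt)

    eps = 1e-4
    a, b = max(h2 - eps, 0.0), min(h2 + eps, 1.0)
    mid = (a + b) / 2
    curv = (neg(a) - 2 * neg(mid) + neg(b)) / ((b - a) / 2) ** 2
    se = float(1.0 / np.sqrt(curv)) if curv > 0 else float("nan")

    return HeritabilityEstimate(
        h2=h2, sigma2_g=h2 * sigma2, sigma2_e=(1.0 - h2) * sigma2,
        se=se, converged=converged, loglik=float(ll))


def score_test_scan(y: np.ndarray, X: Optional[np.ndarray], grm: GRM,
                    test_genotypes: np.ndarray,
                    snp_meta: Optional[pd.DataFrame] = None,
                    null: Optional[HeritabilityEstimate] = None) -> pd.DataFrame:
    """1-df efficient-score association test per SNP at the fitted null.

    For each SNP g: stat = (g' P y)^2 / (g' P g) with
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1 and V the null model's fitted
    covariance; p-values from chi-square(1).  Zero-variance SNPs come back
    as NaN with a warning.  The null model is fitted once; no per-SNP
    refitting.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(test_genotypes, dtype=float)
    if G.shape[0] != grm.n or len(y) != grm.n:
        raise AlignmentError("test genotypes / phenotype do not match GRM")
    if null is None:
        null = reml_fit(y, X, grm)
    lam, U = grm.eigen()
    sigma2 = null.sigma2_g + null.sigma2_e
    d = sigma2 * (null.h2 * lam + (1.0 - null.h2))
    d = np.maximum(d, 1e-12 * sigma2)

    yt = U.T @ y
    Gt = U.T @ G
    Gd = Gt / d[:, None]
    if X is not None and np.size(X):
        Xmat = np.atleast_2d(np.asarray(X, dtype=float))
        Xt = U.T @ Xmat
        Xd = Xt / d[:, None]
        XtX = Xt.T @ Xd
        alpha = yt / d - Xd @ np.linalg.solve(XtX, Xd.T @ yt)
        A = Xt.T @ Gd                       # p x m
        var = (Gt * Gd).sum(axis=0) - (A * np.linalg.solve(XtX, A)).sum(axis=0)
    else:
        alpha = yt / d
        var = (Gt * Gd).sum(axis=0)

    score = Gt.T @ alpha
    sd = G.std(axis=0)
    bad = (sd == 0) | (var <= 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance SNP(s): statistic undefined",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(bad, np.nan, score ** 2 / var)
    pval = stats.chi2.sf(stat, df=1)

    out = pd.DataFrame({"score_stat": stat, "pvalue": pval})
    if snp_meta is not None:
        for c in ("snp_id", "chrom", "pos"):
            if c in snp_meta.columns:
                out.insert(0, c, snp_meta[c].to_numpy())
        out = out[[c for c in ("snp_id", "chrom", "pos", "score_stat", "pvalue")
                   if c in out.columns]]
    return out


class LinearMixedModel:
    """sklearn-style estimator for the REML mixed model.

    Parameters: none beyond the optimisation tolerance.  ``fit(X, y, grm=...)``
    estimates the variance components and exposes ``h2_``, ``sigma2_g_``,
    ``sigma2_e_``, ``se_``, ``converged_`` and ``loglik_``;
    ``score_scan(G, snp_meta=None)`` runs the efficient-score GWAS under the
    fitted null.
    """

    def __init__(self, xatol: float = 1e-10):
        self.xatol = xatol

    def get_params(self, deep=True):
        return {"xatol": self.xatol}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, grm: GRM = None):
        if grm is None:
            raise ConfigurationError("fit requires grm=")
        est = reml_fit(np.asarray(y, float),
                       None if X is None else np.asarray(X, float),
                       grm, xatol=self.xatol)
        self.estimate_ = est
        self.h2_ = est.h2
        self.sigma2_g_ = est.sigma2_g
        self.sigma2_e_ = est.sigma2_e
        self.se_ = est.se
        self.converged_ = est.converged
        self.loglik_ = est.loglik
        self._X = None if X is None else np.asarray(X, float)
        self._y = np.asarray(y, float)
        self._grm = grm
        return self

    def score_scan(self, G, snp_meta: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        if not hasattr(self, "estimate_"):
            raise ConfigurationError("call fit before score_scan")
        return score_test_scan(self._y, self._X, self._grm, G,
                               snp_meta=snp_meta, null=self.estimate_)
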