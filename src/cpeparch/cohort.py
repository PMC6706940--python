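"""Clinical cohort analysis: transforms, antibody status, classification,
prevalence tabulation, and the C-peptide interaction regression.

C-peptide (pmol/l) is analysed as log10, with values below the assay's lower
limit of detection (3 pmol/l) set to 0 on the log scale.  Autoantibody
titres are called positive above the assay 97.5th reference percentiles
(GAD 11, IA2 7.5 WHO units/ml; ZnT8 65 up to age 30 at sampling, 9.1 above).
Individuals with C-peptide > 600 pmol/l and no detectable autoantibody are
labelled "possible type 2" (probable misdiagnoses) and excluded from the
regression; everyone else is "definite type 1".

The regression models log10 C-peptide on mean-centred covariates — a plasma
glucose > 5 mmol/l indicator, sqrt(age at onset), female sex, duration, the
two genome-wide genotypic risk scores and BMI — plus interactions of
sqrt(age at onset) with sex, duration, both scores and BMI.  Centring before
forming interactions makes each main effect the predicted effect at the mean
of the other covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .exceptions import AlignmentError, ConfigurationError
from .loess import loess_surface  # re-exported  # noqa: F401

logger = logging.getLogger(__name__)

ANTIBODY_THRESHOLDS = {"GAD": 11.0, "IA2": 7.5}
ZNT8_THRESHOLD_YOUNG = 65.0   # age at sampling <= 30 years
ZNT8_THRESHOLD_OLD = 9.1      # age at sampling > 30 years
ZNT8_AGE_SWITCH = 30.0

DEFAULT_ONSET_BINS = (0.0, 15.0, 25.0, 35.0, np.inf)
DEFAULT_DURATION_BINS = (0.0, 5.0, 10.0, 15.0, np.inf)
DEFAULT_CPEP_EDGES = (0.0, 30.0, 200.0, 600.0, 7000.0)

REGRESSION_TERMS = [
    "glucose_gt5", "sqrt_onset", "female", "duration",
    "t1_score", "t2_score", "bmi",
    "sqrt_onset:female", "sqrt_onset:duration",
    "sqrt_onset:t1_score", "sqrt_onset:t2_score", "sqrt_onset:bmi",
]


def transform_cpeptide(cpeptide, lod: float = 3.0):
    """log10 of detectable C-peptide; 0.0 below the detection limit.

    Monotone non-decreasing on [lod, inf).  Negative concentrations are an
    error.
    """
    x = np.asarray(cpeptide, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative C-peptide concentration")
    out = np.where(x >= lod, np.log10(np.where(x >= lod, x, 1.0)), 0.0)
    return float(out) if np.isscalar(cpeptide) else out


def antibody_positive(analyte: str, titre, age_sampling=None):
    """Titre above the assay's 97.5th reference percentile?

    The ZnT8 threshold is age-dependent (65 WHO units/ml up to age 30 at
    sampling, 9.1 above 30) and requires ``age_sampling``.
    """
    analyte = analyte.upper()
    t = np.asarray(titre, dtype=float)
    if analyte in ANTIBODY_THRESHOLDS:
        thr = ANTIBODY_THRESHOLDS[analyte]
    elif analyte == "ZNT8":
        if age_sampling is None:
            raise ConfigurationError("ZnT8 positivity requires age at sampling")
        age = np.asarray(age_sampling, dtype=float)
        thr = np.where(age > ZNT8_AGE_SWITCH, ZNT8_THRESHOLD_OLD, ZNT8_THRESHOLD_YOUNG)
    else:
        raise ConfigurationError(f"unknown analyte {analyte!r}")
    out = t > thr
    return bool(out) if np.isscalar(titre) else out


def all_antibody_negative(records: pd.DataFrame) -> pd.Series:
    """True where GAD, IA2 and ZnT8 are all below their positivity
    thresholds; NaN-titre rows come back as pandas NA."""
    gad = antibody_positive("GAD", records["gad"])
    ia2 = antibody_positive("IA2", records["ia2"])
    znt8 = antibody_positive("ZnT8", records["znt8"], records["age_sampling"])
    neg = ~(gad | ia2 | znt8)
    has_all = records[["gad", "ia2", "znt8"]].notna().all(axis=1)
    return pd.Series(np.where(has_all, neg, pd.NA), index=records.index, dtype="object")


def classify_possible_t2(records: pd.DataFrame, cpep_cut: float = 600.0) -> pd.Series:
    """Label each record possible_t2 (C-peptide strictly > cpep_cut pmol/l
    and all three autoantibodies negative) or definite_t1.

    Records with a missing titre cannot be classified: they are flagged with
    a warning and labelled NA.
    """
    neg = all_antibody_negative(records)
    n_missing = int(neg.isna().sum())
    if n_missing:
        logger.warning("%d record(s) with missing antibody titres excluded "
                       "from classification", n_missing)
    high = records["cpeptide"].to_numpy(dtype=float) > cpep_cut
    neg_filled = np.array([v is True or v is np.True_ for v in neg], dtype=bool)
    label = np.where(high & neg_filled, "possible_t2", "definite_t1")
    return pd.Series(np.where(neg.isna(), pd.NA, label), index=records.index,
                     name="label", dtype="object")


def _round_half_up(x):
    return np.floor(x + 0.5)


@dataclass
class PrevalenceTable:
    """Numerator/denominator cross-tabulation with printed-style percents."""

    numerators: np.ndarray
    denominators: np.ndarray
    row_labels: list
    col_labels: list
    row_name: str = "row"
    col_name: str = "col"
    _has_margins: bool = field(default=False, repr=False)

    @property
    def percent(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.numerators / self.denominators
        return np.where(self.denominators > 0, _round_half_up(pct), np.nan)

    def with_margins(self) -> "PrevalenceTable":
        """Append an "All" row and column whose cells are sums of the strata."""
        num = np.vstack([self.numerators, self.numerators.sum(axis=0)])
        num = np.hstack([num, num.sum(axis=1, keepdims=True)])
        den = np.vstack([self.denominators, self.denominators.sum(axis=0)])
        den = np.hstack([den, den.sum(axis=1, keepdims=True)])
        return PrevalenceTable(num, den,
                               list(self.row_labels) + ["All"],
                               list(self.col_labels) + ["All"],
                               self.row_name, self.col_name, _has_margins=True)

    def to_frame(self, formatted: bool = False) -> pd.DataFrame:
        if formatted:
            cells = np.empty(self.numerators.shape, dtype=object)
            pct = self.percent
            for i in range(cells.shape[0]):
                for j in range(cells.shape[1]):
                    if self.denominators[i, j] > 0:
                        cells[i, j] = (f"{int(pct[i, j])}% "
                                       f"{int(self.numerators[i, j])}/{int(self.denominators[i, j])}")
                    else:
                        cells[i, j] = ""
            data = cells
        else:
            data = self.percent
        return pd.DataFrame(data, index=pd.Index(self.row_labels, name=self.row_name),
                            columns=pd.Index(self.col_labels, name=self.col_name))


def _bin_labels(edges, closed_right: bool) -> list:
    labels = []
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        if np.isinf(b):
            labels.append(f"{a:g} or more")
        elif closed_right:
            # lowest bin includes its left edge: [a, b]; others are (a, b]
            labels.append(f"[{a:g}, {b:g}]" if i == 0 else f"({a:g}, {b:g}]")
        else:
            labels.append(f"{a:g} to {b:g}")
    return labels


def _tabulate(records: pd.DataFrame, row_values, col_values, success,
              row_edges, col_edges, col_closed_right: bool,
              row_name: str, col_name: str) -> PrevalenceTable:
    row_values = np.asarray(row_values, dtype=float)
    col_values = np.asarray(col_values, dtype=float)
    success = np.asarray(success, dtype=bool)
    ok = np.isfinite(row_values) & np.isfinite(col_values)
    if not ok.all():
        logger.warning("%d record(s) with missing binning variables excluded",
                       int((~ok).sum()))
    row_values, col_values, success = row_values[ok], col_values[ok], success[ok]
    # rows: left-closed [a, b); columns either the same or right-closed (a, b]
    ri = np.searchsorted(row_edges[1:-1], row_values, side="right")
    if col_closed_right:
        ci = np.searchsorted(col_edges[1:-1], col_values, side="left")
        in_range = (col_values >= col_edges[0]) & (col_values <= col_edges[-1])
    else:
        ci = np.searchsorted(col_edges[1:-1], col_values, side="right")
        in_range = (col_values >= col_edges[0]) & (col_values < np.inf)
    if not in_range.all():
        logger.warning("%d record(s) outside the column bin range excluded",
                       int((~in_range).sum()))
        ri, ci, success = ri[in_range], ci[in_range], success[in_range]
    R, C = len(row_edges) - 1, len(col_edges) - 1
    num = np.zeros((R, C))
    den = np.zeros((R, C))
    np.add.at(den, (ri, ci), 1)
    np.add.at(num, (ri, ci), success.astype(float))
    return PrevalenceTable(num, den,
                           _bin_labels(row_edges, False),
                           _bin_labels(col_edges, col_closed_right),
                           row_name, col_name)


def prevalence_by_onset_duration(records: pd.DataFrame,
                                 onset_bins=DEFAULT_ONSET_BINS,
                                 duration_bins=DEFAULT_DURATION_BINS,
                                 lod: float = 3.0) -> PrevalenceTable:
    """Prevalence of detectable C-peptide (>= lod) by age-at-onset column and
    duration row, with half-open left-closed bins."""
    detectable = records["cpeptide"].to_numpy(dtype=float) >= lod
    return _tabulate(records, records["duration"], records["age_onset"], detectable,
                     np.asarray(duration_bins, float), np.asarray(onset_bins, float),
                     col_closed_right=False,
                     row_name="duration", col_name="age_onset")


def abneg_by_duration_cpeptide(records: pd.DataFrame,
                               cpep_edges=DEFAULT_CPEP_EDGES,
                               duration_bins=DEFAULT_DURATION_BINS) -> PrevalenceTable:
    """Proportion negative for all three autoantibodies by duration row and
    C-peptide column; C-peptide bins are right-closed as printed,
    [0, 30], (30, 200], (200, 600], (600, 7000]."""
    neg = all_antibody_negative(records)
    keep = ~neg.isna()
    if (~keep).any():
        logger.warning("%d record(s) with missing titres excluded from tabulation",
                       int((~keep).sum()))
    sub = records[keep]
    return _tabulate(sub, sub["duration"], sub["cpeptide"],
                     neg[keep].astype(bool),
                     np.asarray(duration_bins, float), np.asarray(cpep_edges, float),
                     col_closed_right=True,
                     row_name="duration", col_name="cpeptide")


def _build_design(records: pd.DataFrame, glucose_cut: float) -> pd.DataFrame:
    need = ["glucose", "age_onset", "sex", "duration", "t1_score", "t2_score", "bmi"]
    missing = [c for c in need if c not in records.columns]
    if missing:
        raise AlignmentError(f"phenotype table missing columns: {missing}")
    base = pd.DataFrame(index=records.index)
    base["glucose_gt5"] = (records["glucose"] > glucose_cut).astype(float)
    base["sqrt_onset"] = np.sqrt(records["age_onset"].to_numpy(dtype=float))
    base["female"] = (records["sex"].astype(str).str.lower() == "female").astype(float)
    base["duration"] = records["duration"].astype(float)
    base["t1_score"] = records["t1_score"].astype(float)
    base["t2_score"] = records["t2_score"].astype(float)
    base["bmi"] = records["bmi"].astype(float)
    centred = base - base.mean()
    X = centred.copy()
    for k in ("female", "duration", "t1_score", "t2_score", "bmi"):
        X[f"sqrt_onset:{k}"] = centred["sqrt_onset"] * centred[k]
    return X[REGRESSION_TERMS]


def fit_cpeptide_regression(records: pd.DataFrame,
                            scores: pd.DataFrame | None = None,
                            glucose_cut: float = 5.0, lod: float = 3.0,
                            exclude_possible_t2: bool = True) -> pd.DataFrame:
    """OLS of log10 C-peptide on the centred interaction design.

    ``scores`` (optional) supplies ``t1_score``/``t2_score`` indexed by
    individual_id when the phenotype table does not already carry them.
    Possible-type-2 individuals are excluded before fitting when titres are
    available.  Returns a table (term, estimate, se, pvalue) including the
    intercept; a rank-deficient design is an error naming collinear terms.
    """
    df = records.copy()
    if scores is not None:
        df = df.merge(scores, left_on="individual_id", right_index=True,
                      how="left", validate="one_to_one")
    if exclude_possible_t2:
        if "label" in df.columns:
            labels = df["label"]
        elif {"gad", "ia2", "znt8"}.issubset(df.columns):
            labels = classify_possible_t2(df)
        else:
            labels = pd.Series("definite_t1", index=df.index)
        df = df[labels != "possible_t2"]
    y = transform_cpeptide(df["cpeptide"].to_numpy(dtype=float), lod=lod)
    X = _build_design(df, glucose_cut)
    Xc = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        _, r = np.linalg.qr(Xc.to_numpy())
        bad = [Xc.columns[j] for j in range(Xc.shape[1])
               if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise AlignmentError(f"rank-deficient design; collinear terms: {bad}")
    fit = sm.OLS(y, Xc).fit()
    out = pd.DataFrame({"estimate": fit.params, "se": fit.bse, "pvalue": fit.pvalues})
    out.index.name = "term"
    return out


class CPeptideRegression(BaseEstimator):
    """sklearn-style wrapper for the C-peptide interaction model.

    ``fit(records, scores=None)`` stores the coefficient table in
    ``results_``; ``coef_`` holds the non-intercept estimates in the
    canonical term order and ``rsquared_`` the model fit.
    """

    def __init__(self, glucose_cut: float = 5.0, lod: float = 3.0,
                 exclude_possible_t2: bool = True):
        self.glucose_cut = glucose_cut
        self.lod = lod
        self.exclude_possible_t2 = exclude_possible_t2

    def fit(self, records: pd.DataFrame, scores: pd.DataFrame | None = None):
        self.results_ = fit_cpeptide_regression(
            records, scores, glucose_cut=self.glucose_cut, lod=self.lod,
            exclude_possible_t2=self.exclude_possible_t2)
        self.coef_ = self.results_.loc[REGRESSION_TERMS, "estimate"].to_numpy()
        self.intercept_ = float(self.results_.loc["const", "estimate"])
        return self
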