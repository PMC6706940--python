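"""HLA DRB1/DQB1 serotype grouping, risk score and HLA-residual score.

Four-digit alleles are grouped as DR3 (DRB1 0301-0304), DR4 (DRB1 0401-0413)
and DQ8 (DQB1 0302-0305).  Each genotype is assigned to exactly one of six
serotype groups — DR3/DR4-DQ8, DR3/DR3, DR4-DQ8/DR4-DQ8, DR4-DQ8/X, DR3/X,
X/X — which map to configured risk weights.  DR4-DQ8 status is evaluated at
genotype level because imputed per-locus calls are effectively unphased: the
number of DR4-DQ8 haplotype copies claimed is min(#DR4 DRB1 alleles,
#DQ8 DQB1 alleles) by default (strict), or #DR4 when any DQ8 is present
(``strict_dq8=False``).

The HLA-residual score is the residual of an OLS regression of the
HLA-region polygenic score on the serotype score: the component of HLA
region risk not captured by classical serotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .exceptions import AlleleCodeError, AlignmentError, ConfigurationError

SEROTYPE_GROUPS = ["DR3/DR4-DQ8", "DR3/DR3", "DR4-DQ8/DR4-DQ8",
                   "DR4-DQ8/X", "DR3/X", "X/X"]


@dataclass
class AlleleFlags:
    """Per-genotype counts of DR3/DR4 DRB1 alleles and DQ8 DQB1 alleles."""

    n_dr3: int
    n_dr4: int
    n_dq8: int


def _parse_allele(code: str, individual: str = "?") -> int:
    code = str(code)
    if len(code) != 4 or not code.isdigit():
        raise AlleleCodeError(
            f"individual {individual}: allele code {code!r} is not a 4-digit string")
    return int(code)


def group_alleles(drb1: tuple[str, str], dqb1: tuple[str, str],
                  individual: str = "?") -> AlleleFlags:
    """Flag DR3/DR4/DQ8 membership per allele copy.

    DR3: DRB1 in [0301, 0304]; DR4: DRB1 in [0401, 0413];
    DQ8: DQB1 in [0302, 0305].
    """
    d = [_parse_allele(a, individual) for a in drb1]
    q = [_parse_allele(a, individual) for a in dqb1]
    return AlleleFlags(
        n_dr3=sum(301 <= a <= 304 for a in d),
        n_dr4=sum(401 <= a <= 413 for a in d),
        n_dq8=sum(302 <= a <= 305 for a in q),
    )


def classify_serotype(flags: AlleleFlags, strict_dq8: bool = True) -> str:
    """Map allele flags to one of the six serotype groups.

    Total and deterministic: every genotype maps to exactly one group, and
    the result does not depend on the order of the two alleles at a locus.
    A DR4 allele without DQ8 support does not count as DR4-DQ8 (so one DR3
    plus DR4-without-DQ8 is DR3/X).
    """
    if strict_dq8:
        dr4dq8 = min(flags.n_dr4, flags.n_dq8)
    else:
        dr4dq8 = flags.n_dr4 if flags.n_dq8 >= 1 else 0
    if flags.n_dr3 >= 2:
        return "DR3/DR3"
    if flags.n_dr3 == 1 and dr4dq8 >= 1:
        return "DR3/DR4-DQ8"
    if dr4dq8 >= 2:
        return "DR4-DQ8/DR4-DQ8"
    if dr4dq8 == 1:
        return "DR4-DQ8/X"
    if flags.n_dr3 == 1:
        return "DR3/X"
    return "X/X"


def classify_cohort(calls: pd.DataFrame, strict_dq8: bool = True) -> pd.Series:
    """Vectorised grouping of a serotype-call table (columns individual_id,
    drb1_1, drb1_2, dqb1_1, dqb1_2) -> Series of group labels."""
    labels = []
    for rec in calls.itertuples(index=False):
        flags = group_alleles((rec.drb1_1, rec.drb1_2), (rec.dqb1_1, rec.dqb1_2),
                              individual=str(rec.individual_id))
        labels.append(classify_serotype(flags, strict_dq8=strict_dq8))
    return pd.Series(labels, index=calls["individual_id"].to_numpy(), name="serotype")


def serotype_score(groups: pd.Series, weights: dict) -> pd.Series:
    """Look up the configured risk weight of each individual's group."""
    missing = [g for g in SEROTYPE_GROUPS if g not in weights]
    if missing:
        raise ConfigurationError(f"serotype weights missing groups: {missing}")
    bad = [v for v in weights.values() if not np.isfinite(v)]
    if bad:
        raise ConfigurationError("serotype weights must be finite")
    unknown = set(groups.unique()) - set(SEROTYPE_GROUPS)
    if unknown:
        raise ConfigurationError(f"unknown serotype group(s): {sorted(unknown)}")
    return groups.map(weights).astype(float).rename("serotype_score")


def hla_residual_score(hla_polygenic: np.ndarray, serotype: np.ndarray) -> np.ndarray:
    """Residuals of OLS of the HLA polygenic score on (1, serotype score).

    The output has mean zero and is numerically orthogonal to the serotype
    score.  Requires >= 3 individuals and a non-constant serotype score.
    """
    y = np.asarray(hla_polygenic, dtype=float)
    s = np.asarray(serotype, dtype=float)
    if y.shape != s.shape:
        raise AlignmentError("score vectors differ in length")
    if len(y) < 3:
        raise AlignmentError("need >= 3 individuals to residualize")
    if np.ptp(s) == 0:
        raise AlignmentError("serotype score is constant; residualization undefined")
    X = np.column_stack([np.ones_like(s), s])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def load_weights(path) -> dict:
    """Read a serotype-weight YAML mapping group label -> weight."""
    with open(path) as fh:
        weights = yaml.safe_load(fh)
    if not isinstance(weights, dict):
        raise ConfigurationError("weight file must be a mapping of group -> weight")
    return {str(k): float(v) for k, v in weights.items()}


def example_weights() -> dict:
    """Synthetic placeholder serotype weights for simulation and examples.

    These are NOT the published serotype risk weights (which must be supplied
    by the user as a YAML config); they only preserve the qualitative
    ordering of type 1 diabetes risk across the six groups.
    """
    return {
        "DR3/DR4-DQ8": 3.9,
        "DR4-DQ8/DR4-DQ8": 3.6,
        "DR3/DR3": 3.3,
        "DR4-DQ8/X": 2.3,
        "DR3/X": 2.2,
        "X/X": 0.0,
    }


def write_weights(weights: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(weights, fh, sort_keys=False)
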