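"""Summary-statistic ingestion, SNP filtering and locus designation.

Diabetes-associated SNPs are taken from published per-SNP meta-analysis
results, filtered on p-value (< 1e-5), minor allele frequency (>= 0.02) and
imputation information (>= 0.7).  Filtered SNPs are partitioned into
locus-specific regions — maximal single-linkage chains in which consecutive
SNPs are less than one megabase apart, kept only if they contain at least one
SNP with p < 1e-6 — plus a residual genome-wide set holding everything else.

Threshold comparisons follow the published wording: p-value thresholds are
strict (<), MAF/info use >= (records are excluded when "less than" the
cutoff).  Coordinates are 1-based; exclusion intervals are closed at both
ends (VCF convention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MissingMetadataError

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "pvalue"]

#: chr6 interval treated as the extended HLA region (GRCh37-style bounds);
#: excluded from the type 2 genome-wide score.
HLA_REGION = ("6", 25_000_000, 34_000_000)


@dataclass
class LocusDefinition:
    """A contiguous set of filtered SNPs designated as an associated region."""

    locus_id: str
    chrom: str
    start: int
    end: int
    snp_ids: list
    lead_p: float

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("locus end < start")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return str(self.chrom) == str(chrom) and not (self.end < start or self.start > end)


def filter_snps(records: pd.DataFrame, snp_meta: pd.DataFrame,
                p_max: float = 1e-5, maf_min: float = 0.02,
                info_min: float = 0.7) -> pd.DataFrame:
    """Keep records with pvalue < p_max, MAF >= maf_min and info >= info_min.

    ``snp_meta`` must provide ``maf`` and ``info`` per ``snp_id``; a record
    without metadata is a hard error listing the offending ids.  Input order
    is preserved.
    """
    if records.empty:
        return records.copy()
    meta = snp_meta.set_index("snp_id")[["maf", "info"]]
    missing = [s for s in records["snp_id"] if s not in meta.index]
    if missing:
        raise MissingMetadataError(missing)
    maf = meta["maf"].reindex(records["snp_id"]).to_numpy()
    info = meta["info"].reindex(records["snp_id"]).to_numpy()
    keep = (records["pvalue"].to_numpy() < p_max) & (maf >= maf_min) & (info >= info_min)
    return records[keep].copy()


def designate_loci(filtered: pd.DataFrame, gap_bp: int = 1_000_000,
                   lead_p: float = 1e-6) -> tuple[list[LocusDefinition], pd.DataFrame]:
    """Partition filtered SNPs into lead-containing loci and a residual set.

    Per chromosome, SNPs sorted by position are chained by single linkage:
    consecutive SNPs closer than ``gap_bp`` join the same cluster; a gap of
    ``gap_bp`` or more starts a new one.  Clusters containing at least one
    SNP with pvalue < ``lead_p`` become loci; all other filtered SNPs go to
    the residual genome-wide set.  Every filtered SNP lands in exactly one of
    the two.  Clustering is order-invariant (input is sorted internally).
    """
    if filtered.empty:
        return [], filtered.copy()
    df = filtered.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    loci: list[LocusDefinition] = []
    residual_idx: list[int] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp) + 1
        for cluster in np.split(np.arange(len(grp)), breaks):
            sub = grp.iloc[cluster]
            pmin = float(sub["pvalue"].min())
            if pmin < lead_p:
                loci.append(LocusDefinition(
                    locus_id=f"{chrom}:{int(sub['pos'].min())}",
                    chrom=str(chrom),
                    start=int(sub["pos"].min()),
                    end=int(sub["pos"].max()),
                    snp_ids=list(sub["snp_id"]),
                    lead_p=pmin,
                ))
            else:
                residual_idx.extend(sub.index)
    residual = df.loc[sorted(residual_idx)].reset_index(drop=True)
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci, residual


def exclude_region(loci: list[LocusDefinition], residual: pd.DataFrame,
                   region: tuple[str, int, int]) -> tuple[list[LocusDefinition], pd.DataFrame]:
    """Drop loci overlapping ``region`` and residual SNPs inside it.

    ``region`` is (chrom, start, end) with a closed interval at both ends.
    Used to exclude the HLA region from the type 2 genome-wide score.
    Removals are logged.
    """
    chrom, start, end = region
    kept, dropped = [], []
    for locus in loci:
        (dropped if locus.overlaps(chrom, start, end) else kept).append(locus)
    for locus in dropped:
        logger.info("excluding locus %s overlapping %s:%d-%d",
                    locus.locus_id, chrom, start, end)
    if residual.empty:
        return kept, residual.copy()
    inside = ((residual["chrom"].astype(str) == str(chrom))
              & (residual["pos"] >= start) & (residual["pos"] <= end))
    if inside.any():
        logger.info("excluding %d residual SNP(s) inside %s:%d-%d",
                    int(inside.sum()), chrom, start, end)
    return kept, residual[~inside].reset_index(drop=True)


def harmonize_alleles(sumstats: pd.DataFrame, geno_meta: pd.DataFrame) -> pd.DataFrame:
    """Align summary-stat records to genotype data by chrom+pos+allele pair.

    When effect/other alleles are swapped relative to the genotype's
    effect/other orientation the beta sign is flipped.  Strand-ambiguous
    (A/T, C/G) and allele-mismatched records are dropped with a warning.
    """
    amb = {frozenset(("A", "T")), frozenset(("C", "G"))}
    g = geno_meta.set_index(["chrom", "pos"])
    rows = []
    n_amb = n_mismatch = n_absent = 0
    for rec in sumstats.itertuples(index=False):
        pair = frozenset((rec.effect_allele, rec.other_allele))
        if pair in amb:
            n_amb += 1
            continue
        key = (rec.chrom, rec.pos)
        if key not in g.index:
            n_absent += 1
            continue
        tgt = g.loc[key]
        if isinstance(tgt, pd.DataFrame):
            tgt = tgt.iloc[0]
        if {tgt["effect_allele"], tgt["other_allele"]} != set(pair):
            n_mismatch += 1
            continue
        rec_d = rec._asdict()
        if rec.effect_allele != tgt["effect_allele"]:
            rec_d["beta"] = -rec_d["beta"]
            rec_d["effect_allele"], rec_d["other_allele"] = (
                tgt["effect_allele"], tgt["other_allele"])
        rows.append(rec_d)
    for n, what in ((n_amb, "strand-ambiguous"), (n_mismatch, "allele-mismatched"),
                    (n_absent, "absent-from-genotypes")):
        if n:
            logger.warning("harmonization dropped %d %s SNP(s)", n, what)
    return pd.DataFrame(rows, columns=list(sumstats.columns))


# ---------------------------------------------------------------------- I/O

def read_sumstats(path, columns: dict | None = None) -> pd.DataFrame:
    """Read tab-delimited summary statistics; ``columns`` maps the canonical
    names to the file's header names when they differ."""
    df = pd.read_csv(path, sep="\t")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns and c != "se"]
    if missing:
        raise ValueError(f"summary-stat file missing columns: {missing}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_loci(loci: list[LocusDefinition], residual: pd.DataFrame, outdir) -> None:
    """Write loci as BED-like text (chrom, start, end, locus_id, lead_p),
    the residual set as TSV, and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "loci.bed", "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t{l.lead_p:.3g}\n")
    residual.to_csv(outdir / "residual_snps.tsv", sep="\t", index=False)
    manifest = {"n_loci": len(loci), "n_residual": len(residual),
                "loci": [asdict(l) for l in loci]}
    with open(outdir / "loci.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_loci(outdir) -> list[LocusDefinition]:
    with open(Path(outdir) / "loci.json") as fh:
        manifest = json.load(fh)
    return [LocusDefinition(**d) for d in manifest["loci"]]
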