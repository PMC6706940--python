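"""Readers and writers for the pipeline's file formats.

Genotypes travel either as VCF with a DS (dosage) FORMAT field — read with
cyvcf2, falling back to GT hard calls when DS is absent — or as a plain
tab-delimited individuals x SNPs matrix.  Phenotypes, summary statistics and
score tables are tab-delimited text with a header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeData

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
"""


def write_vcf(geno: GenotypeData, path) -> None:
    """Write dosages as an uncompressed VCF with GT:DS per sample.

    The effect allele is written as ALT so that DS counts effect-allele
    copies; the other allele is REF.
    """
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.ids) + "\n")
        meta = geno.meta
        for j in range(geno.m):
            row = meta.iloc[j]
            ds = geno.dosages[:, j]
            cells = []
            for v in ds:
                if np.isnan(v):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_map.get(int(round(v)), './.')}:{v:g}")
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                     f"{row['other_allele']}\t{row['effect_allele']}\t.\tPASS\t.\t"
                     "GT:DS\t" + "\t".join(cells) + "\n")


def read_vcf(path) -> GenotypeData:
    """Read a VCF into dosages using the DS field, falling back to GT counts
    of the ALT allele; missing genotypes become NaN."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    rows, cols = [], []
    for variant in vcf:
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where(col < 0, np.nan, col)
        else:
            col = np.asarray(variant.gt_types, dtype=float)
            col[col == 3] = np.nan  # unknown
        cols.append(col)
        rows.append({
            "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
            "chrom": str(variant.CHROM), "pos": int(variant.POS),
            "effect_allele": variant.ALT[0] if variant.ALT else ".",
            "other_allele": variant.REF,
        })
    vcf.close()
    dosages = np.column_stack(cols) if cols else np.empty((len(ids), 0))
    meta = pd.DataFrame(rows)
    meta["maf"] = np.minimum(dosages.mean(axis=0) / 2.0,
                             1 - dosages.mean(axis=0) / 2.0) if len(rows) else []
    return GenotypeData(dosages=dosages, meta=meta, ids=ids)


def write_matrix(geno: GenotypeData, path) -> None:
    """Plain matrix format: individuals x SNPs TSV, SNP ids as columns."""
    df = pd.DataFrame(geno.dosages, index=pd.Index(geno.ids, name="individual_id"),
                      columns=geno.meta["snp_id"])
    df.to_csv(path, sep="\t")


def read_matrix(path, meta: pd.DataFrame | None = None) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if meta is None:
        meta = pd.DataFrame({"snp_id": df.columns, "chrom": "0",
                             "pos": np.arange(1, df.shape[1] + 1),
                             "effect_allele": "A", "other_allele": "G"})
        meta["maf"] = np.minimum(df.mean(axis=0) / 2, 1 - df.mean(axis=0) / 2).to_numpy()
    return GenotypeData(dosages=df.to_numpy(dtype=float), meta=meta,
                        ids=list(df.index))


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
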