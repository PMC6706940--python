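"""Plotting helpers (Manhattan plot with highlighted regions)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def _chrom_sort_key(c):
    try:
        return (0, int(c))
    except (TypeError, ValueError):
        return (1, str(c))


def manhattan(scan: pd.DataFrame, highlight=None, out=None, cap: float = 15.0,
              ax=None):
    """Manhattan plot of -log10 p by genomic position.

    ``highlight`` is an optional list of (chrom, start, end) regions drawn in
    a contrasting colour (e.g. the diabetes-associated loci); the vertical
    axis is truncated at ``cap``.  Writes a PNG when ``out`` is given and
    returns the matplotlib axes.
    """
    df = scan.dropna(subset=["pvalue"]).copy()
    df["chrom"] = df["chrom"].astype(str)
    chroms = sorted(df["chrom"].unique(), key=_chrom_sort_key)
    offset, offsets, ticks = 0, {}, []
    for c in chroms:
        span = df.loc[df["chrom"] == c, "pos"].max()
        offsets[c] = offset
        ticks.append(offset + span / 2)
        offset += span + 1_000_000
    x = df["pos"].to_numpy() + df["chrom"].map(offsets).to_numpy()
    y = np.minimum(-np.log10(np.clip(df["pvalue"].to_numpy(), 1e-300, 1.0)), cap)

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.2))
    shade = df["chrom"].map({c: i % 2 for i, c in enumerate(chroms)}).to_numpy()
    ax.scatter(x, y, s=6, c=np.where(shade == 0, "#4c4c4c", "#9c9c9c"),
               linewidths=0)
    if highlight:
        mask = np.zeros(len(df), dtype=bool)
        for chrom, start, end in highlight:
            mask |= ((df["chrom"] == str(chrom)) & (df["pos"] >= start)
                     & (df["pos"] <= end)).to_numpy()
        ax.scatter(x[mask], y[mask], s=8, c="forestgreen", linewidths=0)
    ax.set_xticks(ticks, chroms)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    ax.set_ylim(0, cap * 1.05)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
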