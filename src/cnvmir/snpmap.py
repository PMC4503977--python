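"""SNP counting and density (SNPs/kb) per gene region.

SNPs arrive already assigned to a gene region (5'UTR, CDS or 3'UTR), the
form in which region-restricted queries of SNP databases are exported.
Densities are pooled within a group: total SNPs over total region length,
which is stabler than averaging per-gene densities when regions are short.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .sitescan import REGIONS

logger = logging.getLogger(__name__)

_REGION_LEN_COL = {"UTR5": "utr5_len", "CDS": "cds_len", "UTR3": "utr3_len"}

#: default transcript-size bin edges: 1 kb steps to 10 kb, then open-ended
DEFAULT_BINS = tuple(range(1000, 10001, 1000))


def read_snp_table(path) -> pd.DataFrame:
    """Read and deduplicate a TSV of (snp_id, gene_id, region, species)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "gene_id", "region", "species"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"SNP table missing column(s): {', '.join(missing)}")
    bad = sorted(set(table["region"]) - set(REGIONS))
    if bad:
        raise FormatError(f"unknown region label(s): {', '.join(bad)}")
    n0 = len(table)
    table = table.drop_duplicates(subset=["snp_id", "gene_id", "region"])
    if len(table) < n0:
        logger.warning("dropped %d duplicate SNP row(s)", n0 - len(table))
    return table.reset_index(drop=True)


def snps_per_gene(
    snps: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-region SNP counts, zero-filled for SNP-free genes.

    *genes* is the annotation table with cnv_status assigned. SNPs whose
    gene_id is not annotated are excluded (logged). Returns
    (counts, group_means) where group_means holds mean SNPs per gene for
    each (species, cnv_status, region) plus an all-region total per
    (species, cnv_status).
    """
    known = set(genes["gene_id"])
    unknown = ~snps["gene_id"].isin(known)
    if unknown.any():
        logger.warning(
            "%d SNP(s) referencing unknown genes excluded", int(unknown.sum())
        )
        snps = snps[~unknown]
    observed = (
        snps.groupby(["gene_id", "region"]).size().rename("n_snps").reset_index()
    )
    scaffold = genes.loc[:, ["gene_id", "species", "cnv_status", "utr_class"]].merge(
        pd.DataFrame({"region": REGIONS}), how="cross"
    )
    counts = scaffold.merge(observed, on=["gene_id", "region"], how="left")
    counts["n_snps"] = counts["n_snps"].fillna(0).astype(int)

    per_region = (
        counts.groupby(["species", "cnv_status", "region"])["n_snps"]
        .mean()
        .rename("mean_snps_per_gene")
        .reset_index()
    )
    totals = (
        counts.groupby(["species", "cnv_status", "gene_id"])["n_snps"]
        .sum()
        .groupby(["species", "cnv_status"])
        .mean()
        .rename("mean_snps_per_gene")
        .reset_index()
    )
    totals["region"] = "ALL"
    group_means = pd.concat([per_region, totals], ignore_index=True)
    return counts, group_means


def assign_size_bins(
    lengths: pd.Series, size_bins: Sequence[int] = DEFAULT_BINS
) -> pd.Series:
    """Label each transcript length with its half-open [lo, hi) size bin."""
    edges = [0, *sorted(size_bins), np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"[{int(lo)},{'inf' if np.isinf(hi) else int(hi)})")
    idx = np.searchsorted(edges[1:-1], lengths.to_numpy(), side="right")
    return pd.Series([labels[i] for i in idx], index=lengths.index, name="size_bin")


def snp_density(
    counts: pd.DataFrame,
    genes: pd.DataFrame,
    size_bins: Sequence[int] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Pooled SNP density per (species, cnv_status, region, size_bin).

    density = sum(SNPs) / sum(region length in kb). Groups whose pooled
    region length is zero are flagged (density NaN) rather than dropped,
    so binning conserves the total SNP count.
    """
    if not set(_REGION_LEN_COL.values()) <= set(genes.columns):
        raise ValidationError("gene table lacks region length columns")
    g = genes.copy()
    g["size_bin"] = assign_size_bins(g["mrna_length"], size_bins)
    lengths = g.melt(
        id_vars=["gene_id", "size_bin"],
        value_vars=list(_REGION_LEN_COL.values()),
        var_name="region",
        value_name="region_len",
    )
    lengths["region"] = lengths["region"].map(
        {v: k for k, v in _REGION_LEN_COL.items()}
    )
    merged = counts.merge(lengths, on=["gene_id", "region"], how="left")
    out = []
    for key, grp in merged.groupby(
        ["species", "cnv_status", "region", "size_bin"], sort=True
    ):
        n_snps = int(grp["n_snps"].sum())
        total_kb = float(grp["region_len"].sum()) / 1000.0
        out.append(
            {
                "species": key[0],
                "cnv_status": key[1],
                "region": key[2],
                "size_bin": key[3],
                "n_genes": grp["gene_id"].nunique(),
                "n_snps": n_snps,
                "total_len_kb": total_kb,
                "density": n_snps / total_kb if total_kb > 0 else np.nan,
                "undefined": total_kb == 0,
            }
        )
    return pd.DataFrame(out)
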