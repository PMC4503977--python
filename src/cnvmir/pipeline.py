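"""End-to-end orchestration: classify -> scan -> count -> enrich -> compare.

``run_full`` executes the whole comparative analysis from a fixture (or
real-data) directory and emits one plain TSV per report:

* short-UTR gene counts per species x CNV status,
* pathway enrichment of each species' short-UTR gene set,
* mean binding sites per gene by species/CNV status/UTR class/region,
* 5'UTR binding-site enrichment, CNV vs non-CNV genes, short and long,
* SNP means and pooled SNP densities by transcript-size bin,
* CNV-/non-CNV-miRNA targeting means and the DER comparison (human only).

Everything is deterministic given the inputs; exclusions (unmapped genes,
genes without sequences) are counted in the run log, never silently
dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import cnv_atlas, compare, enrich, genemodel, sitescan, snpmap
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str | Path
    output_dir: str | Path
    reference: str = "hsa"
    long_threshold: int = genemodel.LONG_UTR_THRESHOLD
    scan_mode: str = "consensus"
    min_walk_len: int = 7
    allow_wobble: bool = False
    site_correction: str = "holm"
    pathway_correction: str = "bh"
    alpha: float = 0.05
    size_bins: tuple[int, ...] = snpmap.DEFAULT_BINS

    def validate(self):
        if not Path(self.input_dir).is_dir():
            raise ValidationError(f"input directory not found: {self.input_dir}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass
class ReportSet:
    genes: pd.DataFrame
    short_utr_counts: pd.DataFrame
    pathway_enrichment: pd.DataFrame
    site_counts: pd.DataFrame
    mean_sites: pd.DataFrame
    utr5_enrichment: pd.DataFrame
    species_comparisons: pd.DataFrame
    snp_means: pd.DataFrame
    snp_density: pd.DataFrame
    mirna_class_fraction: float
    mirna_targeting: pd.DataFrame
    der_comparison: pd.DataFrame
    log: dict = field(default_factory=dict)


def classify_report(genes: pd.DataFrame) -> pd.DataFrame:
    """Short-UTR gene counts per species split by CNV status."""
    short = genes[genes["utr_class"] == "short"]
    counts = (
        short.groupby(["species", "cnv_status"], dropna=False)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    wide = (
        counts.pivot(index="species", columns="cnv_status", values="n_genes")
        .fillna(0)
        .astype(int)
    )
    for col in ("CNV", "nonCNV"):
        if col not in wide.columns:
            wide[col] = 0
    wide = wide[["CNV", "nonCNV"]]
    wide["total"] = wide.sum(axis=1)
    return wide.reset_index()


def _load_genes(cfg: RunConfig):
    root = Path(cfg.input_dir)
    records = genemodel.read_transcripts(
        root / "transcripts.tsv", root / "transcripts.fasta"
    )
    selected = genemodel.select_longest_transcript(records)
    genes = genemodel.annotate_genes(selected, cfg.long_threshold)

    cnv = cnv_atlas.read_bed(root / "cnv.bed")
    human = {
        gid: cnv_atlas.GenomicInterval(
            rec.chrom, rec.g_start, rec.g_end, rec.strand
        )
        for gid, rec in selected.items()
        if rec.species == cfg.reference
    }
    status, unplaced = cnv_atlas.classify_genes_by_cnv(human, cnv)
    homologs = cnv_atlas.read_homolog_table(root / "homologs.tsv")
    all_status = dict(status)
    excluded: dict[str, int] = {}
    for sp in sorted(genes["species"].unique()):
        if sp == cfg.reference:
            continue
        sp_genes = genes.loc[genes["species"] == sp, "gene_id"]
        sp_status, n_excl = cnv_atlas.propagate_to_homologs(
            status, homologs, sp, sp_genes
        )
        all_status.update(sp_status)
        excluded[sp] = n_excl
    genes["cnv_status"] = genes["gene_id"].map(all_status)
    return genes, selected, status, excluded, unplaced


def run_full(cfg: RunConfig, seed: int = 0) -> ReportSet:
    """Run the complete analysis over one input bundle."""
    cfg.validate()
    root = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes, selected, human_status, excluded, unplaced = _load_genes(cfg)
    classified = genes[genes["cnv_status"].notna()].reset_index(drop=True)
    short_counts = classify_report(classified)

    # pathway enrichment of short-UTR gene sets, per species
    annotations = enrich.read_gmt(root / "pathways.gmt")
    pathway_frames = []
    for sp, grp in classified.groupby("species"):
        universe = grp["gene_id"]
        for label, sub in (
            ("all", grp),
            ("CNV", grp[grp["cnv_status"] == "CNV"]),
            ("nonCNV", grp[grp["cnv_status"] == "nonCNV"]),
        ):
            gene_set = sub.loc[sub["utr_class"] == "short", "gene_id"]
            if gene_set.empty:
                continue
            res = enrich.pathway_enrichment(
                gene_set, universe, annotations, cfg.alpha, cfg.pathway_correction
            )
            res.insert(0, "species", sp)
            res.insert(1, "category", label)
            pathway_frames.append(res)
    pathway_report = pd.concat(pathway_frames, ignore_index=True)

    # binding-site scan (both scanners + consensus by default)
    mirnas = _load_mirnas(root)
    region_seqs = {}
    for gid, rec in selected.items():
        if rec.sequence is None:
            continue
        u5, cds, u3 = genemodel.extract_region_sequences(rec)
        region_seqs[gid] = {"UTR5": u5, "CDS": cds, "UTR3": u3}
    site_counts = sitescan.count_sites(
        classified, region_seqs, mirnas, cfg.scan_mode, cfg.min_walk_len, cfg.allow_wobble
    )
    mean_sites = sitescan.mean_sites_per_gene(site_counts)

    # 5'UTR enrichment contrasts: CNV vs non-CNV within each UTR class (human)
    contrasts = []
    for utr_class in ("short", "long"):
        contrasts.append(
            (
                {"species": cfg.reference, "utr_class": utr_class, "cnv_status": "CNV"},
                {"species": cfg.reference, "utr_class": utr_class, "cnv_status": "nonCNV"},
                "UTR5",
            )
        )
    utr5_enrichment = enrich.site_enrichment_run(
        site_counts, contrasts, cfg.site_correction, cfg.alpha
    )

    # cross-species comparison of per-gene 3'UTR site counts (long genes)
    long_utr3 = site_counts[
        (site_counts["utr_class"] == "long") & (site_counts["region"] == "UTR3")
    ].rename(columns={"n_sites": "value"})
    if long_utr3["species"].nunique() >= 2:
        species_cmp = compare.compare_species_means(
            long_utr3, cfg.reference, alpha=cfg.alpha
        )
    else:
        logger.warning("fewer than 2 species; species comparison skipped")
        species_cmp = pd.DataFrame()

    # SNPs: per-gene counts, group means, pooled density by size bin
    snps = snpmap.read_snp_table(root / "snps.tsv")
    snp_counts, snp_means = snpmap.snps_per_gene(snps, classified)
    snp_density = snpmap.snp_density(snp_counts, classified, cfg.size_bins)

    # human-only stages: miRNA CNV classing, class targeting, DER comparison
    cnv_gene_ivs = [
        cnv_atlas.GenomicInterval(rec.chrom, rec.g_start, rec.g_end)
        for gid, rec in selected.items()
        if rec.species == cfg.reference and human_status.get(gid) == "CNV"
    ]
    mirnas, cnv_frac = cnv_atlas.classify_mirnas(mirnas, cnv_gene_ivs)
    mirna_class = {m.mirna_id: m.cnv_class for m in mirnas}

    human_genes = classified[classified["species"] == cfg.reference]
    target_rows = []
    for g in human_genes.itertuples(index=False):
        seqs = region_seqs.get(g.gene_id)
        if seqs is None:
            continue
        for s in sitescan.scan_gene(
            g.gene_id, seqs, mirnas, cfg.scan_mode, cfg.min_walk_len, cfg.allow_wobble
        ):
            target_rows.append(
                {
                    "mirna_id": s.mirna_id,
                    "gene_id": s.gene_id,
                    "region": s.region,
                    "mirna_class": mirna_class[s.mirna_id],
                    "gene_status": human_status.get(s.gene_id),
                }
            )
    targets = pd.DataFrame(
        target_rows,
        columns=["mirna_id", "gene_id", "region", "mirna_class", "gene_status"],
    )
    if targets.empty:
        mirna_targeting = pd.DataFrame()
    else:
        per_gene = (
            targets.groupby(["mirna_class", "gene_status", "region", "gene_id"])
            .size()
            .rename("n_sites")
            .reset_index()
        )
        mirna_targeting = (
            per_gene.groupby(["mirna_class", "gene_status", "region"])["n_sites"]
            .agg(["mean", "sem", "count"])
            .reset_index()
            .rename(columns={"count": "n"})
        )
    der = pd.read_csv(root / "der.tsv", sep="\t")
    der_cmp = compare.der_by_target_category(der, targets, human_status)

    reports = ReportSet(
        genes=classified,
        short_utr_counts=short_counts,
        pathway_enrichment=pathway_report,
        site_counts=site_counts,
        mean_sites=mean_sites,
        utr5_enrichment=utr5_enrichment,
        species_comparisons=species_cmp,
        snp_means=snp_means,
        snp_density=snp_density,
        mirna_class_fraction=cnv_frac,
        mirna_targeting=mirna_targeting,
        der_comparison=der_cmp,
        log={
            "parameters": {
                "reference": cfg.reference,
                "long_threshold": cfg.long_threshold,
                "scan_mode": cfg.scan_mode,
                "alpha": cfg.alpha,
            },
            "n_genes_classified": int(len(classified)),
            "n_genes_unmapped": int(genes["cnv_status"].isna().sum()),
            "n_genes_unplaced": len(unplaced),
            "excluded_homologs": excluded,
            "cnv_mirna_fraction": cnv_frac,
        },
    )
    _write_reports(reports, outdir)
    return reports


def _load_mirnas(root: Path) -> list[cnv_atlas.MiRNARecord]:
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(root / "mirnas.fasta"), "fasta")
    }
    table = pd.read_csv(root / "mirnas.tsv", sep="\t", dtype={"chrom": str})
    records = []
    for row in table.itertuples(index=False):
        records.append(
            cnv_atlas.MiRNARecord(
                row.mirna_id,
                seqs[row.mirna_id],
                cnv_atlas.GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
            )
        )
    return records


def _write_reports(reports: ReportSet, outdir: Path) -> None:
    tables = {
        "short_utr_counts.tsv": reports.short_utr_counts,
        "pathway_enrichment.tsv": reports.pathway_enrichment,
        "site_counts.tsv": reports.site_counts,
        "mean_sites.tsv": reports.mean_sites,
        "utr5_enrichment.tsv": reports.utr5_enrichment,
        "species_comparisons.tsv": reports.species_comparisons,
        "snp_means.tsv": reports.snp_means,
        "snp_density.tsv": reports.snp_density,
        "mirna_targeting.tsv": reports.mirna_targeting,
        "der_comparison.tsv": reports.der_comparison,
    }
    for name, frame in tables.items():
        frame.to_csv(outdir / name, sep="\t", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(reports.log, fh, indent=2, sort_keys=True)
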