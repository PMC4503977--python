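"""Synthetic multi-species fixtures with planted, parameterized effects.

The generator emits everything the pipeline ingests — transcript tables
with mRNA sequences, CNV intervals, mature miRNAs with coordinates, a
homolog table, SNP tables, a pathway map and a DER table — together with a
ground-truth manifest, so that every analysis stage can be checked against
what was planted.

Planted structure (all switchable / zeroable):

* CNV status is assigned per human gene and realised geometrically: a CNV
  interval is placed inside each chosen gene's span, and gene spans are
  separated by fixed gaps, so interval overlap recovers the assignment
  exactly. Other species inherit status through the homolog table.
* Human short-3'UTR genes get their own CNV fraction (default 0.65 vs 0.30
  elsewhere), reproducing the qualitative pattern of human short-UTR genes
  being majority-CNV while other species are majority-non-CNV.
* Exact 8mer seed sites for randomly chosen miRNAs are embedded,
  non-overlapping, in every 5'UTR at a baseline rate; human CNV short-UTR
  genes get ``planted_site_multiplier`` times that rate.
* SNPs are placed per region as Poisson(rate/kb x region kb); default
  rates make the human:mouse ratio exactly 2 in every region.
* One pathway is overrepresented in the human short-UTR gene set at a
  configurable relative representation.
* Human CNV genes get an additive DER shift.

Background sequence is i.i.d. uniform over ACGT (configurable GC bias),
which keeps analytic background site rates exact for scanner calibration.
One RNG stream per file type, all derived from the master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv_atlas import GenomicInterval, MiRNARecord
from .errors import ValidationError
from .sitescan import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: eight study species, ordered by expected short-UTR gene count (human lowest)
DEFAULT_SPECIES_ORDER = ("hsa", "cfa", "ptr", "mml", "rno", "mmu", "bta", "gga")

_SHORT_FRACTIONS = {
    "hsa": 0.10,
    "cfa": 0.16,
    "ptr": 0.20,
    "mml": 0.22,
    "rno": 0.24,
    "mmu": 0.26,
    "bta": 0.28,
    "gga": 0.30,
}

#: SNPs per kb by region; human rates are exactly 2x mouse in every region
_SNP_RATES = {
    "hsa": {"UTR5": 8.0, "CDS": 6.0, "UTR3": 10.0},
    "mmu": {"UTR5": 4.0, "CDS": 3.0, "UTR3": 5.0},
    "rno": {"UTR5": 1.0, "CDS": 0.8, "UTR3": 1.2},
    "gga": {"UTR5": 1.2, "CDS": 1.0, "UTR3": 1.5},
}

_GENE_GAP = 1000  # bp between consecutive gene spans; keeps CNV planting local
_N_CHROMS = 5


@dataclass
class SpeciesParams:
    n_genes: int = 500
    short_utr_fraction: float = 0.2
    cnv_fraction: float = 0.30
    short_utr_cnv_fraction: float | None = None  # falls back to cnv_fraction
    mean_utr5: int = 200
    mean_cds: int = 900
    mean_utr3: int = 500
    length_cv: float = 0.2
    snp_rate_per_kb: dict[str, float] | None = None

    def validate(self):
        for frac in (self.short_utr_fraction, self.cnv_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError(f"fraction {frac} outside [0, 1]")
        if self.short_utr_cnv_fraction is not None and not (
            0 <= self.short_utr_cnv_fraction <= 1
        ):
            raise ValidationError("short_utr_cnv_fraction outside [0, 1]")
        if min(self.mean_utr5, self.mean_cds, self.mean_utr3) <= 0:
            raise ValidationError("mean region lengths must be positive")


@dataclass
class SyntheticConfig:
    seed: int = 0
    species: dict[str, SpeciesParams] = field(default_factory=dict)
    n_mirnas: int = 30
    mirna_length: int = 22
    mirna_cnv_fraction: float = 0.25
    utr5_site_rate_per_kb: float = 25.0
    planted_site_multiplier: float = 2.0
    n_pathways: int = 20
    pathway_size: int = 40
    planted_pathway_id: str = "pw01"
    planted_pathway_rel_rep: float = 8.0
    der_mean: float = 0.30
    der_sd: float = 0.12
    der_shift: float = 0.10
    homolog_coverage: float = 0.92
    extra_transcript_fraction: float = 0.25
    gc_bias: float = 0.5

    def validate(self):
        if "hsa" not in self.species:
            raise ValidationError("config must include the human species 'hsa'")
        for sp, params in self.species.items():
            params.validate()
            if self.pathway_size > params.n_genes:
                raise ValidationError(
                    f"pathway size {self.pathway_size} exceeds gene count of {sp}"
                )
        if not 0 <= self.mirna_cnv_fraction <= 1:
            raise ValidationError("mirna_cnv_fraction outside [0, 1]")
        if self.planted_site_multiplier < 0 or self.utr5_site_rate_per_kb < 0:
            raise ValidationError("site rates must be non-negative")


def default_config(seed: int = 0, n_genes: int = 500) -> SyntheticConfig:
    """The study conditions: 8 species, human lowest short-UTR fraction and
    majority-CNV short genes, 2x planted 5'UTR site rate in human CNV
    short-UTR genes, human:mouse SNP rate ratio 2."""
    species = {}
    for sp in DEFAULT_SPECIES_ORDER:
        species[sp] = SpeciesParams(
            n_genes=n_genes,
            short_utr_fraction=_SHORT_FRACTIONS[sp],
            cnv_fraction=0.30,
            short_utr_cnv_fraction=0.65 if sp == "hsa" else None,
            snp_rate_per_kb=dict(_SNP_RATES[sp]) if sp in _SNP_RATES else None,
        )
    return SyntheticConfig(seed=seed, species=species)


def null_config(config: SyntheticConfig) -> SyntheticConfig:
    """Zero every planted effect: no embedded seed sites (background
    sequence only), no DER shift, flat pathway representation, and
    identical per-species parameters (human's), so all between-group
    contrasts are null."""
    cfg = dataclasses.replace(
        config,
        utr5_site_rate_per_kb=0.0,
        planted_site_multiplier=1.0,
        der_shift=0.0,
        planted_pathway_rel_rep=1.0,
    )
    ref = config.species["hsa"]
    cfg.species = {
        sp: dataclasses.replace(
            ref,
            short_utr_cnv_fraction=None,
            snp_rate_per_kb=dict(ref.snp_rate_per_kb)
            if ref.snp_rate_per_kb is not None
            else None,
        )
        for sp in config.species
    }
    return cfg


@dataclass
class TableBundle:
    """In-memory fixture: the generator's output before serialization."""

    config: SyntheticConfig
    transcripts: pd.DataFrame
    sequences: dict[str, str]  # transcript_id -> mRNA sequence
    cnv_intervals: list[GenomicInterval]  # human CNV regions
    cnv_gene_intervals: list[GenomicInterval]  # spans of human CNV genes
    mirnas: list[MiRNARecord]
    mirna_table: pd.DataFrame
    homologs: pd.DataFrame
    snps: pd.DataFrame
    pathways: dict[str, tuple[str, set[str]]]
    der: pd.DataFrame
    manifest: pd.DataFrame
    planted_sites: pd.DataFrame


@dataclass
class FixtureBundle:
    """Paths of a serialized fixture."""

    root: Path
    transcripts_tsv: Path
    transcripts_fasta: Path
    cnv_bed: Path
    mirna_tsv: Path
    mirna_fasta: Path
    homolog_tsv: Path
    snp_tsv: Path
    pathway_gmt: Path
    der_tsv: Path
    manifest_tsv: Path


def _random_seq(rng: np.random.Generator, length: int, gc_bias: float) -> bytearray:
    if gc_bias == 0.5:
        codes = rng.integers(0, 4, size=length)
    else:
        p_gc = gc_bias / 2.0
        p_at = (1.0 - gc_bias) / 2.0
        codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return bytearray(_BASES[codes].tobytes())


def plant_seed_sites(
    region_seq: bytearray | str,
    mirna_seq: str,
    n: int,
    rng: np.random.Generator,
    gene_id: str = "",
) -> tuple[bytearray, list[int]]:
    """Embed *n* non-overlapping exact 8mer sites for one miRNA.

    The 8mer is the reverse complement of miRNA positions 2-8 followed by
    an A (the base opposite miRNA position 1). Returns the modified
    sequence and the recorded 0-based site starts.
    """
    seq = bytearray(region_seq, "ascii") if isinstance(region_seq, str) else region_seq
    if n == 0:
        return seq, []
    site = (revcomp(mirna_seq.upper().replace("U", "T")[1:8]) + "A").encode()
    length = len(seq)
    # non-overlapping 8-nt lattice slots guarantee placement up to ~L/8 sites
    slots = np.arange(0, length - 7, 8)
    if n > len(slots):
        raise ValidationError(
            f"gene {gene_id}: region of {length} nt cannot hold {n} sites"
        )
    positions = sorted(int(p) for p in rng.choice(slots, size=n, replace=False))
    for pos in positions:
        seq[pos : pos + 8] = site
    return seq, positions


def _normal_len(rng, mean: float, cv: float, minimum: int) -> int:
    return max(minimum, int(round(rng.normal(mean, cv * mean))))


def generate_tables(config: SyntheticConfig) -> TableBundle:
    """Build the full fixture in memory (deterministic given config.seed)."""
    config.validate()
    root_ss = np.random.SeedSequence(config.seed)
    streams = root_ss.spawn(7)
    rng_genes, rng_seq, rng_mirna, rng_snp, rng_pathway, rng_der, rng_plant = (
        np.random.default_rng(s) for s in streams
    )

    mirna_records: list[MiRNARecord] = []
    mirna_seqs = []
    for i in range(config.n_mirnas):
        seq = _random_seq(rng_mirna, config.mirna_length, 0.5).decode()
        mirna_seqs.append(seq)
        mirna_records.append(MiRNARecord(f"mir-{i + 1:03d}", seq))

    species_order = list(config.species)
    tx_rows, sequences = [], {}
    manifest_rows, planted_rows, snp_rows, der_rows = [], [], [], []
    cnv_intervals: list[GenomicInterval] = []
    cnv_gene_intervals: list[GenomicInterval] = []
    homolog_rows = []
    gene_spans: dict[str, list[tuple[str, GenomicInterval]]] = {}
    human_status: dict[str, str] = {}

    # --- human CNV assignment drives every species via the homolog table ---
    hsa_params = config.species["hsa"]
    n_ref = hsa_params.n_genes
    short_flags: dict[str, np.ndarray] = {}
    for sp in species_order:
        p = config.species[sp]
        short_flags[sp] = rng_genes.random(p.n_genes) < p.short_utr_fraction
    short_cnv_frac = (
        hsa_params.short_utr_cnv_fraction
        if hsa_params.short_utr_cnv_fraction is not None
        else hsa_params.cnv_fraction
    )
    hsa_short = short_flags["hsa"]
    cnv_draw = rng_genes.random(n_ref)
    hsa_cnv = np.where(hsa_short, cnv_draw < short_cnv_frac, cnv_draw < hsa_params.cnv_fraction)

    for sp in species_order:
        p = config.species[sp]
        if sp != "hsa":
            covered = rng_genes.random(p.n_genes) < config.homolog_coverage
        spans: list[tuple[str, GenomicInterval]] = []
        cursors = {f"chr{c + 1}": 0 for c in range(_N_CHROMS)}
        for i in range(p.n_genes):
            gene_id = f"{sp}_g{i + 1:04d}"
            short = bool(short_flags[sp][i])
            utr5 = _normal_len(rng_genes, p.mean_utr5, p.length_cv, 40)
            cds = _normal_len(rng_genes, p.mean_cds, p.length_cv, 90)
            utr3 = (
                int(rng_genes.integers(0, 8))
                if short
                else _normal_len(rng_genes, p.mean_utr3, p.length_cv, 8)
            )
            mrna_len = utr5 + cds + utr3
            chrom = f"chr{(i % _N_CHROMS) + 1}"
            g_start = cursors[chrom]
            g_end = g_start + mrna_len
            cursors[chrom] = g_end + _GENE_GAP
            span = GenomicInterval(chrom, g_start, g_end)
            spans.append((gene_id, span))

            # CNV truth: human by direct assignment, others via their partner
            if sp == "hsa":
                is_cnv = bool(hsa_cnv[i])
                status = "CNV" if is_cnv else "nonCNV"
                human_status[gene_id] = status
                if is_cnv:
                    pad = max(1, mrna_len // 10)
                    lo = g_start + min(pad, mrna_len - 1)
                    hi = max(lo + 1, g_end - pad)
                    cnv_intervals.append(GenomicInterval(chrom, lo, hi))
                    cnv_gene_intervals.append(span)
            else:
                if covered[i] and i < n_ref:
                    status = "CNV" if hsa_cnv[i] else "nonCNV"
                    homolog_rows.append(
                        {
                            "human_gene_id": f"hsa_g{i + 1:04d}",
                            "species": sp,
                            "homolog_gene_id": gene_id,
                        }
                    )
                else:
                    status = None  # no homolog: excluded downstream

            # mRNA sequence with planted 5'UTR seed sites
            tid = f"{gene_id}_t1"
            seq = _random_seq(rng_seq, mrna_len, config.gc_bias)
            rate = config.utr5_site_rate_per_kb
            if sp == "hsa" and short and status == "CNV":
                rate *= config.planted_site_multiplier
            lam = rate * utr5 / 1000.0
            n_sites = int(rng_plant.poisson(lam)) if lam > 0 else 0
            n_sites = min(n_sites, max(0, (utr5 - 7) // 8))  # lattice capacity
            planted_positions: list[tuple[str, int]] = []
            if n_sites > 0:
                mir_idx = int(rng_plant.integers(0, config.n_mirnas))
                utr5_part, pos = plant_seed_sites(
                    seq[:utr5], mirna_seqs[mir_idx], n_sites, rng_plant, gene_id
                )
                seq[:utr5] = utr5_part
                planted_positions = [(mirna_records[mir_idx].mirna_id, q) for q in pos]
            sequences[tid] = seq.decode()

            tx_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": tid,
                    "species": sp,
                    "chrom": chrom,
                    "start": g_start + 1,  # table convention: 1-based inclusive
                    "end": g_end,
                    "strand": "+",
                    "mrna_length": mrna_len,
                    "cds_start": utr5 + 1,
                    "cds_end": utr5 + cds,
                }
            )
            # occasional shorter secondary transcript exercises deduplication
            if rng_genes.random() < config.extra_transcript_fraction and mrna_len > 200:
                alt_len = int(rng_genes.integers(150, mrna_len))
                alt_cds_start = min(utr5 + 1, alt_len)
                alt_cds_end = min(utr5 + cds, alt_len)
                if alt_cds_end < alt_cds_start:
                    alt_cds_start = alt_cds_end = alt_len
                tid2 = f"{gene_id}_t2"
                sequences[tid2] = _random_seq(rng_seq, alt_len, config.gc_bias).decode()
                tx_rows.append(
                    {
                        "gene_id": gene_id,
                        "transcript_id": tid2,
                        "species": sp,
                        "chrom": chrom,
                        "start": g_start + 1,
                        "end": g_start + alt_len,
                        "strand": "+",
                        "mrna_length": alt_len,
                        "cds_start": alt_cds_start,
                        "cds_end": alt_cds_end,
                    }
                )

            manifest_rows.append(
                {
                    "species": sp,
                    "gene_id": gene_id,
                    "transcript_id": tid,
                    "utr5_len": utr5,
                    "cds_len": cds,
                    "utr3_len": utr3,
                    "utr_class": "short" if short else "long",
                    "cnv_status": status if status is not None else "unmapped",
                    "n_planted_utr5_sites": len(planted_positions),
                }
            )
            for mir_id, pos in planted_positions:
                planted_rows.append(
                    {
                        "gene_id": gene_id,
                        "region": "UTR5",
                        "mirna_id": mir_id,
                        "pos": pos,
                    }
                )

            # region-wise Poisson SNPs for species with SNP data
            if p.snp_rate_per_kb is not None:
                for region, length in (("UTR5", utr5), ("CDS", cds), ("UTR3", utr3)):
                    lam = p.snp_rate_per_kb[region] * length / 1000.0
                    for _ in range(int(rng_snp.poisson(lam))):
                        snp_rows.append(
                            {
                                "snp_id": f"{sp}_rs{len(snp_rows) + 1:06d}",
                                "gene_id": gene_id,
                                "region": region,
                                "species": sp,
                            }
                        )

            if sp == "hsa":
                der = max(0.0, rng_der.normal(config.der_mean, config.der_sd))
                if status == "CNV":
                    der += config.der_shift
                der_rows.append({"gene_id": gene_id, "der": round(der, 6)})

        gene_spans[sp] = spans

    # --- miRNA genomic placement: inside CNV gene spans or in gene gaps ---
    mirna_rows = []
    hsa_spans = gene_spans["hsa"]
    cnv_spans = [s for g, s in hsa_spans if human_status[g] == "CNV"]
    noncnv_spans = [s for g, s in hsa_spans if human_status[g] == "nonCNV"]
    for i, rec in enumerate(mirna_records):
        in_cnv = rng_mirna.random() < config.mirna_cnv_fraction
        if in_cnv and cnv_spans:
            host = cnv_spans[int(rng_mirna.integers(0, len(cnv_spans)))]
            start = host.start + int(
                rng_mirna.integers(0, max(1, host.end - host.start - 80))
            )
        else:
            in_cnv = False
            host = noncnv_spans[int(rng_mirna.integers(0, len(noncnv_spans)))]
            start = host.end + 100 + int(rng_mirna.integers(0, _GENE_GAP - 300))
        rec.interval = GenomicInterval(host.chrom, start, start + 80)
        mirna_rows.append(
            {
                "mirna_id": rec.mirna_id,
                "chrom": rec.interval.chrom,
                "start": rec.interval.start,
                "end": rec.interval.end,
                "cnv_truth": "CNV-miRNA" if in_cnv else "non-CNV-miRNA",
            }
        )

    # --- pathway map; one pathway overrepresented in human short-UTR genes ---
    pathways: dict[str, tuple[str, set[str]]] = {}
    for j in range(config.n_pathways):
        pid = f"pw{j + 1:02d}"
        members: set[str] = set()
        for sp in species_order:
            ids = np.array([g for g, _ in gene_spans[sp]])
            if pid == config.planted_pathway_id and sp == "hsa":
                w = np.where(short_flags[sp], config.planted_pathway_rel_rep, 1.0)
                w = w / w.sum()
                chosen = rng_pathway.choice(
                    ids, size=config.pathway_size, replace=False, p=w
                )
            else:
                chosen = rng_pathway.choice(ids, size=config.pathway_size, replace=False)
            members.update(chosen.tolist())
        pathways[pid] = (f"pathway {j + 1}", members)

    transcripts = pd.DataFrame(tx_rows)
    manifest = pd.DataFrame(manifest_rows)
    return TableBundle(
        config=config,
        transcripts=transcripts,
        sequences=sequences,
        cnv_intervals=sorted(cnv_intervals, key=lambda iv: (iv.chrom, iv.start)),
        cnv_gene_intervals=sorted(
            cnv_gene_intervals, key=lambda iv: (iv.chrom, iv.start)
        ),
        mirnas=mirna_records,
        mirna_table=pd.DataFrame(mirna_rows),
        homologs=pd.DataFrame(
            homolog_rows, columns=["human_gene_id", "species", "homolog_gene_id"]
        ),
        snps=pd.DataFrame(
            snp_rows, columns=["snp_id", "gene_id", "region", "species"]
        ),
        pathways=pathways,
        der=pd.DataFrame(der_rows, columns=["gene_id", "der"]),
        manifest=manifest,
        planted_sites=pd.DataFrame(
            planted_rows, columns=["gene_id", "region", "mirna_id", "pos"]
        ),
    )


def write_bundle(tables: TableBundle, outdir) -> FixtureBundle:
    """Serialize a fixture to the package's standard text formats."""
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    paths = FixtureBundle(
        root=root,
        transcripts_tsv=root / "transcripts.tsv",
        transcripts_fasta=root / "transcripts.fasta",
        cnv_bed=root / "cnv.bed",
        mirna_tsv=root / "mirnas.tsv",
        mirna_fasta=root / "mirnas.fasta",
        homolog_tsv=root / "homologs.tsv",
        snp_tsv=root / "snps.tsv",
        pathway_gmt=root / "pathways.gmt",
        der_tsv=root / "der.tsv",
        manifest_tsv=root / "manifest.tsv",
    )
    tables.transcripts.to_csv(paths.transcripts_tsv, sep="\t", index=False)
    with open(paths.transcripts_fasta, "w") as fh:
        for tid in tables.transcripts["transcript_id"]:
            fh.write(f">{tid}\n{tables.sequences[tid]}\n")
    with open(paths.cnv_bed, "w") as fh:
        for iv in tables.cnv_intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    tables.mirna_table.to_csv(paths.mirna_tsv, sep="\t", index=False)
    with open(paths.mirna_fasta, "w") as fh:
        for rec in tables.mirnas:
            fh.write(f">{rec.mirna_id}\n{rec.mature_seq}\n")
    tables.homologs.to_csv(paths.homolog_tsv, sep="\t", index=False)
    tables.snps.to_csv(paths.snp_tsv, sep="\t", index=False)
    with open(paths.pathway_gmt, "w") as fh:
        for pid in sorted(tables.pathways):
            name, genes = tables.pathways[pid]
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")
    tables.der.to_csv(paths.der_tsv, sep="\t", index=False)
    tables.manifest.to_csv(paths.manifest_tsv, sep="\t", index=False)
    return paths


def generate(config: SyntheticConfig, outdir) -> tuple[FixtureBundle, TableBundle]:
    """Generate and serialize a fixture; returns (paths, in-memory tables)."""
    tables = generate_tables(config)
    return write_bundle(tables, outdir), tables
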