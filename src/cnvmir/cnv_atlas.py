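"""CNV / non-CNV classification of genes and miRNAs.

A gene is a "CNV gene" when its genomic span shares at least one base pair
with a copy-number-variable interval; a mature miRNA is a "CNV-miRNA" when
its genomic location overlaps the coordinates of CNV genes. Human CNV status
is propagated to the other species through a homolog table, mirroring the
way cross-species CNV gene sets are usually compiled (CNV maps exist
primarily for human).

All intervals are 0-based half-open; overlap ignores strand.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CNV = "CNV"
NON_CNV = "nonCNV"
CNV_MIRNA = "CNV-miRNA"
NON_CNV_MIRNA = "non-CNV-miRNA"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class MiRNARecord:
    """A mature miRNA: id, 5'->3' sequence and genomic location."""

    mirna_id: str
    mature_seq: str
    interval: GenomicInterval | None = None
    cnv_class: str | None = None


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into validated intervals sorted by
    (chrom, start). Malformed lines raise with their line number."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share >= 1 bp (same chromosome; half-open)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _by_chrom(intervals: Iterable[GenomicInterval]):
    grouped: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        grouped[iv.chrom].append(iv)
    arrays = {}
    for chrom, ivs in grouped.items():
        arrays[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    return arrays


def _overlaps_any(arrays, iv: GenomicInterval) -> bool:
    got = arrays.get(iv.chrom)
    if got is None:
        return False
    starts, ends = got
    return bool(np.any((starts < iv.end) & (ends > iv.start)))


def classify_genes_by_cnv(
    genes: Mapping[str, GenomicInterval | None],
    cnv: Iterable[GenomicInterval],
) -> tuple[dict[str, str], list[str]]:
    """Assign every placed gene CNV/nonCNV by >=1 bp overlap with any CNV
    interval. Returns (status mapping, list of unplaced gene ids excluded
    from both classes)."""
    arrays = _by_chrom(cnv)
    status: dict[str, str] = {}
    unplaced: list[str] = []
    for gene_id in sorted(genes):
        iv = genes[gene_id]
        if iv is None:
            unplaced.append(gene_id)
            continue
        status[gene_id] = CNV if _overlaps_any(arrays, iv) else NON_CNV
    if unplaced:
        logger.warning("%d gene(s) without genomic interval excluded", len(unplaced))
    return status, unplaced


def read_homolog_table(path) -> pd.DataFrame:
    """Read a TSV of (human_gene_id, species, homolog_gene_id) rows."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["human_gene_id", "species", "homolog_gene_id"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"homolog table missing column(s): {', '.join(missing)}")
    return table


def propagate_to_homologs(
    human_status: Mapping[str, str],
    table: pd.DataFrame,
    species: str,
    species_genes: Iterable[str] | None = None,
) -> tuple[dict[str, str], int]:
    """Propagate human CNV status to one species' homologs.

    Each homolog inherits its human partner's status. A species gene mapped
    to both a CNV and a non-CNV human gene gets the dominant CNV label (with
    a warning). Returns (status mapping, number of species genes excluded
    because they are absent from the table or their human partner is
    unclassified). *species_genes*, when given, is the full gene universe of
    the species used for the exclusion count.
    """
    sub = table[table["species"] == species]
    dup = sub.duplicated(subset=["human_gene_id", "species"], keep=False)
    if dup.any():
        conflicting = sub[dup]
        pairs = conflicting.groupby("human_gene_id")["homolog_gene_id"].nunique()
        bad = pairs[pairs > 1]
        if not bad.empty:
            raise ValidationError(
                "conflicting homolog rows for human gene(s): "
                + ", ".join(sorted(bad.index))
            )
    status: dict[str, str] = {}
    for row in sub.itertuples(index=False):
        human_stat = human_status.get(row.human_gene_id)
        if human_stat is None:
            continue
        prev = status.get(row.homolog_gene_id)
        if prev is not None and prev != human_stat:
            logger.warning(
                "homolog %s maps to both CNV and non-CNV human genes; "
                "keeping CNV",
                row.homolog_gene_id,
            )
            status[row.homolog_gene_id] = CNV
        else:
            status[row.homolog_gene_id] = human_stat
    if species_genes is not None:
        universe = set(species_genes)
        excluded = len(universe - set(status))
        status = {g: s for g, s in status.items() if g in universe}
    else:
        excluded = 0
    return status, excluded


def classify_mirnas(
    mirnas: Iterable[MiRNARecord],
    cnv_gene_intervals: Iterable[GenomicInterval],
) -> tuple[list[MiRNARecord], float]:
    """Label each miRNA CNV-miRNA iff its location overlaps >= 1 CNV gene
    interval. Returns (annotated records, CNV fraction)."""
    arrays = _by_chrom(cnv_gene_intervals)
    out = []
    n_cnv = 0
    for rec in mirnas:
        if rec.interval is not None and _overlaps_any(arrays, rec.interval):
            rec.cnv_class = CNV_MIRNA
            n_cnv += 1
        else:
            rec.cnv_class = NON_CNV_MIRNA
        out.append(rec)
    frac = n_cnv / len(out) if out else 0.0
    return out, frac
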