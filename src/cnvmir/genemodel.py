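"""Transcript ingestion and 3'UTR-length gene classification.

One gene is represented by its single longest mRNA. Region lengths are
derived from the CDS coordinates printed in transcript tables (1-based,
inclusive, on the mRNA):

    utr5_len = cds_start - 1
    cds_len  = cds_end - cds_start + 1
    utr3_len = mrna_length - cds_end

Genes whose selected transcript has a 3'UTR of at least ``LONG_UTR_THRESHOLD``
nucleotides are "long" 3'UTR genes; the rest are "short" and are presumed to
lack canonical (3'UTR-mediated) miRNA regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

#: a 3'UTR of at least this many nucleotides counts as "long"
LONG_UTR_THRESHOLD = 8

REQUIRED_COLUMNS = [
    "gene_id",
    "transcript_id",
    "species",
    "chrom",
    "start",
    "end",
    "strand",
    "mrna_length",
    "cds_start",
    "cds_end",
]


@dataclass
class TranscriptRecord:
    """One mRNA with CDS coordinates and (optionally) its sequence.

    Genomic coordinates ``g_start``/``g_end`` are 0-based half-open
    (converted at the reader boundary from the 1-based inclusive table
    columns). CDS positions stay 1-based inclusive on the mRNA, matching
    the source-table convention.
    """

    gene_id: str
    transcript_id: str
    species: str
    chrom: str
    g_start: int
    g_end: int
    strand: str
    mrna_length: int
    cds_start: int
    cds_end: int
    sequence: str | None = field(default=None, repr=False)

    def validate(self) -> None:
        if not (1 <= self.cds_start <= self.cds_end <= self.mrna_length):
            raise ValidationError(
                f"transcript {self.transcript_id}: CDS coordinates "
                f"({self.cds_start}..{self.cds_end}) inconsistent with "
                f"mRNA length {self.mrna_length}"
            )
        if self.g_start >= self.g_end:
            raise ValidationError(
                f"transcript {self.transcript_id}: empty genomic interval"
            )
        if self.sequence is not None and len(self.sequence) != self.mrna_length:
            raise ValidationError(
                f"transcript {self.transcript_id}: sequence length "
                f"{len(self.sequence)} != mRNA length {self.mrna_length}"
            )


@dataclass
class GeneAnnotation:
    """Per-gene region lengths, UTR class and (later) CNV status."""

    gene_id: str
    species: str
    transcript_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    utr_class: str  # "short" | "long"
    cnv_status: str | None = None  # "CNV" | "nonCNV", assigned by cnv_atlas


def read_transcripts(path, seq_path=None) -> list[TranscriptRecord]:
    """Read a tab-delimited transcript table, optionally attaching sequences.

    The table's genomic ``start``/``end`` are 1-based inclusive and converted
    to the internal 0-based half-open convention. FASTA ids in *seq_path*
    must match ``transcript_id``. Invalid rows are reported together in a
    single :class:`ValidationError` naming each offending transcript.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"transcript table missing column(s): {', '.join(missing)}")

    sequences: dict[str, str] = {}
    if seq_path is not None:
        sequences = {
            rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(seq_path), "fasta")
        }

    records: list[TranscriptRecord] = []
    bad: list[str] = []
    for row in table.itertuples(index=False):
        rec = TranscriptRecord(
            gene_id=str(row.gene_id),
            transcript_id=str(row.transcript_id),
            species=str(row.species),
            chrom=str(row.chrom),
            g_start=int(row.start) - 1,
            g_end=int(row.end),
            strand=str(row.strand),
            mrna_length=int(row.mrna_length),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            sequence=sequences.get(str(row.transcript_id)),
        )
        try:
            rec.validate()
        except ValidationError:
            bad.append(rec.transcript_id)
            continue
        records.append(rec)
    if bad:
        raise ValidationError(
            f"{len(bad)} invalid transcript row(s): {', '.join(sorted(bad))}"
        )
    return records


def select_longest_transcript(
    records: Iterable[TranscriptRecord],
) -> dict[str, TranscriptRecord]:
    """Keep one transcript per gene: maximal mRNA length, ties broken by
    lexicographically smallest transcript id (deterministic, order-free)."""
    best: dict[str, TranscriptRecord] = {}
    for rec in records:
        cur = best.get(rec.gene_id)
        if (
            cur is None
            or rec.mrna_length > cur.mrna_length
            or (
                rec.mrna_length == cur.mrna_length
                and rec.transcript_id < cur.transcript_id
            )
        ):
            best[rec.gene_id] = rec
    return best


def compute_region_lengths(rec: TranscriptRecord) -> tuple[int, int, int]:
    """Return (utr5_len, cds_len, utr3_len); they sum to the mRNA length."""
    utr5 = rec.cds_start - 1
    cds = rec.cds_end - rec.cds_start + 1
    utr3 = rec.mrna_length - rec.cds_end
    return utr5, cds, utr3


def classify_utr(utr3_len: int, long_threshold: int = LONG_UTR_THRESHOLD) -> str:
    """Classify a 3'UTR length as ``"long"`` (>= threshold nt) or ``"short"``."""
    if utr3_len < 0:
        raise ValidationError(f"negative 3'UTR length: {utr3_len}")
    return "long" if utr3_len >= long_threshold else "short"


def extract_region_sequences(rec: TranscriptRecord) -> tuple[str, str, str]:
    """Slice the mRNA sequence into (5'UTR, CDS, 3'UTR); concatenation of the
    three pieces reproduces the full sequence."""
    if rec.sequence is None:
        raise ValidationError(
            f"transcript {rec.transcript_id} has no sequence attached"
        )
    s = rec.sequence
    return s[: rec.cds_start - 1], s[rec.cds_start - 1 : rec.cds_end], s[rec.cds_end :]


def annotate_genes(
    selected: Mapping[str, TranscriptRecord],
    long_threshold: int = LONG_UTR_THRESHOLD,
) -> pd.DataFrame:
    """Build the per-gene annotation table from deduplicated transcripts.

    Returns a DataFrame with columns gene_id, species, transcript_id,
    utr5_len, cds_len, utr3_len, mrna_length, utr_class (cnv_status is
    added later by the CNV atlas step).
    """
    rows = []
    for gene_id in sorted(selected):
        rec = selected[gene_id]
        u5, cds, u3 = compute_region_lengths(rec)
        rows.append(
            {
                "gene_id": gene_id,
                "species": rec.species,
                "transcript_id": rec.transcript_id,
                "utr5_len": u5,
                "cds_len": cds,
                "utr3_len": u3,
                "mrna_length": rec.mrna_length,
                "utr_class": classify_utr(u3, long_threshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "species",
            "transcript_id",
            "utr5_len",
            "cds_len",
            "utr3_len",
            "mrna_length",
            "utr_class",
        ],
    )
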