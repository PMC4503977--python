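"""miRNA binding-site prediction with two independent scanners.

Two transparent scanners are applied to the 5'UTR, CDS and 3'UTR of each
mRNA and their predictions intersected, so that only interactions called by
both survive — the usual both-algorithms filter used to suppress single-
predictor false positives.

``seed_sites``
    Canonical seed matching: every occurrence on the target of the reverse
    complement of miRNA positions 2-7 is a 6mer site, upgraded to 7mer-m8
    (pairing extends to position 8), 7mer-A1 (adenosine opposite miRNA
    position 1) or 8mer (both).

``walk_sites``
    Longest-consecutive-complementarity scanning: at each target position
    the longest run of Watson-Crick pairs anchored at miRNA position 1 or 2
    is computed; maximal runs of at least ``min_len`` (default 7) nt are
    reported as ``walk-k`` sites.

Both scanners use Watson-Crick pairs only (U === T; G:U wobble optionally
allowed) and report every occurrence, including overlapping ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cnv_atlas import MiRNARecord
from .errors import ValidationError

logger = logging.getLogger(__name__)

REGIONS = ("UTR5", "CDS", "UTR3")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize(seq: str) -> str:
    """Uppercase and fold RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _pairs(target_base: str, mirna_base: str, wobble: bool) -> bool:
    if target_base == mirna_base.translate(_COMPLEMENT):
        return True
    if wobble:
        # G:U wobble: target G pairs miRNA U(T); target T pairs miRNA G
        return (target_base == "G" and mirna_base == "T") or (
            target_base == "T" and mirna_base == "G"
        )
    return False


@dataclass(frozen=True)
class BindingSite:
    """One predicted miRNA site on a region sequence.

    ``pos`` is the 0-based start of the matched span on the region;
    ``length`` its extent in nt.
    """

    mirna_id: str
    gene_id: str
    region: str
    pos: int
    length: int
    site_type: str
    predictor: str  # "seed" | "walk" | "consensus"

    @property
    def end(self) -> int:
        return self.pos + self.length


def _find_all(haystack: str, needle: str):
    """Yield all (overlapping) occurrence starts of needle in haystack."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def seed_sites(
    mirna: MiRNARecord,
    target_seq: str,
    gene_id: str = "",
    region: str = "UTR3",
    allow_wobble: bool = False,
) -> list[BindingSite]:
    """Canonical seed-match scan of one target region.

    Reports every occurrence of the reverse complement of miRNA positions
    2-7 and classifies the 6mer/7mer-A1/7mer-m8/8mer upgrade at each one.
    Wobble pairing, when enabled, applies to the seed core occurrence test
    via a per-position comparison (slower path).
    """
    m = normalize(mirna.mature_seq)
    if len(m) < 8:
        raise ValidationError(f"miRNA {mirna.mirna_id} shorter than 8 nt")
    t = normalize(target_seq)
    if len(t) < 6:
        return []
    sites: list[BindingSite] = []
    if not allow_wobble:
        core = revcomp(m[1:7])
        starts = _find_all(t, core)
    else:
        starts = (
            p
            for p in range(len(t) - 5)
            # core pairs miRNA positions 2..7; target 5'->3' reverses order
            if all(_pairs(t[p + k], m[6 - k], True) for k in range(6))
        )
    comp_m8 = m[7].translate(_COMPLEMENT)
    for p in starts:
        has_m8 = p >= 1 and (
            t[p - 1] == comp_m8 or (allow_wobble and _pairs(t[p - 1], m[7], True))
        )
        has_a1 = p + 6 < len(t) and t[p + 6] == "A"
        if has_m8 and has_a1:
            site_type, start, length = "8mer", p - 1, 8
        elif has_m8:
            site_type, start, length = "7mer-m8", p - 1, 7
        elif has_a1:
            site_type, start, length = "7mer-A1", p, 7
        else:
            site_type, start, length = "6mer", p, 6
        sites.append(
            BindingSite(mirna.mirna_id, gene_id, region, start, length, site_type, "seed")
        )
    return sites


def walk_sites(
    mirna: MiRNARecord,
    target_seq: str,
    min_len: int = 7,
    gene_id: str = "",
    region: str = "UTR3",
    allow_wobble: bool = False,
) -> list[BindingSite]:
    """Longest-consecutive-complementarity scan of one target region.

    A run of k Watson-Crick pairs anchored at miRNA position 1 covers
    miRNA positions 1..k; anchored at position 2, positions 2..k+1. Runs
    are extended maximally toward the miRNA 3' end and reported once, as
    ``walk-k``; a position-2 run whose position-1 pair also matches is
    subsumed by the position-1 run and not double-reported.
    """
    if min_len < 6:
        raise ValidationError(f"min_len must be >= 6, got {min_len}")
    m = normalize(mirna.mature_seq)
    if len(m) < min_len + 1:
        raise ValidationError(f"miRNA {mirna.mirna_id} shorter than min_len+1")
    t = normalize(target_seq)
    if len(t) < min_len:
        return []

    def pair_ok(tpos: int, mpos: int) -> bool:
        return _pairs(t[tpos], m[mpos], allow_wobble)

    sites: list[BindingSite] = []
    for anchor in (0, 1):  # miRNA position 1 or 2 (0-based index)
        if not allow_wobble:
            pattern = revcomp(m[anchor : anchor + min_len])
            seeds = _find_all(t, pattern)
        else:
            seeds = (
                p
                for p in range(len(t) - min_len + 1)
                if all(
                    pair_ok(p + k, anchor + min_len - 1 - k) for k in range(min_len)
                )
            )
        for q in seeds:
            # target position q + min_len - 1 pairs miRNA position anchor+1;
            # extension toward the miRNA 3' end grows the span leftwards.
            if anchor == 1:
                opp1 = q + min_len
                if opp1 < len(t) and pair_ok(opp1, 0):
                    continue  # contained in an anchor-1 run
            k = min_len
            while q - 1 >= 0 and anchor + k < len(m) and pair_ok(q - 1, anchor + k):
                q -= 1
                k += 1
            sites.append(
                BindingSite(
                    mirna.mirna_id, gene_id, region, q, k, f"walk-{k}", "walk"
                )
            )
    sites.sort(key=lambda s: (s.pos, s.length, s.site_type))
    return sites


def consensus_sites(
    a: Sequence[BindingSite], b: Sequence[BindingSite]
) -> list[BindingSite]:
    """Intersect seed predictions *a* with walk predictions *b*.

    Each (seed, walk) pair for the same miRNA/gene/region whose spans share
    >= 1 nt yields one consensus site at the seed-site coordinates.
    """
    by_key: dict[tuple, list[BindingSite]] = {}
    for w in b:
        by_key.setdefault((w.mirna_id, w.gene_id, w.region), []).append(w)
    out: list[BindingSite] = []
    for s in a:
        for w in by_key.get((s.mirna_id, s.gene_id, s.region), []):
            if s.pos < w.end and w.pos < s.end:
                out.append(
                    BindingSite(
                        s.mirna_id,
                        s.gene_id,
                        s.region,
                        s.pos,
                        s.length,
                        s.site_type,
                        "consensus",
                    )
                )
    return out


def scan_gene(
    gene_id: str,
    region_seqs: dict[str, str],
    mirnas: Iterable[MiRNARecord],
    mode: str = "consensus",
    min_walk_len: int = 7,
    allow_wobble: bool = False,
) -> list[BindingSite]:
    """Scan one gene's region sequences against a set of miRNAs."""
    sites: list[BindingSite] = []
    for region in REGIONS:
        seq = region_seqs.get(region, "")
        if not seq:
            continue
        for mir in mirnas:
            if mode == "seed":
                sites.extend(seed_sites(mir, seq, gene_id, region, allow_wobble))
            elif mode == "walk":
                sites.extend(
                    walk_sites(mir, seq, min_walk_len, gene_id, region, allow_wobble)
                )
            elif mode == "consensus":
                s = seed_sites(mir, seq, gene_id, region, allow_wobble)
                if not s:
                    continue
                w = walk_sites(mir, seq, min_walk_len, gene_id, region, allow_wobble)
                sites.extend(consensus_sites(s, w))
            else:
                raise ValidationError(f"unknown scan mode: {mode}")
    return sites


def count_sites(
    genes: pd.DataFrame,
    region_sequences: dict[str, dict[str, str]],
    mirnas: Sequence[MiRNARecord],
    mode: str = "consensus",
    min_walk_len: int = 7,
    allow_wobble: bool = False,
) -> pd.DataFrame:
    """Total binding sites per (gene, region) across all miRNAs.

    *genes* is the annotation table (gene_id, species, utr_class and,
    optionally, cnv_status); *region_sequences* maps gene_id -> region ->
    sequence. Genes without sequences are excluded and logged. Zero-length
    regions get an explicit 0 row, so every gene contributes one row per
    region. Also emits ``n_distinct_mirnas``, the number of distinct miRNA
    types with at least one site in the region.
    """
    rows = []
    skipped = 0
    for g in genes.itertuples(index=False):
        seqs = region_sequences.get(g.gene_id)
        if seqs is None:
            skipped += 1
            continue
        sites = scan_gene(g.gene_id, seqs, mirnas, mode, min_walk_len, allow_wobble)
        per_region: dict[str, list[BindingSite]] = {r: [] for r in REGIONS}
        for s in sites:
            per_region[s.region].append(s)
        for region in REGIONS:
            rs = per_region[region]
            rows.append(
                {
                    "species": g.species,
                    "gene_id": g.gene_id,
                    "cnv_status": getattr(g, "cnv_status", None),
                    "utr_class": g.utr_class,
                    "region": region,
                    "n_sites": len(rs),
                    "n_distinct_mirnas": len({s.mirna_id for s in rs}),
                }
            )
    if skipped:
        logger.warning("%d gene(s) without sequences excluded from scan", skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "gene_id",
            "cnv_status",
            "utr_class",
            "region",
            "n_sites",
            "n_distinct_mirnas",
        ],
    )


def mean_sites_per_gene(
    table: pd.DataFrame,
    group_by: Sequence[str] = ("species", "cnv_status", "utr_class", "region"),
) -> pd.DataFrame:
    """Mean and SEM of sites per gene within each group.

    SEM is the sample standard deviation over sqrt(n); a single-gene group
    reports SEM 0 and is flagged with n = 1.
    """
    if table.empty:
        raise ValidationError("empty site-count table")
    out = []
    for key, grp in table.groupby(list(group_by), dropna=False, sort=True):
        vals = grp["n_sites"].to_numpy(dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        row = dict(zip(group_by, key if isinstance(key, tuple) else (key,)))
        row.update({"mean": float(np.mean(vals)), "sem": sem, "n": n})
        out.append(row)
    return pd.DataFrame(out)
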