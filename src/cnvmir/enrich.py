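"""Overrepresentation analysis: Fisher's exact test plus multiplicity control.

The two-sided Fisher p is defined by the minimum-likelihood rule: with the
table margins fixed, sum the hypergeometric probabilities of every table at
least as improbable as the observed one. The sum is computed with exact
integer binomial coefficients (a table with total n has at most n+1
same-margin configurations), so p is the correctly rounded float of an
exact rational — implementations of this test genuinely differ in the
two-sided rule, so it is pinned down here rather than delegated.

Holm (step-down) and Benjamini-Hochberg (step-up FDR) adjustments are
delegated to statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, inf
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ValidationError
from .sitescan import REGIONS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b | c, d): a = feature in set, b = feature in complement,
    c = non-feature in set, d = non-feature in complement."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("negative count in 2x2 table")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("all-zero 2x2 table")


@dataclass
class EnrichmentResult:
    label: str
    table: ContingencyTable2x2
    odds_ratio: float
    p: float
    p_adj: float | None = None
    significant: bool | None = None


def fisher_exact(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test.

    Returns (odds_ratio, p). The odds ratio is the sample ad/bc (inf when
    bc = 0 and ad > 0; NaN when both products vanish). p sums, over the
    support k of a with margins fixed, the probabilities
    C(r1,k) C(r2,c1-k) / C(n,c1) whose numerator weight does not exceed
    the observed one (exact integer comparison, so ties are exact).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c)
    num = sum(
        w for k in range(lo, hi + 1) if (w := comb(r1, k) * comb(r2, c1 - k)) <= w_obs
    )
    p = num / comb(n, c1)
    ad, bc = a * d, b * c
    if bc == 0:
        odds = inf if ad > 0 else float("nan")
    else:
        odds = ad / bc
    return odds, min(p, 1.0)


def adjust_pvalues(ps: Sequence[float], method: str = "holm") -> np.ndarray:
    """Adjust p-values ('holm' or 'bh'), returned in the input order."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps
    if np.any((ps < 0) | (ps > 1) | ~np.isfinite(ps)):
        raise ValidationError("p-values must lie in [0, 1]")
    sm_method = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if sm_method is None:
        raise ValidationError(f"unknown adjustment method: {method}")
    return multipletests(ps, method=sm_method)[1]


def build_site_table(
    counts: pd.DataFrame,
    mask_a: pd.Series,
    mask_b: pd.Series,
    region: str,
) -> ContingencyTable2x2:
    """2x2 layout for binding-site enrichment of *region* in category A vs B:
    a = A sites in region, b = A sites elsewhere, c/d likewise for B."""
    if region not in REGIONS:
        raise ValidationError(f"unknown region: {region}")
    in_region = counts["region"] == region
    a = int(counts.loc[mask_a & in_region, "n_sites"].sum())
    b = int(counts.loc[mask_a & ~in_region, "n_sites"].sum())
    c = int(counts.loc[mask_b & in_region, "n_sites"].sum())
    d = int(counts.loc[mask_b & ~in_region, "n_sites"].sum())
    return ContingencyTable2x2(a, b, c, d)


def site_enrichment(
    counts: pd.DataFrame,
    contrast: tuple[Mapping[str, str], Mapping[str, str]],
    region: str,
    label: str | None = None,
) -> EnrichmentResult | None:
    """Fisher test for enrichment of sites in *region* between two gene
    categories, each given as a column->value filter on the count table.
    Returns None (with a warning) when either category is empty."""

    def mask(flt: Mapping[str, str]) -> pd.Series:
        m = pd.Series(True, index=counts.index)
        for col, val in flt.items():
            m &= counts[col] == val
        return m

    mask_a, mask_b = mask(contrast[0]), mask(contrast[1])
    if not mask_a.any() or not mask_b.any():
        logger.warning("empty category in contrast %s; skipped", contrast)
        return None
    table = build_site_table(counts, mask_a, mask_b, region)
    if table.a + table.b + table.c + table.d == 0:
        logger.warning("no sites in contrast %s; skipped", contrast)
        return None
    odds, p = fisher_exact(table)
    if label is None:
        label = f"{contrast[0]} vs {contrast[1]} in {region}"
    return EnrichmentResult(label, table, odds, p)


def site_enrichment_run(
    counts: pd.DataFrame,
    contrasts: Sequence[tuple[Mapping[str, str], Mapping[str, str], str]],
    method: str = "holm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run several site-enrichment contrasts and correct across them.

    Each contrast is (filter_a, filter_b, region). The default correction
    is Holm, applied over all tests of the run.
    """
    results = []
    for flt_a, flt_b, region in contrasts:
        res = site_enrichment(counts, (flt_a, flt_b), region)
        if res is not None:
            results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["label", "a", "b", "c", "d", "odds_ratio", "p", "p_adj", "significant"]
        )
    adj = adjust_pvalues([r.p for r in results], method)
    rows = []
    for r, pa in zip(results, adj):
        r.p_adj, r.significant = float(pa), bool(pa < alpha)
        rows.append(
            {
                "label": r.label,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT-style pathway map: pathway_id <tab> name <tab> gene ids."""
    annotations: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 GMT columns")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway with no genes")
            annotations[fields[0]] = (fields[1], genes)
    return annotations


def pathway_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, tuple[str, set[str]]],
    alpha: float = 0.05,
    method: str = "bh",
) -> pd.DataFrame:
    """Per-pathway Fisher overrepresentation of *gene_set* within *universe*,
    Benjamini-Hochberg corrected across pathways by default."""
    gene_set, universe = set(gene_set), set(universe)
    if not gene_set <= universe:
        raise ValidationError("gene set is not a subset of the universe")
    rows = []
    for pathway_id in sorted(annotations):
        name, genes = annotations[pathway_id]
        members = genes & universe
        if not members:
            logger.warning("pathway %s has no universe genes; skipped", pathway_id)
            continue
        a = len(gene_set & members)
        b = len(gene_set - members)
        c = len(members - gene_set)
        d = len(universe) - a - b - c
        odds, p = fisher_exact(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "pathway_id": pathway_id,
                "name": name,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["p_adj"] = result["significant"] = []
        return result
    result["p_adj"] = adjust_pvalues(result["p"].to_numpy(), method)
    result["significant"] = result["p_adj"] < alpha
    return result
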