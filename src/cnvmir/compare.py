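"""Cross-group statistics: ANOVA omnibus, Wilcoxon rank-sum, DER contrasts.

The comparison protocol mirrors the usual two-stage design: a one-way
ANOVA over all species first, then pairwise reference-vs-other Wilcoxon
rank-sum tests. The Wilcoxon test is exact (full enumeration of the
rank-sum null) for small tie-free samples and uses the normal
approximation with midranks, tie-corrected variance and continuity
correction otherwise. All tests are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: largest combined sample size for which the exact null is enumerated
EXACT_LIMIT = 12


@dataclass
class ComparisonResult:
    groups: tuple[str, ...]
    statistic: float
    p: float
    test: str  # "anova" | "wilcoxon"
    group_means: tuple[float, ...] = ()
    group_sems: tuple[float, ...] = ()
    group_ns: tuple[int, ...] = ()
    exact: bool | None = None
    note: str = ""


def _describe(values: Sequence[np.ndarray]):
    means, sems, ns = [], [], []
    for v in values:
        v = np.asarray(v, dtype=float)
        n = len(v)
        means.append(float(np.mean(v)) if n else float("nan"))
        sems.append(float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
        ns.append(n)
    return tuple(means), tuple(sems), tuple(ns)


def anova_oneway(
    groups: Mapping[str, Sequence[float]], log1p: bool = False
) -> ComparisonResult:
    """One-way ANOVA across named groups (raw values by default)."""
    names = tuple(groups)
    if len(names) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    for name, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValidationError(f"group {name} has fewer than 2 values")
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"group {name} contains non-finite values")
    if log1p:
        arrays = [np.log1p(a) for a in arrays]
    means, sems, ns = _describe(arrays)
    concat = np.concatenate(arrays)
    if np.ptp(concat) == 0:
        # all values identical in every group: no variance anywhere, report
        # no difference instead of a 0/0 F statistic
        return ComparisonResult(
            names, float("nan"), 1.0, "anova", means, sems, ns, note="zero variance"
        )
    f, p = stats.f_oneway(*arrays)
    return ComparisonResult(names, float(f), float(p), "anova", means, sems, ns)


def _rank_sum_exact_p(ranks_x_sum: float, n_x: int, ranks: np.ndarray) -> float:
    """Exact two-sided p for the rank sum of x by dynamic-programming
    enumeration of all C(N, n_x) subset sums of the (integer) rank vector."""
    scaled = np.rint(ranks * 2).astype(int)  # midranks are multiples of 1/2
    w_obs = int(round(ranks_x_sum * 2))
    total = int(scaled.sum())
    # dp[k][s] = number of k-subsets of the ranks with scaled sum s
    dp = [np.zeros(total + 1, dtype=np.int64) for _ in range(n_x + 1)]
    dp[0][0] = 1
    for r in scaled:
        for k in range(n_x, 0, -1):
            dp[k][r:] = dp[k][r:] + dp[k - 1][: total + 1 - r]
    dist = dp[n_x]
    n_total = int(dist.sum())
    lower = int(dist[: w_obs + 1].sum())
    upper = int(dist[w_obs:].sum())
    p = 2 * min(lower, upper) / n_total
    return min(p, 1.0)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_limit: int = EXACT_LIMIT
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when n_x + n_y <= *exact_limit* and there are no
    ties; otherwise the normal approximation with midranks, tie-corrected
    variance and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty sample in Wilcoxon test")
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks for ties
    w = float(ranks[:n_x].sum())
    has_ties = len(np.unique(pooled)) < len(pooled)
    means, sems, ns = _describe([x, y])
    if n_x + n_y <= exact_limit and not has_ties:
        p = _rank_sum_exact_p(w, n_x, ranks)
        return ComparisonResult(("x", "y"), w, p, "wilcoxon", means, sems, ns, True)
    n = n_x + n_y
    mu = n_x * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return ComparisonResult(
            ("x", "y"), w, 1.0, "wilcoxon", means, sems, ns, False, "all values tied"
        )
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return ComparisonResult(("x", "y"), w, min(p, 1.0), "wilcoxon", means, sems, ns, False)


def compare_species_means(
    table: pd.DataFrame,
    reference: str = "hsa",
    value_col: str = "value",
    alpha: float = 0.05,
    holm: bool = False,
    log1p: bool = False,
) -> pd.DataFrame:
    """ANOVA omnibus over species, then reference-vs-each-other Wilcoxon.

    *table* needs columns (species, value_col). Pairwise p values are raw
    by default; pass ``holm=True`` for a step-down correction over the
    pairwise family. Returns one 'anova' row followed by one row per pair.
    """
    species = sorted(table["species"].unique())
    if reference not in species:
        raise ValidationError(f"reference species {reference!r} absent from table")
    if len(species) < 2:
        raise ValidationError("need at least 2 species to compare")
    groups = {sp: table.loc[table["species"] == sp, value_col].to_numpy() for sp in species}
    omnibus = anova_oneway(groups, log1p=log1p)
    rows = [
        {
            "comparison": "omnibus",
            "test": "anova",
            "statistic": omnibus.statistic,
            "p": omnibus.p,
            "p_adj": omnibus.p,
            "significant": omnibus.p < alpha,
            "mean_a": float("nan"),
            "mean_b": float("nan"),
            "n_a": int(sum(omnibus.group_ns)),
            "n_b": 0,
        }
    ]
    pair_rows = []
    for other in species:
        if other == reference:
            continue
        res = wilcoxon_rank_sum(groups[reference], groups[other])
        pair_rows.append(
            {
                "comparison": f"{reference} vs {other}",
                "test": "wilcoxon",
                "statistic": res.statistic,
                "p": res.p,
                "mean_a": res.group_means[0],
                "mean_b": res.group_means[1],
                "n_a": res.group_ns[0],
                "n_b": res.group_ns[1],
            }
        )
    if pair_rows:
        ps = [r["p"] for r in pair_rows]
        if holm:
            from .enrich import adjust_pvalues

            adj = adjust_pvalues(ps, "holm")
        else:
            adj = ps
        for r, pa in zip(pair_rows, adj):
            r["p_adj"] = float(pa)
            r["significant"] = bool(pa < alpha)
    return pd.DataFrame(rows + pair_rows)


def der_by_target_category(
    der: pd.DataFrame,
    targets: pd.DataFrame,
    gene_status: Mapping[str, str],
    min_group: int = 2,
) -> pd.DataFrame:
    """Compare DER of CNV-gene vs non-CNV-gene targets per miRNA class.

    *der* has columns (gene_id, der); *targets* is a site table with
    columns (mirna_id, gene_id) plus a ``mirna_class`` column; *gene_status*
    maps gene_id -> CNV/nonCNV. For each miRNA class the DER values of its
    CNV-gene targets are tested against its non-CNV-gene targets (Wilcoxon,
    two-sided). Classes with a group smaller than *min_group* are skipped.
    """
    der_map = dict(zip(der["gene_id"], der["der"].astype(float)))
    if (der["der"].astype(float) < 0).any():
        raise ValidationError("negative DER value")
    rows = []
    for mirna_class, grp in targets.groupby("mirna_class", sort=True):
        gene_ids = sorted(set(grp["gene_id"]) & set(der_map))
        cnv_vals = [der_map[g] for g in gene_ids if gene_status.get(g) == "CNV"]
        non_vals = [der_map[g] for g in gene_ids if gene_status.get(g) == "nonCNV"]
        if len(cnv_vals) < min_group or len(non_vals) < min_group:
            logger.warning(
                "miRNA class %s: group too small (CNV n=%d, nonCNV n=%d); skipped",
                mirna_class,
                len(cnv_vals),
                len(non_vals),
            )
            continue
        res = wilcoxon_rank_sum(cnv_vals, non_vals)
        rows.append(
            {
                "mirna_class": mirna_class,
                "mean_der_cnv_targets": res.group_means[0],
                "sem_der_cnv_targets": res.group_sems[0],
                "n_cnv_targets": res.group_ns[0],
                "mean_der_noncnv_targets": res.group_means[1],
                "sem_der_noncnv_targets": res.group_sems[1],
                "n_noncnv_targets": res.group_ns[1],
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
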