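from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvmir import compare
from cnvmir.compare import (
    anova_oneway,
    compare_species_means,
    der_by_target_category,
    wilcoxon_rank_sum,
)
from cnvmir.errors import ValidationError


def wilcoxon_oracle(x, y):
    """Exact two-sided p by brute-force enumeration of all rank
    assignments (tie-free samples only)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n_x = len(x)
    w_obs = ranks[:n_x].sum()
    sums = [sum(c) for c in combinations(ranks, n_x)]
    lower = sum(s <= w_obs + 1e-9 for s in sums)
    upper = sum(s >= w_obs - 1e-9 for s in sums)
    return min(1.0, 2 * min(lower, upper) / len(sums))


class TestAnova:
    def test_identical_groups(self):
        res = anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.statistic == pytest.approx(0) and res.p == pytest.approx(1)

    def test_separated_groups(self):
        res = anova_oneway({"a": [0.0, 0.01, -0.01], "b": [10.0, 10.01, 9.99]})
        assert res.p < 1e-10

    def test_all_values_identical_reports_no_difference(self):
        res = anova_oneway({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert res.p == 1.0 and res.note == "zero variance"

    def test_matches_textbook_two_pass_formula(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            groups = {
                f"g{i}": rng.normal(rng.normal(), 1, size=int(rng.integers(3, 12)))
                for i in range(int(rng.integers(2, 5)))
            }
            res = anova_oneway(groups)
            arrays = list(groups.values())
            grand = np.concatenate(arrays).mean()
            k = len(arrays)
            n_total = sum(len(a) for a in arrays)
            ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
            ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
            f = (ss_between / (k - 1)) / (ss_within / (n_total - k))
            assert res.statistic == pytest.approx(f)
            assert res.p == pytest.approx(stats.f.sf(f, k - 1, n_total - k))

    def test_shift_invariance_and_scale(self):
        rng = np.random.default_rng(32)
        groups = {"a": rng.normal(size=8), "b": rng.normal(1, 1, size=9)}
        f0 = anova_oneway(groups).statistic
        shifted = {k: v + 100.0 for k, v in groups.items()}
        scaled = {k: v * 7.0 for k, v in groups.items()}
        assert anova_oneway(shifted).statistic == pytest.approx(f0)
        assert anova_oneway(scaled).statistic == pytest.approx(f0)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_oneway({"a": [1], "b": [1, 2]})


class TestWilcoxon:
    def test_most_extreme_small_sample(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.exact and res.p == pytest.approx(2 / 6)

    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_path_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(33)
        for _ in range(100):
            n_x = int(rng.integers(1, 6))
            n_y = int(rng.integers(1, 6))
            vals = rng.choice(1000, size=n_x + n_y, replace=False).astype(float)
            x, y = vals[:n_x], vals[n_x:]
            res = wilcoxon_rank_sum(x, y)
            assert res.exact
            assert res.p == pytest.approx(wilcoxon_oracle(x, y), abs=1e-12)

    def test_exact_path_matches_scipy_mannwhitney(self):
        rng = np.random.default_rng(34)
        for _ in range(30):
            n_x, n_y = int(rng.integers(2, 6)), int(rng.integers(2, 7))
            vals = rng.choice(500, size=n_x + n_y, replace=False).astype(float)
            x, y = vals[:n_x], vals[n_x:]
            p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")[1]
            assert wilcoxon_rank_sum(x, y).p == pytest.approx(p_scipy, abs=1e-12)

    def test_large_sample_normal_path_near_scipy(self):
        rng = np.random.default_rng(35)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.4, 1, 70)
        res = wilcoxon_rank_sum(x, y)
        assert not res.exact
        p_ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )[1]
        assert res.p == pytest.approx(p_ref, rel=1e-6)

    def test_tied_values_use_midrank_correction(self):
        x = [1, 2, 2, 3, 5, 5, 5, 8, 9, 9, 11, 12, 13]
        y = [2, 2, 4, 5, 5, 7, 9, 9, 10, 11, 14, 15]
        res = wilcoxon_rank_sum(x, y)
        p_ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )[1]
        assert res.p == pytest.approx(p_ref, rel=1e-6)


class TestSpeciesComparison:
    def _table(self, means, n=60, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sp, mu in means.items():
            for v in rng.poisson(mu, size=n):
                rows.append({"species": sp, "value": float(v)})
        return pd.DataFrame(rows)

    def test_two_species_gives_single_pair(self):
        res = compare_species_means(self._table({"hsa": 10, "mmu": 10}), "hsa")
        assert list(res.comparison) == ["omnibus", "hsa vs mmu"]

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            compare_species_means(self._table({"mmu": 10, "rno": 10}), "hsa")

    def test_shifted_reference_detected_with_power(self):
        """Human mean +50%: every human-vs-other pair significant in >= 80%
        of simulation replicates."""
        hits = 0
        n_reps = 60
        for i in range(n_reps):
            table = self._table(
                {"hsa": 15, "mmu": 10, "rno": 10, "gga": 10}, n=60, seed=100 + i
            )
            res = compare_species_means(table, "hsa")
            pairs = res[res.test == "wilcoxon"]
            hits += bool((pairs.p < 0.05).all())
        assert hits / n_reps >= 0.8

    def test_null_omnibus_calibrated(self):
        """Identical generators: ANOVA omnibus rejects ~5% of the time."""
        rejections = 0
        n_reps = 200
        for i in range(n_reps):
            table = self._table({"hsa": 10, "mmu": 10, "rno": 10}, n=40, seed=500 + i)
            res = compare_species_means(table, "hsa")
            rejections += bool(res.iloc[0].p < 0.05)
        rate = rejections / n_reps
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_reps) <= rate <= 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / n_reps
        )


class TestDerComparison:
    def _inputs(self, delta, n=80, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        status = {g: ("CNV" if i < n // 2 else "nonCNV") for i, g in enumerate(genes)}
        der = pd.DataFrame(
            {
                "gene_id": genes,
                "der": [
                    max(0.0, rng.normal(0.3 + (delta if status[g] == "CNV" else 0), 0.1))
                    for g in genes
                ],
            }
        )
        targets = pd.DataFrame(
            {
                "mirna_id": "m1",
                "gene_id": genes * 2,
                "mirna_class": ["CNV-miRNA"] * n + ["non-CNV-miRNA"] * n,
            }
        )
        return der, targets, status

    def test_planted_shift_detected_for_both_classes(self):
        der, targets, status = self._inputs(delta=0.12, seed=40)
        res = der_by_target_category(der, targets, status)
        assert set(res.mirna_class) == {"CNV-miRNA", "non-CNV-miRNA"}
        assert (res.p < 0.01).all()
        assert (res.mean_der_cnv_targets > res.mean_der_noncnv_targets).all()

    def test_null_shift_mostly_nonsignificant(self):
        flags = 0
        n_reps = 100
        for i in range(n_reps):
            der, targets, status = self._inputs(delta=0.0, seed=600 + i)
            res = der_by_target_category(der, targets, status)
            flags += int((res.p < 0.05).sum())
        rate = flags / (2 * n_reps)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / (2 * n_reps))

    def test_degenerate_group_skipped(self):
        der = pd.DataFrame({"gene_id": ["g1", "g2"], "der": [0.1, 0.2]})
        targets = pd.DataFrame(
            {"mirna_id": "m1", "gene_id": ["g1", "g2"], "mirna_class": "CNV-miRNA"}
        )
        res = der_by_target_category(der, targets, {"g1": "CNV", "g2": "nonCNV"})
        assert res.empty
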