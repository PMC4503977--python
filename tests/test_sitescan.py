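import numpy as np
import pandas as pd
import pytest

from cnvmir.cnv_atlas import MiRNARecord
from cnvmir.errors import ValidationError
from cnvmir.sitescan import (
    BindingSite,
    consensus_sites,
    count_sites,
    mean_sites_per_gene,
    normalize,
    revcomp,
    seed_sites,
    walk_sites,
)

LET7A = MiRNARecord("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


def _naive_pairs(t, m):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return [[t[i] == comp[b] for b in m] for i in range(len(t))]


def _naive_walk(mirna, target, min_len=7):
    """Independent per-position reimplementation of the walk rule."""
    t, m = normalize(target), normalize(mirna.mature_seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    found = []
    for anchor in (0, 1):
        # e = target index opposite miRNA position anchor+1
        for e in range(len(t)):
            if anchor == 1 and e + 1 < len(t) and t[e + 1] == comp[m[0]]:
                continue  # subsumed by the anchor-1 run
            k = 0
            while e - k >= 0 and anchor + k < len(m) and t[e - k] == comp[m[anchor + k]]:
                k += 1
            if k >= min_len:
                found.append((e - k + 1, k))
    return sorted(found)


class TestSeedSites:
    def test_let7_8mer_site(self):
        """CTACCTCA carries a full 2-8 match plus the A1 adenosine."""
        sites = seed_sites(LET7A, "GGGCTACCTCAGGG")
        eight = [s for s in sites if s.site_type == "8mer"]
        assert len(eight) == 1
        s = eight[0]
        assert (s.pos, s.length) == (3, 8)
        assert "GGGCTACCTCAGGG"[s.pos : s.end] == "CTACCTCA"

    @pytest.mark.parametrize(
        "target,expected",
        [
            ("GGCTACCTCAGG", "8mer"),     # m8 pair + A1
            ("GGCTACCTCGGG", "7mer-m8"),  # m8 pair, no A1
            ("GGTTACCTCAGG", "7mer-A1"),  # A1 only (T breaks the m8 pair)
            ("GGTTACCTCGGG", "6mer"),     # bare core
        ],
    )
    def test_site_type_taxonomy(self, target, expected):
        types = {s.site_type for s in seed_sites(LET7A, target)}
        assert types == {expected}

    def test_no_complementarity_gives_empty(self):
        assert seed_sites(LET7A, "A" * 50) == []

    def test_short_target_gives_empty(self):
        assert seed_sites(LET7A, "ACG") == []

    def test_overlapping_occurrences_all_reported(self):
        core = revcomp(normalize(LET7A.mature_seq)[1:7])
        target = core + core[:3] + core  # two occurrences, plus junk
        assert len(seed_sites(LET7A, target)) >= 2

    def test_u_and_t_equivalent(self):
        rna_target = "GGGCUACCUCAGGG"
        assert [s.site_type for s in seed_sites(LET7A, rna_target)] == ["8mer"]


class TestWalkSites:
    def test_seven_consecutive_pairs_is_walk7(self):
        m = normalize(LET7A.mature_seq)
        target = "AAAA" + revcomp(m[:7]) + "AAAA"
        sites = walk_sites(LET7A, target)
        assert [(s.pos, s.site_type) for s in sites] == [(4, "walk-7")]

    def test_extendable_run_reported_once_at_full_length(self):
        m = normalize(LET7A.mature_seq)
        target = "AAAA" + revcomp(m[:9]) + "AAAA"
        sites = walk_sites(LET7A, target)
        assert [(s.pos, s.length, s.site_type) for s in sites] == [(4, 9, "walk-9")]

    def test_min_len_below_six_rejected(self):
        with pytest.raises(ValidationError):
            walk_sites(LET7A, "ACGT" * 10, min_len=5)

    def test_matches_naive_position_scan(self):
        """Implementation equals an independent per-position oracle on
        random sequences and miRNAs."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            mir = MiRNARecord(
                "m", "".join(rng.choice(list("ACGU"), size=22))
            )
            target = "".join(rng.choice(list("ACGT"), size=200))
            got = sorted((s.pos, s.length) for s in walk_sites(mir, target))
            assert got == _naive_walk(mir, target)


def test_walk_background_rate_matches_analytic_expectation():
    """Walk-site count on i.i.d. uniform sequence: ~(L-6) * 4^-7 sites per
    anchor, with the position-2 anchor discounted by the 3/4 chance that
    the position-1 pair fails (else it merges into the position-1 run)."""
    rng = np.random.default_rng(321)
    L, n = 1000, 400
    counts = []
    for _ in range(n):
        t = "".join(rng.choice(list("ACGT"), size=L))
        counts.append(len(walk_sites(LET7A, t)))
    expected = (L - 6) * 4.0**-7 * (1 + 3 / 4)
    se = np.std(counts, ddof=1) / np.sqrt(n)
    assert abs(np.mean(counts) - expected) <= 3 * se


class TestConsensus:
    def _site(self, pos, length, predictor, mirna="m1", gene="g1"):
        return BindingSite(mirna, gene, "UTR5", pos, length, "x", predictor)

    def test_identical_coordinates_yield_one_site(self):
        out = consensus_sites([self._site(5, 7, "seed")], [self._site(5, 7, "walk")])
        assert len(out) == 1 and out[0].predictor == "consensus"
        assert (out[0].pos, out[0].length) == (5, 7)

    def test_disjoint_sites_yield_nothing(self):
        assert consensus_sites([self._site(0, 6, "seed")], [self._site(20, 7, "walk")]) == []

    def test_different_mirna_never_intersects(self):
        out = consensus_sites(
            [self._site(5, 6, "seed", mirna="m1")],
            [self._site(5, 7, "walk", mirna="m2")],
        )
        assert out == []

    def test_matches_bruteforce_pair_intersection(self):
        rng = np.random.default_rng(12)
        seeds = [
            self._site(int(rng.integers(0, 300)), 6, "seed", f"m{rng.integers(3)}")
            for _ in range(100)
        ]
        walks = [
            self._site(int(rng.integers(0, 300)), 7, "walk", f"m{rng.integers(3)}")
            for _ in range(100)
        ]
        got = consensus_sites(seeds, walks)
        expected = [
            (s.mirna_id, s.pos, s.length)
            for s in seeds
            for w in walks
            if s.mirna_id == w.mirna_id and s.pos < w.end and w.pos < s.end
        ]
        assert sorted((s.mirna_id, s.pos, s.length) for s in got) == sorted(expected)

    def test_consensus_contained_in_seed_predictions(self):
        """Every consensus site has seed coordinates and overlaps a walk
        site for the same miRNA (set-containment invariant)."""
        rng = np.random.default_rng(13)
        mir = MiRNARecord("m", "".join(rng.choice(list("ACGU"), size=22)))
        target = "".join(rng.choice(list("ACGT"), size=2000))
        s = seed_sites(mir, target)
        w = walk_sites(mir, target)
        cons = consensus_sites(s, w)
        seed_coords = {(x.pos, x.length) for x in s}
        for c in cons:
            assert (c.pos, c.length) in seed_coords
            assert any(c.pos < x.end and x.pos < c.end for x in w)


class TestCountSites:
    GENES = pd.DataFrame(
        [
            {"gene_id": "g1", "species": "hsa", "cnv_status": "CNV", "utr_class": "short"},
        ]
    )

    def test_single_planted_site_counted_in_utr5(self):
        m = normalize(LET7A.mature_seq)
        utr5 = "GGGG" + revcomp(m[1:8]) + "A" + "GGGG"
        seqs = {"g1": {"UTR5": utr5, "CDS": "G" * 60, "UTR3": ""}}
        table = count_sites(self.GENES, seqs, [LET7A], mode="seed")
        utr5_row = table[table.region == "UTR5"].iloc[0]
        assert utr5_row.n_sites == 1
        assert table[table.region == "UTR3"].iloc[0].n_sites == 0

    def test_empty_mirna_set_gives_all_zero(self):
        seqs = {"g1": {"UTR5": "ACGT" * 10, "CDS": "ACGT" * 30, "UTR3": "ACGT" * 5}}
        table = count_sites(self.GENES, seqs, [], mode="seed")
        assert (table.n_sites == 0).all() and len(table) == 3

    def test_gene_without_sequences_excluded(self):
        table = count_sites(self.GENES, {}, [LET7A], mode="seed")
        assert table.empty

    def test_mirna_order_invariance(self):
        rng = np.random.default_rng(14)
        mirs = [
            MiRNARecord(f"m{i}", "".join(rng.choice(list("ACGU"), size=22)))
            for i in range(5)
        ]
        seqs = {"g1": {"UTR5": "".join(rng.choice(list("ACGT"), size=500)),
                       "CDS": "".join(rng.choice(list("ACGT"), size=500)),
                       "UTR3": ""}}
        a = count_sites(self.GENES, seqs, mirs, mode="consensus")
        b = count_sites(self.GENES, seqs, list(reversed(mirs)), mode="consensus")
        assert a.equals(b)


def test_planted_sites_fully_recovered(small_tables):
    """Every generator-embedded exact 8mer is detected by the seed scanner
    and survives the consensus filter (100% planted-site recovery)."""
    planted = small_tables.planted_sites
    sample = planted.sample(n=min(60, len(planted)), random_state=0)
    mirnas = {m.mirna_id: m for m in small_tables.mirnas}
    tx = small_tables.transcripts.set_index("transcript_id")
    for row in sample.itertuples(index=False):
        tid = row.gene_id + "_t1"
        seq = small_tables.sequences[tid]
        utr5 = seq[: int(tx.loc[tid, "cds_start"]) - 1]
        mir = mirnas[row.mirna_id]
        s = seed_sites(mir, utr5, row.gene_id, "UTR5")
        assert any(x.pos == row.pos and x.site_type == "8mer" for x in s)
        cons = consensus_sites(s, walk_sites(mir, utr5, 7, row.gene_id, "UTR5"))
        assert any(x.pos == row.pos for x in cons)


class TestMeanSites:
    def _table(self, values):
        return pd.DataFrame(
            {
                "species": "hsa",
                "gene_id": [f"g{i}" for i in range(len(values))],
                "cnv_status": "CNV",
                "utr_class": "long",
                "region": "UTR3",
                "n_sites": values,
            }
        )

    def test_mean_and_sem(self):
        out = mean_sites_per_gene(self._table([2, 4]))
        assert out.iloc[0]["mean"] == 3 and out.iloc[0]["sem"] == 1 and out.iloc[0]["n"] == 2

    def test_single_gene_flagged(self):
        out = mean_sites_per_gene(self._table([5]))
        assert out.iloc[0]["sem"] == 0 and out.iloc[0]["n"] == 1

    def test_random_table_matches_direct_recomputation(self):
        rng = np.random.default_rng(15)
        table = pd.DataFrame(
            {
                "species": rng.choice(["hsa", "mmu"], size=100),
                "gene_id": [f"g{i}" for i in range(100)],
                "cnv_status": rng.choice(["CNV", "nonCNV"], size=100),
                "utr_class": rng.choice(["short", "long"], size=100),
                "region": rng.choice(["UTR5", "CDS", "UTR3"], size=100),
                "n_sites": rng.integers(0, 20, size=100),
            }
        )
        out = mean_sites_per_gene(table)
        for row in out.itertuples(index=False):
            vals = table[
                (table.species == row.species)
                & (table.cnv_status == row.cnv_status)
                & (table.utr_class == row.utr_class)
                & (table.region == row.region)
            ]["n_sites"].to_numpy(dtype=float)
            assert row.mean == pytest.approx(vals.mean())
            if len(vals) > 1:
                assert row.sem == pytest.approx(
                    vals.std(ddof=1) / np.sqrt(len(vals))
                )

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            mean_sites_per_gene(self._table([]).iloc[0:0])
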