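import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirmaster import targets
from mirmaster.annotation import MirnaRecord, UtrRecord
from mirmaster.targets import (EnrichmentResult, conserved_sites, empirical_p,
                               enrich_gps, find_seed_sites, perm_pvalue,
                               score_list, seed_match7, site_counts)

# mature with seed AGCACCA -> match7 TGGTGCT
MIR = MirnaRecord("miR-x", "UAGCACCAUCUGAAAUCGGUUA")


def _utr(seq, gene="GeneA", species="rat"):
    return UtrRecord(gene, species, seq)


class TestSeedMatch:
    def test_match7_reverse_complement(self):
        assert seed_match7("AGCACCA") == "TGGTGCT"

    def test_8mer(self):
        sites = find_seed_sites(_utr("AAATGGTGCTAAAA"), MIR)
        assert [(s.site_type, s.utr_pos) for s in sites] == [("8mer", 3)]

    def test_7mer_m8(self):
        sites = find_seed_sites(_utr("AATGGTGCTCAA"), MIR)
        assert [(s.site_type, s.utr_pos) for s in sites] == [("7mer-m8", 2)]

    def test_7mer_a1(self):
        # GGTGCT (m7[1:]) followed by A, without the m8 match upstream
        sites = find_seed_sites(_utr("CCGGTGCTACC"), MIR)
        assert [(s.site_type, s.utr_pos) for s in sites] == [("7mer-A1", 2)]

    def test_8mer_suppresses_overlapping_7mers(self):
        sites = find_seed_sites(_utr("TGGTGCTA"), MIR)
        assert len(sites) == 1 and sites[0].site_type == "8mer"

    def test_no_match_empty(self):
        assert find_seed_sites(_utr("ACACACACACAC"), MIR) == []

    def test_n_never_matches(self):
        assert find_seed_sites(_utr("AAATGGTGNTAAAA"), MIR) == []

    def test_multiple_sites(self):
        sites = find_seed_sites(_utr("TGGTGCTAccccTGGTGCTC"), MIR)
        assert [(s.site_type, s.utr_pos) for s in sites] == [("8mer", 0), ("7mer-m8", 12)]

    @staticmethod
    def _oracle(seq, seed):
        """Exhaustive position scan over every 7/8-mer window."""
        m7 = seed_match7(seed)
        out = []
        for p in range(len(seq)):
            if seq[p:p + 8] == m7 + "A":
                out.append(("8mer", p))
            elif seq[p:p + 7] == m7:
                out.append(("7mer-m8", p))
            elif seq[p:p + 7] == m7[1:] + "A" and seq[p - 1:p + 7] != m7 + "A":
                out.append(("7mer-A1", p))
        return out

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(data=st.data())
    def test_matches_exhaustive_oracle(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=400))
        seed = data.draw(st.text(alphabet="ACGU", min_size=7, max_size=7))
        mir = MirnaRecord("m", "A" + seed + "A" * 14)
        got = [(s.site_type, s.utr_pos) for s in find_seed_sites(_utr(seq), mir)]
        assert got == self._oracle(seq, seed)


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "species", "mirna_id",
                                       "site_type", "utr_pos"])


class TestConservation:
    def test_two_other_species_conserved(self):
        t = _table([("g", "rat", "m", "8mer", 0),
                    ("g", "human", "m", "7mer-A1", 5),
                    ("g", "mouse", "m", "8mer", 9)])
        out = conserved_sites(t)
        assert out["conserved"].tolist() == [True]
        assert out["species_support"].iloc[0] == "rat,human,mouse"

    def test_one_other_species_not_conserved(self):
        t = _table([("g", "rat", "m", "8mer", 0), ("g", "human", "m", "8mer", 5)])
        assert not conserved_sites(t)["conserved"].iloc[0]

    def test_rat_only_not_conserved(self):
        t = _table([("g", "rat", "m", "8mer", 0)])
        assert not conserved_sites(t)["conserved"].iloc[0]

    def test_support_is_per_gene_mirna(self):
        t = _table([("g1", "rat", "m", "8mer", 0),
                    ("g2", "human", "m", "8mer", 0),
                    ("g2", "mouse", "m", "8mer", 0)])
        assert not conserved_sites(t)["conserved"].iloc[0]


class TestScoring:
    def _counts(self, vals, mirna="m"):
        return pd.DataFrame({mirna: vals},
                            index=[f"g{i}" for i in range(len(vals))])

    def test_density_definition(self):
        counts = self._counts([2, 0, 1, 1])
        assert score_list(["g0", "g1", "g2", "g3"], "m", counts) == pytest.approx(1.0)

    def test_no_sites_zero(self):
        assert score_list(["g0"], "m", self._counts([0])) == 0.0

    def test_gene_without_utr_in_denominator(self):
        counts = self._counts([2])
        assert score_list(["g0", "missing"], "m", counts) == pytest.approx(1.0)

    def test_linearity(self):
        counts = self._counts([2, 0, 3])
        genes = ["g0", "g1", "g2"]
        assert score_list(genes, "m", counts * 2) == pytest.approx(
            2 * score_list(genes, "m", counts))

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            score_list([], "m", self._counts([1]))


class TestPermutationP:
    def test_plus_one_floor(self):
        assert perm_pvalue(np.zeros(1000), 0.5) == pytest.approx(1 / 1001)

    def test_observed_below_all(self):
        assert perm_pvalue(np.ones(1000), 0.5) == pytest.approx(1.0)

    def test_tie_counting(self):
        null = np.concatenate([np.full(900, 0.5), np.full(100, 1.2)])
        assert perm_pvalue(null, 1.2) == pytest.approx(101 / 1001)

    def test_monotone_in_observed(self):
        rng = np.random.default_rng(0)
        null = rng.uniform(size=500)
        ps = [perm_pvalue(null, o) for o in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_background_smaller_than_list_errors(self):
        counts = pd.DataFrame({"m": [1, 1]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="background"):
            empirical_p(["g0", "g1"], "m", ["g0", "g1"], counts)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame({"m": rng.poisson(0.2, 200)},
                              index=[f"g{i}" for i in range(200)])
        bg = list(counts.index)
        a = empirical_p(bg[:20], "m", bg, counts, n_perm=200, rng_seed=42)
        b = empirical_p(bg[:20], "m", bg, counts, n_perm=200, rng_seed=42)
        assert a.p_emp == b.p_emp
        assert np.array_equal(a.null_scores, b.null_scores)

    def test_null_uniformity(self):
        """Lists drawn from the background give approximately uniform p."""
        # dense enough that score ties are rare; heavy ties push the
        # (deliberately conservative) >= tie rule above 0.5 on average
        rng = np.random.default_rng(3)
        counts = pd.DataFrame({"m": rng.poisson(2.0, 500)},
                              index=[f"g{i}" for i in range(500)])
        bg = list(counts.index)
        ps = []
        for rep in range(200):
            lst = [bg[i] for i in rng.choice(500, size=40, replace=False)]
            ps.append(empirical_p(lst, "m", bg, counts, n_perm=200,
                                  rng_seed=1000 + rep).p_emp)
        assert 0.45 <= np.mean(ps) <= 0.55


class TestEnrichGps:
    def test_planted_master_recovered(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(400)]
        counts = pd.DataFrame({
            "master": rng.binomial(1, 0.05, 400),
            "other": rng.binomial(1, 0.05, 400),
        }, index=genes)
        gps = genes[:40]
        counts.loc[gps, "master"] = 1  # all list genes carry a conserved site
        out = enrich_gps(gps, ["master", "other"], genes, counts,
                         n_perm=1000, rng_seed=9)
        assert out["mirna_id"].iloc[0] == "master"
        assert out["p_emp"].iloc[0] == pytest.approx(1 / 1001)
        assert out["frac_targeted"].iloc[0] == pytest.approx(1.0)

    def test_zero_sites_everywhere_p_one(self):
        genes = [f"g{i}" for i in range(50)]
        counts = pd.DataFrame({"m": np.zeros(50, dtype=int)}, index=genes)
        out = enrich_gps(genes[:5], ["m"], genes, counts, n_perm=100, rng_seed=0)
        assert out["p_emp"].iloc[0] == pytest.approx(1.0)

    def test_frac_targeted(self):
        genes = [f"g{i}" for i in range(40)]
        counts = pd.DataFrame({"m": [1] + [0] * 39}, index=genes)
        out = enrich_gps(genes[:4], ["m"], genes, counts, n_perm=50, rng_seed=0)
        assert out["frac_targeted"].iloc[0] == pytest.approx(0.25)

    def test_empty_list_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            out = enrich_gps([], ["m"], ["g0"], pd.DataFrame(), n_perm=10, rng_seed=0)
        assert out.empty


def test_site_counts_wide(small_study):
    from mirmaster.targets import find_sites_all
    table = find_sites_all(small_study.utrs, small_study.mirnas)
    cons = conserved_sites(table)
    counts = site_counts(cons)
    # planted truth: conserved rat site counts agree exactly
    truth = small_study.truth.site_truth
    truth_rat = truth[(truth["species"] == "rat") & truth["conserved"]]
    for row in truth_rat.itertuples(index=False):
        assert counts.loc[row.gene_id, row.mirna_id] == row.n_sites
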