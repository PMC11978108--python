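"""Site thinning, mate-type and sibship posteriors, rate summaries."""

import numpy as np
import pandas as pd
import pytest

import hybridzone as hz
from hybridzone import hmm, mating

from oracles import brute_force_mate_type, brute_force_sibship


def panel_from_positions(positions, chrom="chr01"):
    return hz.SitePanel(pd.DataFrame({
        "chrom": chrom, "pos": positions, "allele_a": "A", "allele_b": "T",
        "freq_g": 0.05, "freq_n": 0.95}))


class TestThinning:
    def test_window_counts(self):
        panel = panel_from_positions([1_000, 5_000, 12_000])
        thinned, idx = mating.thin_sites(panel, spacing=10_000, seed=0)
        assert len(thinned) == 2 and len(idx) == 2

    def test_empty_panel(self):
        empty = hz.SitePanel(pd.DataFrame(columns=[
            "chrom", "pos", "allele_a", "allele_b", "freq_g", "freq_n"]))
        thinned, idx = mating.thin_sites(empty, seed=0)
        assert len(thinned) == 0 and len(idx) == 0

    def test_one_site_per_occupied_window(self, small_panel):
        thinned, idx = mating.thin_sites(small_panel, spacing=10_000, seed=1)
        df = small_panel.sites
        occupied = df.groupby(["chrom", (df["pos"] - 1) // 10_000]).ngroups
        assert len(thinned) == occupied
        tdf = thinned.sites
        assert tdf.groupby(["chrom", (tdf["pos"] - 1) // 10_000]).size().max() == 1

    def test_choice_is_random_but_seeded(self, small_panel):
        a, _ = mating.thin_sites(small_panel, seed=1)
        b, _ = mating.thin_sites(small_panel, seed=1)
        c, _ = mating.thin_sites(small_panel, seed=2)
        pd.testing.assert_frame_equal(a.sites, b.sites)
        assert not a.sites["pos"].equals(c.sites["pos"])


class TestMateTypePosterior:
    def test_impossible_under_selfing(self):
        """Mother AA, offspring showing only the other allele: P(selfed)=0."""
        maternal = np.array([[0.0, 0.0, 1.0]])   # AA = dosage 2
        off_lik = hmm.genotype_read_likelihoods(
            np.array([0]), np.array([5]), 0.0)   # five allele_b reads
        p = mating.mate_type_posterior(maternal, off_lik, np.array([0.5]))
        assert p == 0.0

    def test_flat_likelihood_returns_prior(self):
        maternal = np.tile([0.25, 0.5, 0.25], (6, 1))
        off_lik = np.ones((6, 3))
        for prior in (0.3, 0.5, 0.9):
            assert mating.mate_type_posterior(
                maternal, off_lik, np.full(6, 0.4), prior_selfed=prior
            ) == pytest.approx(prior)

    def test_no_sites_returns_prior(self):
        p = mating.mate_type_posterior(np.empty((0, 3)), np.empty((0, 3)),
                                       np.empty(0), prior_selfed=0.7)
        assert p == 0.7

    def test_two_site_enumeration(self):
        """Mother Aa at both sites, offspring aa at both, freq(a)=0.1:
        posterior = (1/4)^2 / ((1/4)^2 + (1/2 * 0.1)^2)."""
        maternal = np.tile([0.0, 1.0, 0.0], (2, 1))
        off_lik = np.tile([1.0, 0.0, 0.0], (2, 1))  # definitely aa (dosage 0)
        pop_a_freq = np.array([0.9, 0.9])           # allele_a freq; freq(a)=0.1
        p = mating.mate_type_posterior(maternal, off_lik, pop_a_freq)
        expected = 0.25 ** 2 / (0.25 ** 2 + 0.05 ** 2)
        assert p == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("case", range(8))
    def test_matches_brute_force(self, case):
        rng = np.random.default_rng(300 + case)
        L = int(rng.integers(1, 6))
        maternal = rng.dirichlet(np.ones(3), size=L)
        off_lik = rng.uniform(0.01, 1, size=(L, 3))
        pop = rng.uniform(0.05, 0.95, size=L)
        prior = rng.uniform(0.2, 0.8)
        got = mating.mate_type_posterior(maternal, off_lik, pop, prior)
        want = brute_force_mate_type(maternal, off_lik, pop, prior)
        assert got == pytest.approx(want, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize("p,call", [
        (0.95, "selfed"), (0.90, "selfed"),
        (0.50, "ambiguous"), (0.11, "ambiguous"),
        (0.10, "outcrossed"), (0.0, "outcrossed"),
        (float("nan"), "ambiguous"),
    ])
    def test_thresholds(self, p, call):
        assert mating.classify_mate_type(p) == call

    @pytest.mark.parametrize("p", [0.0, 0.05, 0.1, 0.3, 0.5, 0.9, 0.97, 1.0])
    def test_antisymmetric_in_p(self, p):
        """Swapping the two model labels (P -> 1-P) swaps the calls."""
        swap = {"selfed": "outcrossed", "outcrossed": "selfed",
                "ambiguous": "ambiguous"}
        assert mating.classify_mate_type(1 - p) == swap[mating.classify_mate_type(p)]


class TestSelfingRate:
    def test_ambiguous_excluded(self):
        calls = pd.DataFrame({"call": ["selfed"] * 23 + ["outcrossed"] * 83
                              + ["ambiguous"] * 6})
        out = mating.selfing_rate(calls)
        assert out["rate"].iloc[0] == pytest.approx(23 / 106)
        assert out["ambiguous"].iloc[0] == 6

    def test_zero_selfed(self):
        calls = pd.DataFrame({"call": ["outcrossed"] * 10})
        assert mating.selfing_rate(calls)["rate"].iloc[0] == 0.0

    def test_empty_group_missing(self):
        calls = pd.DataFrame({"call": ["ambiguous"] * 3})
        assert np.isnan(mating.selfing_rate(calls)["rate"].iloc[0])

    def test_grouped(self):
        calls = pd.DataFrame({
            "call": ["selfed", "outcrossed", "selfed", "selfed"],
            "cohort": ["a", "a", "b", "b"]})
        out = mating.selfing_rate(calls, by=["cohort"]).set_index("cohort")
        assert out.loc["a", "rate"] == 0.5 and out.loc["b", "rate"] == 1.0


class TestSibship:
    def test_shared_rare_allele_favours_full_sib(self):
        maternal = np.tile([0.0, 0.0, 1.0], (5, 1))      # mother AA
        off_lik = np.tile([0.0, 1.0, 0.0], (5, 1))       # both offspring Aa
        pop = np.full(5, 0.99)                            # allele a freq 0.01
        p = mating.sibship_posterior(maternal, off_lik, off_lik, pop)
        assert p < 0.5

    def test_no_information_is_missing(self):
        maternal = np.tile([0.25, 0.5, 0.25], (4, 1))
        flat = np.ones((4, 3))
        p = mating.sibship_posterior(maternal, flat, flat, np.full(4, 0.5))
        assert p == pytest.approx(0.5)
        assert mating.classify_sibship(p) == "missing"

    @pytest.mark.parametrize("case", range(6))
    def test_matches_brute_force(self, case):
        rng = np.random.default_rng(400 + case)
        L = int(rng.integers(1, 4))
        maternal = rng.dirichlet(np.ones(3), size=L)
        l1 = rng.uniform(0.01, 1, size=(L, 3))
        l2 = rng.uniform(0.01, 1, size=(L, 3))
        pop = rng.uniform(0.05, 0.95, size=L)
        got = mating.sibship_posterior(maternal, l1, l2, pop)
        want = brute_force_sibship(maternal, l1, l2, pop)
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("p,call", [
        (0.6, "half"), (0.4, "full"), (0.5, "missing"),
    ])
    def test_classification(self, p, call):
        assert mating.classify_sibship(p) == call


class TestMultiplePaternity:
    def test_fraction_and_flags(self):
        sib = pd.DataFrame({
            "fruit": ["f1", "f1", "f2", "f3"],
            "p_half": [0.9, 0.1, 0.2, 0.3],
            "call": ["half", "full", "full", "full"]})
        per_fruit, summary = mating.multiple_paternity_summary(sib)
        flags = per_fruit.set_index("fruit")["multi_paternal"]
        assert flags["f1"] and not flags["f2"] and not flags["f3"]
        assert summary["fraction"] == pytest.approx(100 / 3)

    def test_single_outcrossed_offspring_ineligible(self, study):
        """Fruits never appear with zero pairs; pairs require >= 2 outcrossed."""
        empty = pd.DataFrame(columns=["fruit", "p_half", "call"])
        per_fruit, summary = mating.multiple_paternity_summary(empty)
        assert per_fruit.empty and summary["eligible_fruits"] == 0


class TestMatingModel:
    def test_end_to_end_on_small_study(self, study):
        reads = study["reads"]
        thinned, idx = mating.thin_sites(reads.panel, 10_000, seed=3)
        counts = hz.ReadCounts(reads.samples, thinned,
                               reads.count_a[:, idx], reads.count_b[:, idx])
        res = hz.MatingModel(counts, study["families"], error=0.01).fit()
        assert set(res.mate_types["call"]) <= {"selfed", "outcrossed", "ambiguous"}
        assert res.mate_types["p_selfed"].dropna().between(0, 1).all()
        assert res.sibships["p_half"].dropna().between(0, 1).all()
        # nasutus mothers self exclusively in the generator
        nas = res.mate_types[res.mate_types["family"].str.startswith("NAS")]
        called = nas[nas["call"] != "ambiguous"]
        assert (called["call"] == "selfed").mean() > 0.9
        assert "Mating-system inference" in res.summary()
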