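"""Generator correctness: block structure, phenology, mating, reads."""

import numpy as np
import pandas as pd
import pytest

import hybridzone as hz
from hybridzone.simulate import meiosis


class TestMosaic:
    def test_pure_parental_boundaries(self, small_gmap):
        for m, expected in ((0.0, 0.0), (1.0, 1.0)):
            mosaics = hz.simulate_mosaic(5, t=8, m=m, gmap=small_gmap, seed=1)
            assert all(mos.true_hi == expected for mos in mosaics)
            assert all(mos.n_switches == 0 for mos in mosaics)

    def test_invalid_parameters_rejected(self, small_gmap):
        with pytest.raises(ValueError):
            hz.simulate_mosaic(1, t=8, m=1.5, gmap=small_gmap, seed=1)
        with pytest.raises(ValueError):
            hz.simulate_mosaic(1, t=0.2, m=0.5, gmap=small_gmap, seed=1)
        with pytest.raises(ValueError):
            hz.simulate_mosaic(1, t=float("nan"), m=0.5, gmap=small_gmap, seed=1)

    def test_markov_expectations(self, small_gmap):
        """Mean HI matches m and switch count matches 2m(1-m)tr per bp,
        both within 3 standard errors of the analytic expectation."""
        n, m, t = 1000, 0.3, 8.0
        mosaics = hz.simulate_mosaic(n, t=t, m=m, gmap=small_gmap, seed=2)
        hi = np.array([mos.true_hi for mos in mosaics])
        assert abs(hi.mean() - m) <= 3 * hi.std(ddof=1) / np.sqrt(n)
        switches = np.array([mos.n_switches for mos in mosaics])
        expected = 2 * m * (1 - m) * t * small_gmap.rate * small_gmap.total_bp * 2
        assert abs(switches.mean() - expected) <= 3 * switches.std(ddof=1) / np.sqrt(n)

    def test_blocks_tile_each_chromosome(self, small_gmap):
        for mos in hz.simulate_mosaic(20, t=10, m=0.4, gmap=small_gmap, seed=3):
            for hap in mos.haplotypes:
                for chrom, (ends, anc) in hap.items():
                    starts = np.concatenate(([0], ends[:-1]))
                    assert (ends - starts > 0).all()
                    assert ends[-1] == small_gmap.lengths[chrom]
                    assert (np.diff(anc) != 0).all()  # adjacent blocks differ


class TestPhenology:
    @staticmethod
    def _metadata(counts: dict[str, int]) -> pd.DataFrame:
        rows = [(f"{c}_{i}", c, f"{c}_plot", "maternal", "", "")
                for c, n in counts.items() for i in range(n)]
        return pd.DataFrame(rows, columns=["sample", "cohort", "plot", "role",
                                           "family", "fruit"])

    def test_disjoint_windows_never_overlap(self):
        params = hz.MatingParams(cohorts={
            "early": hz.CohortParams(m=0.9, selfing=1.0, flower_peak=100,
                                     flower_half_width=5),
            "late": hz.CohortParams(m=0.1, selfing=0.1, flower_peak=140,
                                    flower_half_width=5)})
        indiv, _ = hz.simulate_phenology(self._metadata({"early": 10, "late": 10}),
                                         params, seed=4)
        days = indiv.merge(self._metadata({"early": 10, "late": 10})
                           .rename(columns={"sample": "individual"}),
                           on="individual")
        shared = set(days[days["cohort"] == "early"]["day"]) & \
            set(days[days["cohort"] == "late"]["day"])
        assert shared == set()

    def test_zero_intensity_and_empty_input(self):
        params = hz.MatingParams(cohorts={
            "c": hz.CohortParams(m=0.5, selfing=0.5, flower_peak=120,
                                 flower_intensity=0.0)})
        indiv, plot = hz.simulate_phenology(self._metadata({"c": 10}), params, seed=5)
        assert indiv.empty and plot.empty
        indiv, plot = hz.simulate_phenology(self._metadata({}), params, seed=5)
        assert indiv.empty and plot.empty

    def test_total_flowers_match_poisson_expectation(self):
        n, intensity, half_width = 500, 2.0, 5  # 11-day windows
        params = hz.MatingParams(cohorts={
            "c": hz.CohortParams(m=0.5, selfing=0.5, flower_peak=120,
                                 flower_half_width=half_width,
                                 flower_intensity=intensity)})
        indiv, _ = hz.simulate_phenology(self._metadata({"c": n}), params, seed=6)
        mean = n * (2 * half_width + 1) * intensity
        assert abs(indiv["count"].sum() - mean) <= 3 * np.sqrt(mean)


class TestMating:
    def test_full_selfing_gives_maternal_hi_in_expectation(self, small_gmap,
                                                           small_panel):
        params = hz.MatingParams(cohorts={
            "c": hz.CohortParams(m=0.4, selfing=1.0, flower_peak=120)})
        pop = hz.simulate_founders({"c": 5}, small_gmap, small_panel, params, seed=7)
        census, _ = hz.simulate_phenology(pop.metadata, params, seed=8)
        ped, off = hz.simulate_mating(pop, census, fruits_per_mother=2,
                                      ovules_per_fruit=10, seed=9)
        assert (ped["mate_type"] == "self").all()
        for mother_id, grp in ped.groupby("mother"):
            mat_hi = pop.individuals[mother_id].mosaic.true_hi
            off_hi = np.array([off.individuals[o].mosaic.true_hi
                               for o in grp["offspring"]])
            # meiotic sampling only: mean offspring HI tracks the mother
            assert abs(off_hi.mean() - mat_hi) < 0.1

    def test_disjoint_flowering_prevents_cross_cohort_outcrossing(
            self, small_gmap, small_panel):
        params = hz.MatingParams(cohorts={
            "early": hz.CohortParams(m=0.9, selfing=0.2, flower_peak=100,
                                     flower_half_width=4),
            "late": hz.CohortParams(m=0.1, selfing=0.2, flower_peak=140,
                                    flower_half_width=4)})
        pop = hz.simulate_founders({"early": 8, "late": 8}, small_gmap,
                                   small_panel, params, seed=10)
        census, _ = hz.simulate_phenology(pop.metadata, params, seed=11)
        ped, _ = hz.simulate_mating(pop, census, 2, 4, seed=12)
        cohort = pop.metadata.set_index("sample")["cohort"]
        out = ped[ped["mate_type"] == "outcross"]
        assert len(out) > 0
        assert (cohort.loc[out["mother"]].to_numpy()
                == cohort.loc[out["father"]].to_numpy()).all()

    def test_realized_selfing_fraction_binomial(self, small_gmap):
        panel = hz.random_panel(small_gmap, 100, seed=13)
        s = 0.3
        params = hz.MatingParams(cohorts={
            "c": hz.CohortParams(m=0.3, selfing=s, flower_peak=120)})
        pop = hz.simulate_founders({"c": 200}, small_gmap, panel, params, seed=14)
        census, _ = hz.simulate_phenology(pop.metadata, params, seed=15)
        ped, _ = hz.simulate_mating(pop, census, fruits_per_mother=2,
                                    ovules_per_fruit=5, seed=16)
        n = len(ped)
        assert n == 200 * 10
        frac = (ped["mate_type"] == "self").mean()
        assert abs(frac - s) <= 3 * np.sqrt(s * (1 - s) / n)

    def test_pedigree_mendelian_consistency(self, study):
        """With the truth in hand, every offspring haplotype's ancestry at
        every panel site matches one of its recorded parent's haplotypes."""
        panel = study["reads"].panel
        ped = study["pedigree"].head(40)
        for rec in ped.itertuples():
            child = study["off"].individuals[rec.offspring]
            parents = (study["pop"].individuals[rec.mother],
                       study["pop"].individuals[rec.father])
            for hap_idx, parent in enumerate(parents):
                for chrom in panel.chromosomes:
                    pos = panel.positions(chrom)
                    child_anc = child.mosaic.hap_ancestry_at(hap_idx, chrom, pos)
                    p0 = parent.mosaic.hap_ancestry_at(0, chrom, pos)
                    p1 = parent.mosaic.hap_ancestry_at(1, chrom, pos)
                    assert ((child_anc == p0) | (child_anc == p1)).all()


class TestReads:
    def test_zero_depth_gives_zero_counts(self, study, small_panel):
        ind = next(iter(study["pop"].individuals.values()))
        counts, _ = hz.simulate_reads({"x": ind}, small_panel, depth=0.0,
                                      error=0.0, seed=17)
        assert counts.depth.sum() == 0

    def test_diagnostic_sites_pure_nasutus_error_free(self, small_gmap):
        sites = pd.DataFrame({
            "chrom": "chr01", "pos": np.arange(1, 201) * 1000,
            "allele_a": "A", "allele_b": "T", "freq_g": 0.0, "freq_n": 1.0})
        panel = hz.SitePanel(sites)
        mos = hz.simulate_mosaic(1, t=8, m=1.0, gmap=small_gmap, seed=18)[0]
        ind = hz.Individual("n", "nasutus", "p", mos,
                            hz.simulate.draw_hap_alleles(
                                mos, panel, np.random.default_rng(0)))
        counts, _ = hz.simulate_reads({"n": ind}, panel, depth=20.0,
                                      error=0.0, seed=19)
        assert counts.count_b.sum() == 0 and counts.count_a.sum() > 0

    def test_zero_depth_site_fraction_poisson(self, study):
        n_sites = 200_000
        gmap = hz.GeneticMap.uniform(n_chromosomes=1, chrom_bp=375_000_000)
        panel = hz.random_panel(gmap, n_sites, seed=20)
        mos = hz.simulate_mosaic(1, t=8, m=0.3, gmap=gmap, seed=21)[0]
        ind = hz.Individual("x", "admixed", "p", mos,
                            hz.simulate.draw_hap_alleles(
                                mos, panel, np.random.default_rng(1)))
        counts, _ = hz.simulate_reads({"x": ind}, panel, depth=1.0,
                                      error=0.0, seed=22)
        frac0 = (counts.depth == 0).mean()
        p = np.exp(-1.0)
        assert abs(frac0 - p) <= 3 * np.sqrt(p * (1 - p) / n_sites)

    def test_halve_depth_option(self, small_panel, study):
        ind = next(iter(study["pop"].individuals.values()))
        full, _ = hz.simulate_reads({"x": ind}, small_panel, 4.0, 0.0, seed=23)
        half, _ = hz.simulate_reads({"x": ind}, small_panel, 4.0, 0.0, seed=23,
                                    halve_depth=True)
        assert half.depth.mean() < full.depth.mean()

    def test_parameter_validation(self, small_panel, study):
        ind = next(iter(study["pop"].individuals.values()))
        with pytest.raises(ValueError):
            hz.simulate_reads({"x": ind}, small_panel, -1.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            hz.simulate_reads({"x": ind}, small_panel, 1.0, 0.7, seed=1)
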