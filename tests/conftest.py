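"""Shared fixtures: a small but complete synthetic study used across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hybridzone as hz


@pytest.fixture(scope="session")
def small_gmap() -> hz.GeneticMap:
    return hz.GeneticMap.uniform(n_chromosomes=2, chrom_bp=10_000_000)


@pytest.fixture(scope="session")
def small_panel(small_gmap) -> hz.SitePanel:
    return hz.random_panel(small_gmap, 1500, seed=11)


@pytest.fixture(scope="session")
def study(small_gmap, small_panel):
    """A three-cohort population with offspring, reads and fitted ancestry.

    Small genome and panel: good for qualitative structure (families, cohort
    labels, deviations), not for calibration claims.
    """
    params = hz.MatingParams()
    pop = hz.simulate_founders({"guttatus": 20, "admixed": 20, "nasutus": 10},
                               small_gmap, small_panel, params, seed=21)
    indiv_census, plot_census = hz.simulate_phenology(pop.metadata, params, seed=22)
    pedigree, off = hz.simulate_mating(pop, indiv_census, fruits_per_mother=2,
                                       ovules_per_fruit=4, seed=23)
    everyone = dict(pop.individuals) | dict(off.individuals)
    reads, truth = hz.simulate_reads(everyone, small_panel, depth=2.0,
                                     error=0.01, seed=24)
    results = hz.AncestryModel(reads, small_gmap).fit(min_called=50)
    return {
        "params": params, "pop": pop, "off": off, "everyone": everyone,
        "indiv_census": indiv_census, "plot_census": plot_census,
        "pedigree": pedigree, "reads": reads, "truth": truth,
        "results": results,
        "families": off.metadata[["sample", "family", "fruit"]],
    }


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
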