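"""Synthetic mosaic hybrid-zone populations.

Generates everything the inference side of the package consumes, with known
truth: admixed diploid genomes under a single-pulse Markov (exponential block)
model, cohort-structured flowering schedules, mixed selfing/outcrossing with
pollen drawn in proportion to same-day open flowers, Mendelian transmission
with Poisson crossovers, and binomial low-coverage read sampling with error.

Ancestry is coded 0 = *guttatus*-type (G) and 1 = *nasutus*-type (N)
throughout. Alleles are coded 1 = panel ``allele_a`` and 0 = ``allele_b``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneticMap, SitePanel

G, N = 0, 1


def rng_for(seed: int | np.random.Generator, stage: str) -> np.random.Generator:
    """A named, reproducible generator for one simulation stage.

    Passing a Generator returns it unchanged (caller manages streams);
    passing an integer derives an independent stream keyed by ``stage``.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    digest = hashlib.sha256(stage.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _validate_prob(name: str, value: float) -> None:
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortParams:
    """Per-cohort simulation settings.

    admixture ``m`` is the stationary probability of N ancestry; ``selfing``
    the per-ovule selfing probability; flowering is a window of integer days
    ``[peak - half_width, peak + half_width]`` with Poisson(intensity)
    open flowers per individual per day.
    """

    m: float
    selfing: float
    flower_peak: int
    flower_half_width: int = 10
    flower_intensity: float = 2.0

    def __post_init__(self) -> None:
        _validate_prob("admixture fraction m", self.m)
        _validate_prob("selfing rate", self.selfing)
        if self.flower_half_width < 0 or self.flower_intensity < 0:
            raise ValueError("flowering window and intensity must be non-negative")

    @property
    def flower_days(self) -> np.ndarray:
        return np.arange(self.flower_peak - self.flower_half_width,
                         self.flower_peak + self.flower_half_width + 1)


#: Study-condition defaults: three ancestry cohorts with the admixture levels,
#: selfing rates and phenological ordering seen in a guttatus/nasutus mosaic
#: hybrid zone (N flowers earliest, admixed mid-season, G latest).
DEFAULT_COHORTS: dict[str, CohortParams] = {
    "guttatus": CohortParams(m=0.08, selfing=0.14, flower_peak=142),
    "admixed": CohortParams(m=0.30, selfing=0.20, flower_peak=130),
    "nasutus": CohortParams(m=0.99, selfing=1.0, flower_peak=115),
}

DEFAULT_PULSE_TIME = 8.0
DEFAULT_DEPTH = 1.0
DEFAULT_ERROR = 0.01


@dataclass(frozen=True)
class MatingParams:
    """Population-level simulation parameters (see :class:`CohortParams`)."""

    cohorts: dict[str, CohortParams] = field(
        default_factory=lambda: dict(DEFAULT_COHORTS))
    pulse_time: float = DEFAULT_PULSE_TIME
    depth: float = DEFAULT_DEPTH
    error: float = DEFAULT_ERROR

    def __post_init__(self) -> None:
        if self.pulse_time < 1:
            raise ValueError("pulse time t must be >= 1 generation")
        if self.depth < 0:
            raise ValueError("mean depth must be >= 0")
        if not 0 <= self.error < 0.5:
            raise ValueError("sequencing error must be in [0, 0.5)")


class DiploidMosaic:
    """Two haplotypes of ancestry blocks tiling a genome.

    Each haplotype maps chromosome -> ``(ends, ancestry)`` where ``ends`` are
    half-open block end coordinates (the last equals the chromosome length)
    and ``ancestry`` is int8 in {0 (G), 1 (N)} with adjacent blocks differing.
    """

    def __init__(self, haplotypes: list[dict[str, tuple[np.ndarray, np.ndarray]]],
                 gmap: GeneticMap):
        if len(haplotypes) != 2:
            raise ValueError("a diploid mosaic needs exactly two haplotypes")
        self.haplotypes = haplotypes
        self.gmap = gmap
        for hap in haplotypes:
            for chrom, (ends, anc) in hap.items():
                if len(ends) != len(anc) or ends[-1] != gmap.lengths[chrom]:
                    raise ValueError(f"blocks do not tile chromosome {chrom}")

    def ancestry_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Diploid N-dosage (0/1/2) at 1-based positions on ``chrom``."""
        pos0 = np.asarray(pos) - 1
        out = np.zeros(len(pos0), dtype=np.int8)
        for ends, anc in (self.haplotypes[0][chrom], self.haplotypes[1][chrom]):
            idx = np.searchsorted(ends, pos0, side="right")
            out += anc[idx]
        return out

    def hap_ancestry_at(self, hap: int, chrom: str, pos: np.ndarray) -> np.ndarray:
        ends, anc = self.haplotypes[hap][chrom]
        return anc[np.searchsorted(ends, np.asarray(pos) - 1, side="right")]

    @property
    def true_hi(self) -> float:
        """Genome-wide fraction of N ancestry (bp-weighted over haplotypes)."""
        n_bp = 0.0
        for hap in self.haplotypes:
            for ends, anc in hap.values():
                starts = np.concatenate(([0], ends[:-1]))
                n_bp += float(np.sum((ends - starts)[anc == N]))
        return n_bp / (2 * self.gmap.total_bp)

    @property
    def n_switches(self) -> int:
        return sum(len(anc) - 1 for hap in self.haplotypes
                   for _, anc in hap.values())

    def blocks_frame(self, sample: str = "") -> pd.DataFrame:
        rows = []
        for h, hap in enumerate(self.haplotypes):
            for chrom, (ends, anc) in hap.items():
                starts = np.concatenate(([0], ends[:-1]))
                for s, e, a in zip(starts, ends, anc):
                    rows.append((sample, h, chrom, int(s), int(e), "GN"[a]))
        return pd.DataFrame(rows, columns=["sample", "haplotype", "chrom",
                                           "start", "end", "ancestry"])


def _simulate_haplotype(m: float, rho: float, gmap: GeneticMap,
                        rng: np.random.Generator) -> dict:
    """One haplotype as a two-state Markov path: stationary P(N) = m, switch
    rates rho*m out of G and rho*(1-m) out of N (exponential block lengths)."""
    hap = {}
    rates = {G: rho * m, N: rho * (1 - m)}
    for chrom, length in gmap.lengths.items():
        state = N if rng.random() < m else G
        ends, anc = [], []
        pos = 0.0
        while pos < length:
            rate = rates[state]
            jump = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            pos = min(pos + jump, length)
            end = int(np.ceil(pos)) if pos < length else length
            if end > (ends[-1] if ends else 0):
                if anc and anc[-1] == state:  # merge after a collapsed block
                    ends[-1] = end
                else:
                    ends.append(end)
                    anc.append(state)
            state = 1 - state
        hap[chrom] = (np.asarray(ends, dtype=np.int64),
                      np.asarray(anc, dtype=np.int8))
    return hap


def simulate_mosaic(n: int, t: float, m: float, gmap: GeneticMap,
                    seed: int | np.random.Generator) -> list[DiploidMosaic]:
    """Admixed diploids from a single pulse ``t`` generations ago.

    Each haplotype is an independent Markov path with stationary N-probability
    ``m`` and switch density ``2 m (1-m) t r`` per bp.
    """
    _validate_prob("admixture fraction m", m)
    if not np.isfinite(t) or t < 1:
        raise ValueError(f"pulse time t must be >= 1, got {t}")
    if n < 0:
        raise ValueError("individual count must be non-negative")
    rng = rng_for(seed, "mosaic")
    rho = t * gmap.rate
    return [DiploidMosaic([_simulate_haplotype(m, rho, gmap, rng) for _ in range(2)],
                          gmap) for _ in range(n)]


def draw_hap_alleles(mosaic: DiploidMosaic, panel: SitePanel,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample the two haplotype allele vectors (1 = allele_a) at panel sites,
    conditional on local ancestry and the parental panel frequencies.

    Within-ancestry linkage disequilibrium is ignored: alleles are independent
    Bernoulli draws given ancestry.
    """
    fg = panel.sites["freq_g"].to_numpy(float)
    fn = panel.sites["freq_n"].to_numpy(float)
    alleles = np.zeros((2, len(panel)), dtype=np.int8)
    for h in range(2):
        for chrom in panel.chromosomes:
            sl = panel.chrom_slice(chrom)
            anc = mosaic.hap_ancestry_at(h, chrom, panel.positions(chrom))
            freq = np.where(anc == N, fn[sl], fg[sl])
            alleles[h, sl] = rng.random(sl.stop - sl.start) < freq
    return alleles


@dataclass
class Individual:
    id: str
    cohort: str
    plot: str
    mosaic: DiploidMosaic
    alleles: np.ndarray  # (2, n_sites) int8, 1 = allele_a


@dataclass
class Population:
    """A simulated cohort-structured population with full truth."""

    panel: SitePanel
    gmap: GeneticMap
    params: MatingParams
    individuals: dict[str, Individual]
    metadata: pd.DataFrame  # sample, cohort, plot, role, family, fruit

    def truth_hi(self) -> pd.Series:
        return pd.Series({s: ind.mosaic.true_hi
                          for s, ind in self.individuals.items()}, name="true_hi")


def random_panel(gmap: GeneticMap, n_sites: int, seed: int | np.random.Generator,
                 min_difference: float = 0.8) -> SitePanel:
    """Ancestry-informative sites scattered over the genome, with parental
    allele-frequency difference at least ``min_difference``."""
    rng = rng_for(seed, "panel")
    lengths = np.array(list(gmap.lengths.values()), dtype=float)
    per_chrom = np.round(n_sites * lengths / lengths.sum()).astype(int)
    per_chrom[-1] = n_sites - per_chrom[:-1].sum()
    frames = []
    for (chrom, length), k in zip(gmap.lengths.items(), per_chrom):
        pos = rng.integers(1, length + 1, size=int(k * 1.2) + 8)
        pos = np.unique(pos)[:k]
        while len(pos) < k:  # top up after duplicate removal (rare)
            extra = rng.integers(1, length + 1, size=k)
            pos = np.unique(np.concatenate((pos, extra)))[:k]
        pos = np.sort(pos)
        low = rng.uniform(0.0, (1 - min_difference) / 2, size=k)
        high = rng.uniform((1 + min_difference) / 2, 1.0, size=k)
        flip = rng.random(k) < 0.5
        fg = np.where(flip, high, low)
        fn = np.where(flip, low, high)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "allele_a": "A", "allele_b": "T",
            "freq_g": fg, "freq_n": fn}))
    return SitePanel(pd.concat(frames, ignore_index=True),
                     min_difference=min_difference)


def simulate_founders(counts: dict[str, int], gmap: GeneticMap, panel: SitePanel,
                      params: MatingParams, seed: int | np.random.Generator,
                      plots_per_cohort: int = 2) -> Population:
    """Wild (maternal-generation) individuals for each cohort."""
    rng = rng_for(seed, "founders")
    individuals: dict[str, Individual] = {}
    meta = []
    for ci, (cohort, n) in enumerate(counts.items()):
        cp = params.cohorts[cohort]
        mosaics = simulate_mosaic(n, params.pulse_time, cp.m, gmap, rng)
        for i, mos in enumerate(mosaics):
            sid = f"{cohort[:3].upper()}_{i:04d}"
            plot = f"P{ci + 1}_{i % plots_per_cohort + 1}"
            individuals[sid] = Individual(sid, cohort, plot, mos,
                                          draw_hap_alleles(mos, panel, rng))
            meta.append((sid, cohort, plot, "maternal", "", ""))
    metadata = pd.DataFrame(meta, columns=["sample", "cohort", "plot", "role",
                                           "family", "fruit"])
    return Population(panel, gmap, params, individuals, metadata)


def simulate_phenology(metadata: pd.DataFrame, params: MatingParams,
                       seed: int | np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily open-flower counts per individual and per plot.

    Each individual flowers on the integer days of its cohort window, with an
    independent Poisson(intensity) count per day. Empty input gives empty
    censuses. Returns ``(individual_census, plot_census)`` with columns
    (individual|plot, day, count); zero-count rows are dropped.
    """
    rng = rng_for(seed, "phenology")
    rows = []
    maternal = metadata[metadata["role"] == "maternal"]
    for _, rec in maternal.iterrows():
        cp = params.cohorts[rec["cohort"]]
        days = cp.flower_days
        counts = rng.poisson(cp.flower_intensity, size=len(days))
        keep = counts > 0
        for d, c in zip(days[keep], counts[keep]):
            rows.append((rec["sample"], rec["plot"], int(d), int(c)))
    indiv = pd.DataFrame(rows, columns=["individual", "plot", "day", "count"])
    if indiv.empty:
        plot = pd.DataFrame(columns=["plot", "day", "count"])
    else:
        plot = (indiv.groupby(["plot", "day"], as_index=False)["count"].sum())
    return indiv, plot


def meiosis(ind: Individual, panel: SitePanel, gmap: GeneticMap,
            rng: np.random.Generator) -> tuple[dict, np.ndarray]:
    """One gamete: Poisson crossovers at rate r per bp, alternating between
    the parent's haplotypes. Returns (haplotype blocks, allele vector)."""
    gamete_hap: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    gamete_alleles = np.zeros(len(panel), dtype=np.int8)
    for chrom, length in gmap.lengths.items():
        n_x = rng.poisson(gmap.rate * length)
        xovers = np.sort(rng.integers(1, length, size=n_x)) if n_x else np.array([], dtype=np.int64)
        xovers = np.unique(xovers)
        start_hap = int(rng.integers(2))
        bounds = np.concatenate((xovers, [length]))
        ends_out: list[int] = []
        anc_out: list[int] = []
        seg_start = 0
        for si, seg_end in enumerate(bounds):
            src = (start_hap + si) % 2
            ends, anc = ind.mosaic.haplotypes[src][chrom]
            i0 = np.searchsorted(ends, seg_start, side="right")
            i1 = np.searchsorted(ends, seg_end - 1, side="right")
            for bi in range(i0, i1 + 1):
                e = min(int(ends[bi]), int(seg_end))
                a = int(anc[bi])
                if anc_out and anc_out[-1] == a:
                    ends_out[-1] = e
                else:
                    ends_out.append(e)
                    anc_out.append(a)
            seg_start = int(seg_end)
        gamete_hap[chrom] = (np.asarray(ends_out, dtype=np.int64),
                             np.asarray(anc_out, dtype=np.int8))
        # allele inheritance follows the same segment structure
        sl = panel.chrom_slice(chrom)
        pos0 = panel.positions(chrom) - 1
        seg_idx = np.searchsorted(xovers, pos0, side="right")
        src_at_site = (start_hap + seg_idx) % 2
        chrom_alleles = np.where(src_at_site == 0,
                                 ind.alleles[0, sl], ind.alleles[1, sl])
        gamete_alleles[sl] = chrom_alleles
    return gamete_hap, gamete_alleles


def simulate_mating(pop: Population, indiv_census: pd.DataFrame,
                    fruits_per_mother: int, ovules_per_fruit: int,
                    seed: int | np.random.Generator,
                    mothers: list[str] | None = None) -> tuple[pd.DataFrame, Population]:
    """Fruits and offspring for each mother; returns (pedigree, offspring pop).

    Per ovule: selfed with the mother's cohort selfing probability, otherwise
    the father is drawn among all *other* individuals' open flowers on the
    fruit's day, proportional to flower counts. An outcross attempt with no
    eligible same-day pollen falls back to selfing and is flagged.
    """
    rng = rng_for(seed, "mating")
    if mothers is None:
        mothers = [s for s in pop.individuals
                   if pop.metadata.set_index("sample").loc[s, "role"] == "maternal"]
    day_flowers = {d: sub for d, sub in indiv_census.groupby("day")}
    mother_days = {m: sub for m, sub in indiv_census.groupby("individual")}

    offspring: dict[str, Individual] = {}
    ped_rows, meta_rows = [], []
    for mother_id in mothers:
        mother = pop.individuals[mother_id]
        s = pop.params.cohorts[mother.cohort].selfing
        own = mother_days.get(mother_id)
        if own is None or own.empty:
            raise ValueError(f"mother {mother_id} has no open flowers in the census")
        day_weights = own["count"].to_numpy(float)
        day_weights /= day_weights.sum()
        for f in range(fruits_per_mother):
            fruit_id = f"{mother_id}_F{f + 1}"
            day = int(rng.choice(own["day"].to_numpy(), p=day_weights))
            pool = day_flowers[day]
            pool = pool[pool["individual"] != mother_id]
            pool_ids = pool["individual"].to_numpy()
            pool_w = pool["count"].to_numpy(float)
            for o in range(ovules_per_fruit):
                selfed = rng.random() < s
                fallback = False
                if not selfed and len(pool_ids) == 0:
                    selfed, fallback = True, True
                if selfed:
                    father_id = mother_id
                else:
                    father_id = str(rng.choice(pool_ids, p=pool_w / pool_w.sum()))
                father = pop.individuals[father_id]
                hap_m, all_m = meiosis(mother, pop.panel, pop.gmap, rng)
                hap_p, all_p = meiosis(father, pop.panel, pop.gmap, rng)
                oid = f"{fruit_id}_O{o + 1}"
                mos = DiploidMosaic([hap_m, hap_p], pop.gmap)
                offspring[oid] = Individual(oid, mother.cohort, mother.plot, mos,
                                            np.stack([all_m, all_p]))
                ped_rows.append((oid, mother_id, father_id, fruit_id, day,
                                 "self" if selfed else "outcross", fallback))
                meta_rows.append((oid, mother.cohort, mother.plot, "offspring",
                                  mother_id, fruit_id))
    pedigree = pd.DataFrame(ped_rows, columns=[
        "offspring", "mother", "father", "fruit", "day", "mate_type", "fallback"])
    off_meta = pd.DataFrame(meta_rows, columns=[
        "sample", "cohort", "plot", "role", "family", "fruit"])
    off_pop = Population(pop.panel, pop.gmap, pop.params, offspring, off_meta)
    return pedigree, off_pop


@dataclass
class ReadCounts:
    """Per-sample, per-site allele read counts over one panel."""

    samples: list[str]
    panel: SitePanel
    count_a: np.ndarray  # (n_samples, n_sites) int32
    count_b: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.count_a + self.count_b

    def to_frame(self) -> pd.DataFrame:
        s_idx, v_idx = np.nonzero(self.depth)
        sites = self.panel.sites
        return pd.DataFrame({
            "sample": np.asarray(self.samples, dtype=object)[s_idx],
            "chrom": sites["chrom"].to_numpy()[v_idx],
            "pos": sites["pos"].to_numpy()[v_idx],
            "count_a": self.count_a[s_idx, v_idx],
            "count_b": self.count_b[s_idx, v_idx]})


def simulate_reads(individuals: dict[str, Individual], panel: SitePanel,
                   depth: float, error: float, seed: int | np.random.Generator,
                   halve_depth: bool = False) -> tuple[ReadCounts, pd.DataFrame]:
    """Low-coverage allele counts: site depth Poisson(depth), each read drawn
    from one of the two haplotype alleles and flipped with probability
    ``error``. ``halve_depth`` emulates keeping only forward reads (used for
    selfing-rate genotype likelihoods) by halving the mean depth.

    Returns (ReadCounts, truth genotype table) where the truth table holds the
    diploid allele_a dosage per sample x site.
    """
    if depth < 0:
        raise ValueError("mean depth must be >= 0")
    if not 0 <= error < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    rng = rng_for(seed, "reads")
    lam = depth * (0.5 if halve_depth else 1.0)
    samples = list(individuals)
    n_s, n_v = len(samples), len(panel)
    count_a = np.zeros((n_s, n_v), dtype=np.int32)
    count_b = np.zeros((n_s, n_v), dtype=np.int32)
    dosage = np.zeros((n_s, n_v), dtype=np.int8)
    for i, sid in enumerate(samples):
        alle = individuals[sid].alleles
        dosage[i] = alle.sum(axis=0)
        n = rng.poisson(lam, size=n_v)
        from_h0 = rng.binomial(n, 0.5)
        from_h1 = n - from_h0
        p0 = np.where(alle[0] == 1, 1 - error, error)
        p1 = np.where(alle[1] == 1, 1 - error, error)
        count_a[i] = rng.binomial(from_h0, p0) + rng.binomial(from_h1, p1)
        count_b[i] = n - count_a[i]
    truth = pd.DataFrame(dosage, index=pd.Index(samples, name="sample"))
    return ReadCounts(samples, panel, count_a, count_b), truth
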