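"""Local-ancestry inference and per-sample ancestry summaries.

`AncestryModel` fits the diploid single-pulse HMM to low-coverage allele read
counts at ancestry-informative sites; `AncestryResults` carries posterior-
thresholded hard calls, hybrid index (HI), ancestry heterozygosity (AH),
cohort classification and F1/allopolyploid candidate flags.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import hmm
from .genome import GeneticMap
from .simulate import ReadCounts

logger = logging.getLogger(__name__)

MISSING = -1
CALL_LABELS = {0: "GG", 1: "GN", 2: "NN", MISSING: "missing"}

DEFAULT_POSTERIOR_THRESHOLD = 0.9
DEFAULT_MIN_CALLED = 25_000
#: HI cutoffs: guttatus below the first, admixed up to the second, nasutus
#: above the third; the (0.8, 0.95] gap is left unassigned.
DEFAULT_COHORT_CUTS = (0.15, 0.8, 0.95)


def estimate_admixture_fraction(counts: ReadCounts) -> pd.Series:
    """Method-of-moments genome-wide N-ancestry fraction per sample.

    Solves the expected allele_a read fraction ``(1-m) f_G + m f_N`` summed
    over covered sites for ``m``; used as the default HMM stationary mixing
    weight when none is supplied. Clipped to [0.01, 0.99].
    """
    fg = counts.panel.sites["freq_g"].to_numpy(float)
    fn = counts.panel.sites["freq_n"].to_numpy(float)
    n = counts.depth
    # least squares for m in E[count_a] = n * (f_G + m (f_N - f_G)); the
    # signed difference weights keep sites with opposite allele orientation
    # from cancelling
    diff = fn - fg
    num = (counts.count_a - n * fg) @ diff
    den = (n * diff ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = num / den
    m = np.where(np.isfinite(m), m, 0.5)
    return pd.Series(np.clip(m, 0.01, 0.99), index=counts.samples, name="m_hat")


def hard_call(posteriors: np.ndarray,
              threshold: float = DEFAULT_POSTERIOR_THRESHOLD) -> np.ndarray:
    """Argmax state where its posterior is at least ``threshold``, else missing.

    The comparison is inclusive ("at least"): a posterior of exactly 0.9
    is called under the default threshold.
    """
    post = np.asarray(posteriors)
    best = post.argmax(axis=-1).astype(np.int8)
    return np.where(post.max(axis=-1) >= threshold, best, np.int8(MISSING))


def summarize(calls: np.ndarray, samples: list[str]) -> pd.DataFrame:
    """Per-sample HI, AH and called-site count from hard calls.

    HI = (n_NN + n_GN / 2) / n_called; AH = n_GN / n_called. Samples with no
    called sites get NaN summaries.
    """
    calls = np.atleast_2d(calls)
    n_gn = (calls == 1).sum(axis=1)
    n_nn = (calls == 2).sum(axis=1)
    n_called = (calls != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hi = (n_nn + 0.5 * n_gn) / n_called
        ah = n_gn / n_called
    hi = np.where(n_called > 0, hi, np.nan)
    ah = np.where(n_called > 0, ah, np.nan)
    return pd.DataFrame({"sample": samples, "hi": hi, "ah": ah,
                         "n_called": n_called}).set_index("sample")


def filter_samples(summaries: pd.DataFrame,
                   min_called: int = DEFAULT_MIN_CALLED) -> pd.Index:
    """Samples with at least ``min_called`` called genotypes (inclusive)."""
    keep = summaries.index[summaries["n_called"] >= min_called]
    dropped = summaries.index.difference(keep)
    if len(dropped):
        logger.warning("dropping %d samples with < %d called sites: %s",
                       len(dropped), min_called, list(dropped[:10]))
    if not len(keep):
        logger.warning("no samples pass the called-site filter")
    return keep


def classify_cohort(hi, cuts: tuple[float, float, float] = DEFAULT_COHORT_CUTS):
    """Cohort label(s) from hybrid index.

    guttatus: HI < cuts[0]; admixed: cuts[0] <= HI <= cuts[1];
    nasutus: HI > cuts[2]; unassigned: the (cuts[1], cuts[2]] gap or NaN.
    """
    lo, mid, hi_cut = cuts
    h = np.asarray(hi, dtype=float)
    scalar = h.ndim == 0
    h = np.atleast_1d(h)
    out = np.full(h.shape, "unassigned", dtype=object)
    out[h < lo] = "guttatus"
    out[(h >= lo) & (h <= mid)] = "admixed"
    out[h > hi_cut] = "nasutus"
    out[~np.isfinite(h)] = "unassigned"
    return out[0] if scalar else out


def flag_f1_polyploid(maternal: pd.Series, offspring: pd.DataFrame | None = None,
                      hi_window: tuple[float, float] = (0.4, 0.6),
                      ah_high: float = 0.85, ah_f1_drop: float = 0.7) -> dict:
    """Distinguish allopolyploid from new-F1 candidates via offspring AH.

    A maternal plant with HI in ``hi_window`` and AH > ``ah_high`` is a
    candidate; offspring retaining AH > ``ah_high`` indicate fixed
    heterozygosity (allopolyploid), while selfed-offspring AH dropping to
    ~0.5 (below ``ah_f1_drop``) indicates a diploid F1. With no offspring the
    candidate is left unresolved.
    """
    flags = {"F1_candidate": False, "polyploid_candidate": False,
             "unresolved_candidate": False}
    is_candidate = (hi_window[0] <= maternal["hi"] <= hi_window[1]
                    and maternal["ah"] > ah_high)
    if not is_candidate:
        return flags
    if offspring is None or len(offspring) == 0:
        flags["unresolved_candidate"] = True
        return flags
    off_ah = float(offspring["ah"].mean())
    if off_ah > ah_high:
        flags["polyploid_candidate"] = True
    elif off_ah <= ah_f1_drop:
        flags["F1_candidate"] = True
    else:
        flags["unresolved_candidate"] = True
    return flags


class AncestryResults:
    """Hard calls plus per-sample ancestry summaries from a fitted model."""

    def __init__(self, model: "AncestryModel", calls: np.ndarray,
                 posteriors: np.ndarray | None, min_called: int,
                 cohort_cuts: tuple[float, float, float]):
        self.model = model
        self.calls = calls
        self.posteriors = posteriors
        self.min_called = min_called
        summ = summarize(calls, model.counts.samples)
        summ["cohort"] = classify_cohort(summ["hi"].to_numpy(), cohort_cuts)
        summ["retained"] = summ["n_called"] >= min_called
        self.summaries = summ

    @property
    def samples(self) -> list[str]:
        return self.model.counts.samples

    @property
    def retained(self) -> pd.Index:
        return filter_samples(self.summaries, self.min_called)

    def calls_for(self, sample: str) -> np.ndarray:
        return self.calls[self.samples.index(sample)]

    def hi(self, sample: str) -> float:
        return float(self.summaries.loc[sample, "hi"])

    def calls_frame(self) -> pd.DataFrame:
        """Long-format non-missing calls (sample, chrom, pos, call)."""
        s_idx, v_idx = np.nonzero(self.calls != MISSING)
        sites = self.model.counts.panel.sites
        return pd.DataFrame({
            "sample": np.asarray(self.samples, dtype=object)[s_idx],
            "chrom": sites["chrom"].to_numpy()[v_idx],
            "pos": sites["pos"].to_numpy()[v_idx],
            "call": [CALL_LABELS[c] for c in self.calls[s_idx, v_idx]]})

    def summary(self) -> str:
        s = self.summaries
        lines = [
            "Local ancestry summary",
            "=" * 52,
            f"samples: {len(s)}  sites: {self.calls.shape[1]}  "
            f"retained (>= {self.min_called} calls): {int(s['retained'].sum())}",
            f"pulse time t = {self.model.pulse_time}, error = {self.model.error}",
            "",
            s.groupby("cohort")["hi"].agg(["count", "mean"]).to_string(),
        ]
        return "\n".join(lines)


class AncestryModel:
    """Diploid single-pulse ancestry HMM over low-coverage read counts.

    Parameters
    ----------
    counts : ReadCounts
        Allele read counts per sample x panel site.
    gmap : GeneticMap
        Supplies the physical->genetic distance conversion (bp times the
        genome-wide recombination rate).
    pulse_time : float
        Generations since the admixture pulse (transition decay scale).
    admixture : float, mapping, or None
        Stationary N fraction per sample; None estimates it from each
        sample's raw allele read fraction.
    error : float
        Per-read allele error rate used in emissions.
    """

    def __init__(self, counts: ReadCounts, gmap: GeneticMap,
                 pulse_time: float = 8.0,
                 admixture: float | dict | pd.Series | None = None,
                 error: float = 0.01):
        if pulse_time < 1:
            raise ValueError("pulse_time must be >= 1")
        if not 0 <= error < 0.5:
            raise ValueError("error must be in [0, 0.5)")
        self.counts = counts
        self.gmap = gmap
        self.pulse_time = float(pulse_time)
        self.error = float(error)
        if admixture is None:
            self.admixture = estimate_admixture_fraction(counts)
        elif np.isscalar(admixture):
            self.admixture = pd.Series(float(admixture), index=counts.samples)
        else:
            self.admixture = pd.Series(admixture).reindex(counts.samples)
        if self.admixture.isna().any() or ((self.admixture < 0) |
                                           (self.admixture > 1)).any():
            raise ValueError("admixture fractions must cover all samples in [0, 1]")

    def posterior(self, sample_idx: np.ndarray | list[int],
                  m: float) -> np.ndarray:
        """Forward-backward posteriors for a set of samples sharing ``m``."""
        panel = self.counts.panel
        idx = np.asarray(sample_idx)
        post = np.empty((len(idx), len(panel), 3))
        prior = hmm.stationary_prior(m)
        fg = panel.sites["freq_g"].to_numpy(float)
        fn = panel.sites["freq_n"].to_numpy(float)
        for chrom in panel.chromosomes:
            sl = panel.chrom_slice(chrom)
            em = hmm.emission_probabilities(
                self.counts.count_a[idx, sl], self.counts.count_b[idx, sl],
                fg[sl], fn[sl], self.error)
            d_m = self.gmap.morgans(np.diff(panel.positions(chrom)).astype(float))
            trans = hmm.diploid_transition(d_m, self.pulse_time, m)
            post[:, sl], _ = hmm.forward_backward(em, trans, prior)
        return post

    def fit(self, posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
            min_called: int = DEFAULT_MIN_CALLED,
            cohort_cuts: tuple[float, float, float] = DEFAULT_COHORT_CUTS,
            store_posteriors: bool = False,
            batch_size: int = 128) -> AncestryResults:
        """Run the HMM for every sample and hard-call genotypes.

        Samples are grouped by admixture fraction rounded to 0.01 so each
        group shares transition matrices; forward-backward is vectorised
        across samples within memory-bounded batches.
        """
        n_s, n_v = len(self.counts.samples), len(self.counts.panel)
        if n_v == 0:
            raise ValueError("read counts cover zero informative sites")
        calls = np.full((n_s, n_v), MISSING, dtype=np.int8)
        posteriors = np.empty((n_s, n_v, 3)) if store_posteriors else None
        m_grouped = self.admixture.round(2)
        for m, members in m_grouped.groupby(m_grouped).groups.items():
            idx_all = np.asarray([self.counts.samples.index(s) for s in members])
            for start in range(0, len(idx_all), batch_size):
                idx = idx_all[start:start + batch_size]
                post = self.posterior(idx, float(m))
                calls[idx] = hard_call(post, posterior_threshold)
                if store_posteriors:
                    posteriors[idx] = post
        return AncestryResults(self, calls, posteriors, min_called, cohort_cuts)
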