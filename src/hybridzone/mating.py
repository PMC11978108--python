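"""Selfing vs outcrossing and half/full-sibship inference from progeny arrays.

This is an explicit per-site likelihood model over thinned ancestry-informative
sites: an offspring genotype arises either from a Mendelian self of the
maternal genotype or from one maternal gamete plus one allele drawn from the
population frequency; sibling pairs share either one father (genotype
integrated over Hardy-Weinberg frequencies) or two independent ones. Per-site
likelihoods multiply across sites and combine with an explicit prior. There is
no MCMC; maternal genotypes enter as (optionally ancestry-augmented)
probability triples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import hmm
from .genome import SitePanel
from .simulate import ReadCounts, rng_for

logger = logging.getLogger(__name__)

DEFAULT_THIN_SPACING = 10_000
DEFAULT_CALL_THRESHOLD = 0.9
DEFAULT_PRIOR_SELFED = 0.5

# Transmission tensors over allele_a dosage. TS[gm, go] is Mendelian selfing;
# TR[gm, gf, go] is one maternal gamete (q = gm/2) + one paternal gamete
# (u = gf/2).
_Q = np.array([0.0, 0.5, 1.0])
TS = np.stack([
    np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) for q in _Q])
TR = np.empty((3, 3, 3))
for _i, _q in enumerate(_Q):
    for _j, _u in enumerate(_Q):
        TR[_i, _j] = [(1 - _q) * (1 - _u), _q * (1 - _u) + (1 - _q) * _u, _q * _u]


def hwe(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies for allele_a frequency ``p``."""
    p = np.asarray(p, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)


def thin_sites(panel: SitePanel, spacing: int = DEFAULT_THIN_SPACING,
               seed: int | np.random.Generator = 0) -> tuple[SitePanel, np.ndarray]:
    """One site per non-overlapping ``spacing``-bp window, chosen uniformly.

    Returns the thinned panel and the integer indices of the retained sites
    in the original panel (so count matrices can be subset consistently).
    """
    rng = rng_for(seed, "thin")
    df = panel.sites
    if df.empty:
        return SitePanel(df.copy()), np.array([], dtype=int)
    window = (df["pos"].to_numpy() - 1) // spacing
    keys = pd.DataFrame({"chrom": df["chrom"], "window": window})
    picks = []
    for _, grp in keys.groupby(["chrom", "window"], sort=False):
        picks.append(int(rng.choice(grp.index.to_numpy())))
    idx = np.sort(np.asarray(picks))
    return SitePanel(df.iloc[idx].reset_index(drop=True)), idx


def genotype_likelihoods(counts: ReadCounts, error: float) -> np.ndarray:
    """Binomial read likelihoods P(reads | g) per sample x site x genotype."""
    return hmm.genotype_read_likelihoods(counts.count_a, counts.depth, error)


def genotype_posteriors(likelihoods: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Normalised genotype probabilities from likelihoods and a prior."""
    post = likelihoods * prior
    return post / post.sum(axis=-1, keepdims=True)


def population_allele_frequencies(genotype_probs: np.ndarray) -> np.ndarray:
    """Mean allele_a dosage / 2 across samples (estimated once, from mothers)."""
    return genotype_probs[..., 1].mean(axis=0) / 2 + genotype_probs[..., 2].mean(axis=0)


def _with_model_error(trans: np.ndarray, background: np.ndarray,
                      model_error: float) -> np.ndarray:
    if model_error == 0:
        return trans
    return (1 - model_error) * trans + model_error * background


def mate_type_posterior(maternal_probs: np.ndarray, offspring_lik: np.ndarray,
                        pop_freq: np.ndarray,
                        prior_selfed: float = DEFAULT_PRIOR_SELFED,
                        model_error: float = 0.0) -> float:
    """P(selfed) for one maternal-offspring pair.

    maternal_probs (L, 3): maternal genotype probability triples;
    offspring_lik (L, 3): offspring read likelihoods per genotype;
    pop_freq (L,): population allele_a frequencies for the outcross draw.
    ``model_error`` mixes each transmission distribution with Hardy-Weinberg
    background to absorb miscalls. Sites with no information (likelihood
    constant across genotypes) leave the posterior at the prior.
    """
    if not 0 <= prior_selfed <= 1:
        raise ValueError("prior must be in [0, 1]")
    if maternal_probs.size == 0:
        return prior_selfed
    bg = hwe(pop_freq)  # (L, 3)
    t_self = _with_model_error(
        np.broadcast_to(TS, (len(pop_freq), 3, 3)), bg[:, None, :], model_error)
    t_out = np.einsum("lf,mfg->lmg", bg, TR)  # father allele from pop freq
    t_out = _with_model_error(t_out, bg[:, None, :], model_error)
    l_self = np.einsum("lm,lmg,lg->l", maternal_probs, t_self, offspring_lik)
    l_out = np.einsum("lm,lmg,lg->l", maternal_probs, t_out, offspring_lik)
    with np.errstate(divide="ignore"):
        log_ratio = np.sum(np.log(l_self) - np.log(l_out))
    if np.isnan(log_ratio):  # both likelihoods zero somewhere: no valid model
        return float("nan")
    if prior_selfed in (0.0, 1.0):
        return prior_selfed
    logit = np.log(prior_selfed / (1 - prior_selfed)) + log_ratio
    return float(expit(logit))


def classify_mate_type(p_selfed: float,
                       threshold: float = DEFAULT_CALL_THRESHOLD) -> str:
    """'selfed' when P >= threshold, 'outcrossed' when 1-P >= threshold
    (both inclusive), otherwise 'ambiguous' (excluded from rates)."""
    if not np.isfinite(p_selfed):
        return "ambiguous"
    if p_selfed >= threshold:
        return "selfed"
    if 1 - p_selfed >= threshold:
        return "outcrossed"
    return "ambiguous"


def selfing_rate(calls: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Cohort selfing rates: n_selfed / (n_selfed + n_outcrossed).

    ``calls`` needs a ``call`` column in {selfed, outcrossed, ambiguous} plus
    any grouping columns named in ``by``. Ambiguous offspring count in
    neither numerator nor denominator; a group with no called offspring gets
    a NaN rate.
    """
    def _agg(grp: pd.DataFrame) -> pd.Series:
        n_self = int((grp["call"] == "selfed").sum())
        n_out = int((grp["call"] == "outcrossed").sum())
        n_amb = int((grp["call"] == "ambiguous").sum())
        rate = n_self / (n_self + n_out) if n_self + n_out else float("nan")
        return pd.Series({"outcrossed": n_out, "selfed": n_self,
                          "ambiguous": n_amb, "rate": rate})

    if not by:
        return _agg(calls).to_frame().T
    out = calls.groupby(by).apply(_agg, include_groups=False).reset_index()
    for col in ("outcrossed", "selfed", "ambiguous"):
        out[col] = out[col].astype(int)
    return out


def sibship_posterior(maternal_probs: np.ndarray, off1_lik: np.ndarray,
                      off2_lik: np.ndarray, pop_freq: np.ndarray,
                      prior_half: float = 0.5,
                      model_error: float = 0.0) -> float:
    """P(half-sib) for two outcrossed offspring of one mother.

    Full sibs share a father whose genotype is integrated over Hardy-Weinberg
    frequencies; half sibs draw independent paternal gametes from the
    population frequency. Indeterminate paternal information at all sites
    leaves the posterior at the prior (0.5 => the pair is 'missing').
    """
    if maternal_probs.size == 0:
        return prior_half
    bg = hwe(pop_freq)  # (L, 3) father genotype prior
    tr = np.broadcast_to(TR, (len(pop_freq), 3, 3, 3))
    tr = _with_model_error(tr, bg[:, None, None, :], model_error)
    a1 = np.einsum("lmfg,lg->lmf", tr, off1_lik)  # given (gm, gf)
    a2 = np.einsum("lmfg,lg->lmf", tr, off2_lik)
    l_full = np.einsum("lm,lf,lmf,lmf->l", maternal_probs, bg, a1, a2)
    b1 = np.einsum("lf,lmf->lm", bg, a1)
    b2 = np.einsum("lf,lmf->lm", bg, a2)
    l_half = np.einsum("lm,lm,lm->l", maternal_probs, b1, b2)
    with np.errstate(divide="ignore"):
        log_ratio = np.sum(np.log(l_half) - np.log(l_full))
    if np.isnan(log_ratio):
        return float("nan")
    if prior_half in (0.0, 1.0):
        return prior_half
    return float(expit(np.log(prior_half / (1 - prior_half)) + log_ratio))


def classify_sibship(p_half: float) -> str:
    """half if P > 0.5, full if P < 0.5, missing at exactly 0.5 (or NaN)."""
    if not np.isfinite(p_half) or p_half == 0.5:
        return "missing"
    return "half" if p_half > 0.5 else "full"


def multiple_paternity_summary(sibships: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-fruit multi-paternity flags and the overall flagged fraction.

    A fruit with at least one half-sib pair among its outcrossed offspring is
    flagged; eligibility requires >= 2 outcrossed offspring (i.e. >= 1 pair).
    Returns (per-fruit frame, summary dict with ``fraction`` in percent and
    the mean pairwise half-sib posterior).
    """
    if sibships.empty:
        return (pd.DataFrame(columns=["fruit", "n_pairs", "multi_paternal"]),
                {"eligible_fruits": 0, "flagged_fruits": 0,
                 "fraction": float("nan"), "mean_p_half": float("nan")})
    per_fruit = sibships.groupby("fruit").agg(
        n_pairs=("p_half", "size"),
        multi_paternal=("call", lambda s: bool((s == "half").any()))).reset_index()
    flagged = int(per_fruit["multi_paternal"].sum())
    eligible = len(per_fruit)
    return per_fruit, {
        "eligible_fruits": eligible, "flagged_fruits": flagged,
        "fraction": 100.0 * flagged / eligible,
        "mean_p_half": float(sibships["p_half"].mean())}


@dataclass
class MatingResults:
    """Mate-type and sibship calls with rate summaries."""

    mate_types: pd.DataFrame  # offspring, family, fruit, p_selfed, call + groups
    sibships: pd.DataFrame    # fruit, offspring_1, offspring_2, p_half, call
    prior_selfed: float

    def selfing_rates(self, by: list[str] | None = None) -> pd.DataFrame:
        return selfing_rate(self.mate_types, by=by)

    def multiple_paternity(self) -> tuple[pd.DataFrame, dict]:
        return multiple_paternity_summary(self.sibships)

    def summary(self) -> str:
        counts = self.mate_types["call"].value_counts()
        _, mp = self.multiple_paternity()
        lines = [
            "Mating-system inference",
            "=" * 52,
            f"offspring: {len(self.mate_types)}  prior P(selfed) = {self.prior_selfed}",
            f"called selfed: {counts.get('selfed', 0)}  "
            f"outcrossed: {counts.get('outcrossed', 0)}  "
            f"ambiguous: {counts.get('ambiguous', 0)}",
            f"multi-paternal fruits: {mp['flagged_fruits']}/{mp['eligible_fruits']}",
        ]
        return "\n".join(lines)


class MatingModel:
    """Per-family selfing/outcrossing and sibship model over thinned sites.

    Parameters
    ----------
    counts : ReadCounts
        Read counts at *thinned* sites for mothers and offspring together
        (see :func:`thin_sites`); forward-read-only depth halving, when
        wanted, belongs to read simulation/extraction upstream.
    families : DataFrame
        Offspring rows with columns (sample, family, fruit) plus optional
        grouping columns (cohort, year, stream) carried through to results.
    error : float
        Per-read allele error for the genotype likelihoods.
    prior_selfed : float
        Prior probability that an offspring is selfed.
    maternal_states : ndarray, optional
        Hard ancestry calls (n_mothers x L, coded -1/0/1/2, rows aligned with
        the mothers' order of first appearance) used to augment maternal
        genotype priors with panel frequencies; Hardy-Weinberg priors at the
        estimated population frequencies are used where absent.
    """

    def __init__(self, counts: ReadCounts, families: pd.DataFrame,
                 error: float = 0.01,
                 prior_selfed: float = DEFAULT_PRIOR_SELFED,
                 model_error: float = 0.0,
                 maternal_states: np.ndarray | None = None):
        self.counts = counts
        self.families = families.reset_index(drop=True)
        self.error = error
        self.prior_selfed = prior_selfed
        self.model_error = model_error
        self.maternal_states = maternal_states
        self._index = {s: i for i, s in enumerate(counts.samples)}
        self.mothers = list(dict.fromkeys(self.families["family"]))

    def fit(self, call_threshold: float = DEFAULT_CALL_THRESHOLD) -> MatingResults:
        lik = genotype_likelihoods(self.counts, self.error)
        mother_rows = np.asarray([self._index[m] for m in self.mothers])
        # population allele frequencies from maternal samples, estimated once
        flat_prior = np.full(3, 1 / 3)
        rough = genotype_posteriors(lik[mother_rows], flat_prior)
        pop_freq = np.clip(population_allele_frequencies(rough), 1e-4, 1 - 1e-4)
        prior = hwe(pop_freq)  # (L, 3)
        maternal_probs = {}
        for row, mother in zip(mother_rows, self.mothers):
            pr = prior
            if self.maternal_states is not None:
                pr = self._ancestry_prior(self.mothers.index(mother), prior)
            maternal_probs[mother] = genotype_posteriors(lik[row], pr)

        mt_rows = []
        extra_cols = [c for c in self.families.columns
                      if c not in ("sample", "family", "fruit")]
        for _, rec in self.families.iterrows():
            off = rec["sample"]
            p = mate_type_posterior(maternal_probs[rec["family"]],
                                    lik[self._index[off]], pop_freq,
                                    self.prior_selfed, self.model_error)
            mt_rows.append([off, rec["family"], rec["fruit"], p,
                            classify_mate_type(p, call_threshold)]
                           + [rec[c] for c in extra_cols])
        mate_types = pd.DataFrame(mt_rows, columns=[
            "offspring", "family", "fruit", "p_selfed", "call"] + extra_cols)

        sib_rows = []
        outcrossed = mate_types[mate_types["call"] == "outcrossed"]
        for (family, fruit), grp in outcrossed.groupby(["family", "fruit"]):
            ids = grp["offspring"].tolist()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    ph = sibship_posterior(
                        maternal_probs[family], lik[self._index[ids[i]]],
                        lik[self._index[ids[j]]], pop_freq,
                        model_error=self.model_error)
                    sib_rows.append((family, fruit, ids[i], ids[j], ph,
                                     classify_sibship(ph)))
        sibships = pd.DataFrame(sib_rows, columns=[
            "family", "fruit", "offspring_1", "offspring_2", "p_half", "call"])
        return MatingResults(mate_types, sibships, self.prior_selfed)

    def _ancestry_prior(self, mother_idx: int, fallback: np.ndarray) -> np.ndarray:
        states = self.maternal_states[mother_idx]
        w = hmm.genotype_weights(
            self.counts.panel.sites["freq_g"].to_numpy(float),
            self.counts.panel.sites["freq_n"].to_numpy(float))
        pr = fallback.copy()
        called = states >= 0
        pr[called] = w[called, states[called], :]
        return pr
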