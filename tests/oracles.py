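"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exhaustive path enumeration for the
HMM, per-flower materialisation for phenological isolation, and explicit
nested sums for the mating likelihoods. None of it shares code with the
package's own computational paths.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def enumerate_hmm_posteriors(prior: np.ndarray, transitions: np.ndarray,
                             emissions: np.ndarray) -> np.ndarray:
    """Posterior state marginals by summing over all 3^L state paths.

    prior (3,), transitions (L-1, 3, 3), emissions (L, 3) for one sample.
    """
    L = emissions.shape[0]
    marginals = np.zeros((L, 3))
    total = 0.0
    for path in product(range(3), repeat=L):
        w = prior[path[0]] * emissions[0, path[0]]
        for i in range(1, L):
            w *= transitions[i - 1, path[i - 1], path[i]] * emissions[i, path[i]]
        total += w
        for i, s in enumerate(path):
            marginals[i, s] += w
    return marginals / total


def brute_force_phenological_ri(census_rows, plot_to_cohort, ovule, pollen,
                                include_focal=False):
    """RI_P by materialising every individual flower.

    ``census_rows`` is an iterable of (plot, day, count). Returns NaN when the
    ovule cohort has no flowers, 1.0 when no between-cohort mating is
    possible.
    """
    flowers = []  # (day, cohort) per physical flower
    for plot, day, count in census_rows:
        cohort = plot_to_cohort.get(plot)
        if cohort is None:
            continue
        flowers.extend([(day, cohort)] * int(count))
    if not any(c == ovule for _, c in flowers):
        return float("nan")
    t_within = t_between = 0.0
    for i, (day, cohort) in enumerate(flowers):
        if cohort != ovule:
            continue
        a = sum(1 for j, (d, c) in enumerate(flowers)
                if d == day and c == ovule and (include_focal or j != i))
        b = sum(1 for d, c in flowers if d == day and c == pollen)
        if a + b == 0:
            continue
        t_within += a / (a + b)
        t_between += b / (a + b)
    if t_within + t_between == 0:
        return float("nan")
    if t_between == 0:
        return 1.0
    p = t_between / (t_within + t_between)
    return 1.0 - 2.0 * p


def _mendel_self(gm: int, go: int) -> float:
    q = gm / 2
    return [(1 - q) ** 2, 2 * q * (1 - q), q ** 2][go]


def _gamete(g: int, allele: int) -> float:
    q = g / 2
    return q if allele == 1 else 1 - q


def _offspring_given(gm: int, gf: int, go: int) -> float:
    total = 0.0
    for am in (0, 1):
        for af in (0, 1):
            if am + af == go:
                total += _gamete(gm, am) * _gamete(gf, af)
    return total


def _hwe(p: float, g: int) -> float:
    return [(1 - p) ** 2, 2 * p * (1 - p), p ** 2][g]


def brute_force_mate_type(maternal_probs, offspring_lik, pop_freq,
                          prior_selfed=0.5):
    """P(selfed) by explicit per-site nested sums over genotypes."""
    l_self = l_out = 1.0
    for pm, lo, p in zip(maternal_probs, offspring_lik, pop_freq):
        s_site = sum(pm[gm] * _mendel_self(gm, go) * lo[go]
                     for gm in range(3) for go in range(3))
        o_site = sum(pm[gm] * _gamete(gm, am) * (p if ap == 1 else 1 - p) * lo[am + ap]
                     for gm in range(3) for am in (0, 1) for ap in (0, 1))
        l_self *= s_site
        l_out *= o_site
    denom = prior_selfed * l_self + (1 - prior_selfed) * l_out
    return prior_selfed * l_self / denom


def brute_force_sibship(maternal_probs, off1_lik, off2_lik, pop_freq,
                        prior_half=0.5):
    """P(half-sib) by explicit sums over maternal and father genotypes."""
    l_full = l_half = 1.0
    for pm, l1, l2, p in zip(maternal_probs, off1_lik, off2_lik, pop_freq):
        full = sum(pm[gm] * _hwe(p, gf)
                   * sum(_offspring_given(gm, gf, go) * l1[go] for go in range(3))
                   * sum(_offspring_given(gm, gf, go) * l2[go] for go in range(3))
                   for gm in range(3) for gf in range(3))
        half = sum(pm[gm]
                   * sum(_hwe(p, gf) * _offspring_given(gm, gf, go) * l1[go]
                         for gf in range(3) for go in range(3))
                   * sum(_hwe(p, gf) * _offspring_given(gm, gf, go) * l2[go]
                         for gf in range(3) for go in range(3))
                   for gm in range(3))
        l_full *= full
        l_half *= half
    denom = prior_half * l_half + (1 - prior_half) * l_full
    return prior_half * l_half / denom
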