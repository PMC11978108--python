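"""Diploid single-pulse ancestry HMM primitives.

States are diploid ancestry genotypes {GG, GN, NN} indexed 0/1/2 (N dosage).
The transition kernel along a chromosome is the tensor product of two
independent haploid pulse chains: over a genetic distance ``d`` Morgans a
haplotype retains its ancestry with probability ``exp(-t d)`` and otherwise
redraws it from the stationary distribution ``(1-m, m)``, where ``t`` is the
time since the admixture pulse (generations) and ``m`` the admixture
fraction.

Emissions are binomial read counts: given diploid ancestry, the genotype at a
site follows the parental panel allele frequencies, and each read reports the
true allele with probability ``1 - error``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom


def haploid_transition(decay: np.ndarray, m: float) -> np.ndarray:
    """Per-interval 2x2 haploid transition matrices.

    ``decay`` is ``exp(-t * d)`` per interval; rows/cols ordered (G, N).
    Shape (L, 2, 2) for input shape (L,).
    """
    decay = np.asarray(decay, dtype=float)
    out = np.empty(decay.shape + (2, 2))
    out[..., 0, 0] = decay + (1 - decay) * (1 - m)
    out[..., 0, 1] = (1 - decay) * m
    out[..., 1, 0] = (1 - decay) * (1 - m)
    out[..., 1, 1] = decay + (1 - decay) * m
    return out


def diploid_transition(distances_m: np.ndarray, t: float, m: float) -> np.ndarray:
    """Per-interval 3x3 transition matrices over N-dosage states.

    ``distances_m`` are inter-site genetic distances in Morgans. The diploid
    kernel is the product of two independent haploid chains collapsed onto
    unordered dosage.
    """
    h = haploid_transition(np.exp(-t * np.asarray(distances_m, dtype=float)), m)
    a, b = h[..., 0, 0], h[..., 0, 1]  # from G
    c, d = h[..., 1, 0], h[..., 1, 1]  # from N
    out = np.empty(h.shape[:-2] + (3, 3))
    out[..., 0, 0] = a * a
    out[..., 0, 1] = 2 * a * b
    out[..., 0, 2] = b * b
    out[..., 1, 0] = a * c
    out[..., 1, 1] = a * d + b * c
    out[..., 1, 2] = b * d
    out[..., 2, 0] = c * c
    out[..., 2, 1] = 2 * c * d
    out[..., 2, 2] = d * d
    return out


def stationary_prior(m: float) -> np.ndarray:
    """Stationary diploid state distribution ((1-m)^2, 2m(1-m), m^2)."""
    return np.array([(1 - m) ** 2, 2 * m * (1 - m), m ** 2])


def genotype_weights(freq_g: np.ndarray, freq_n: np.ndarray) -> np.ndarray:
    """P(genotype | ancestry state) per site: shape (L, 3 states, 3 genotypes).

    Genotype indexes the count of panel allele_a; ``freq_g``/``freq_n`` are
    allele_a frequencies in the two parental panels.
    """
    fg, fn = np.asarray(freq_g, float), np.asarray(freq_n, float)
    w = np.empty((len(fg), 3, 3))
    w[:, 0, 0] = (1 - fg) ** 2
    w[:, 0, 1] = 2 * fg * (1 - fg)
    w[:, 0, 2] = fg ** 2
    w[:, 1, 0] = (1 - fg) * (1 - fn)
    w[:, 1, 1] = fg * (1 - fn) + (1 - fg) * fn
    w[:, 1, 2] = fg * fn
    w[:, 2, 0] = (1 - fn) ** 2
    w[:, 2, 1] = 2 * fn * (1 - fn)
    w[:, 2, 2] = fn ** 2
    return w


def genotype_read_likelihoods(count_a: np.ndarray, depth: np.ndarray,
                              error: float) -> np.ndarray:
    """Binomial P(read counts | genotype) for genotypes 0/1/2 of allele_a.

    Broadcasts over leading axes; returns shape ``count_a.shape + (3,)``.
    Zero-depth sites yield likelihood 1 for every genotype.
    """
    p = np.array([error, 0.5, 1.0 - error])
    return binom.pmf(count_a[..., None], depth[..., None], p)


def emission_probabilities(count_a: np.ndarray, count_b: np.ndarray,
                           freq_g: np.ndarray, freq_n: np.ndarray,
                           error: float) -> np.ndarray:
    """P(reads | diploid ancestry state): shape (n_samples, L, 3)."""
    gl = genotype_read_likelihoods(count_a, count_a + count_b, error)
    w = genotype_weights(freq_g, freq_n)
    return np.einsum("slg,lxg->slx", gl, w)


def forward_backward(emissions: np.ndarray, transitions: np.ndarray,
                     prior: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward-backward over one chromosome.

    emissions (S, L, 3); transitions (L-1, 3, 3) shared across samples;
    prior (3,) or (S, 3). Returns (posteriors (S, L, 3), loglik (S,)).
    """
    S, L, K = emissions.shape
    prior = np.broadcast_to(np.asarray(prior, float), (S, K))
    alpha = np.empty((S, L, K))
    scale = np.empty((S, L))
    a = prior * emissions[:, 0]
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scale[:, 0, None]
    for i in range(1, L):
        a = (alpha[:, i - 1] @ transitions[i - 1]) * emissions[:, i]
        scale[:, i] = a.sum(axis=1)
        alpha[:, i] = a / scale[:, i, None]
    beta = np.empty((S, L, K))
    beta[:, -1] = 1.0
    for i in range(L - 2, -1, -1):
        b = (beta[:, i + 1] * emissions[:, i + 1]) @ transitions[i].T
        beta[:, i] = b / scale[:, i + 1, None]
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post, np.log(scale).sum(axis=1)
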