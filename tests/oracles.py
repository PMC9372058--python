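"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the HMM oracle
enumerates every hidden state path, and the Hardy-Weinberg oracle sums
exact configuration probabilities computed from log-factorials.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import gammaln


def enumerate_ls_posteriors(obs, A, rho, mu):
    """State posteriors of the haplotype-copying HMM by path enumeration.

    obs: length-M vector, 0/1 typed, -1 untyped.  A: (H, M) 0/1 panel.
    Returns gamma (M, H).
    """
    A = np.asarray(A)
    H, M = A.shape
    stay = (1.0 - rho) + rho / H
    move = rho / H
    gamma = np.zeros((M, H))
    total = 0.0
    for path in itertools.product(range(H), repeat=M):
        p = 1.0 / H
        for j in range(1, M):
            p *= stay if path[j] == path[j - 1] else move
        for j in range(M):
            if obs[j] >= 0:
                p *= (1.0 - mu) if A[path[j], j] == obs[j] else mu
        total += p
        for j in range(M):
            gamma[j, path[j]] += p
    return gamma / total


def enumerate_ls_alt_posterior(obs, A, rho, mu):
    gamma = enumerate_ls_posteriors(obs, A, rho, mu)
    A = np.asarray(A)
    return np.einsum("jh,hj->j", gamma, A.astype(float))


def hwe_exact_p_bruteforce(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact HWE p by direct probability enumeration.

    Conditional on allele counts, P(het = h) follows the Levene-Haldane
    distribution; the p-value sums probabilities no larger than the
    observed configuration's.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    def log_prob(h: int) -> float:
        # P(h hets | n, n_a) = n! /(n_aa! n_ab! n_bb!) * 2^h * n_a! n_b! / (2n)!
        if (rare - h) % 2 != 0 or h < 0 or h > rare:
            return -math.inf
        n_rr = (rare - h) // 2
        n_cc = n - h - n_rr
        return (
            gammaln(n + 1)
            - gammaln(n_rr + 1)
            - gammaln(h + 1)
            - gammaln(n_cc + 1)
            + h * math.log(2.0)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )

    obs_h = n_ab
    probs = np.array([log_prob(h) for h in range(rare % 2, rare + 1, 2)])
    probs = np.exp(probs - probs.max())
    probs /= probs.sum()
    hs = np.arange(rare % 2, rare + 1, 2)
    p_obs = probs[hs == obs_h][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
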