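"""Li-Stephens haplotype-copying HMM.

A query haplotype is modelled as an imperfect mosaic of a phased
reference panel: the hidden state at each site is the reference
haplotype being copied.  Transitions between adjacent sites keep the
current state with probability ``(1 - rho) + rho/H`` and jump to each
other state with probability ``rho/H`` (``H`` = panel size); at typed
sites the emitted allele matches the copied haplotype with probability
``1 - mu``.  Untyped sites emit nothing.  Forward-backward posteriors
give the ALT-allele posterior per site; because emissions factorise by
site, leave-one-out posteriors at a typed site are obtained exactly by
dividing that site's emission factor out of the state posterior.

All recursions run in scaled space (per-site normalisation), so panels
of 10^4+ sites do not underflow.  The heavy loops are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .datatypes import ConfigError

__all__ = ["LsParams", "ls_forward_backward", "fb_posteriors_batch"]


@dataclass(frozen=True)
class LsParams:
    """Engine parameters for phasing and imputation.

    switch_prob
        Per inter-marker-interval probability of leaving the current
        copying state (abstract map: every interval has the same rho).
    mismatch_prob
        Total per-site emission mismatch probability mu: the chance the
        observed allele differs from the copied reference allele.  It
        lumps two layers, copy noise (the study haplotype genuinely
        deviating from its reference template) and genotyping error.
    genotype_error
        The genotyping-error component epsilon of ``mismatch_prob``.
        The split only matters when converting posteriors to dosages:
        at a typed site the dosage is the posterior of the *study*
        allele given context and observation, and the larger the copy
        noise (mu - epsilon) relative to epsilon, the more the
        observation dominates -- matching production imputation
        engines, whose typed-site dosages track the input genotypes.
    phasing_iterations, phasing_burnin
        Refinement sweeps after / before the estimate is kept.
    conditioning_haplotypes
        Size K of the conditioning panel used during phasing.
    """

    switch_prob: float = 0.01
    mismatch_prob: float = 0.001
    genotype_error: float = 0.0001
    phasing_iterations: int = 10
    phasing_burnin: int = 5
    conditioning_haplotypes: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.switch_prob < 1.0):
            raise ConfigError("switch_prob must be in (0, 1)")
        if not (0.0 < self.mismatch_prob < 0.5):
            raise ConfigError("mismatch_prob must be in (0, 0.5)")
        if not (0.0 < self.genotype_error <= self.mismatch_prob):
            raise ConfigError("genotype_error must be in (0, mismatch_prob]")
        if self.conditioning_haplotypes < 2:
            raise ConfigError("conditioning_haplotypes must be >= 2")
        if self.phasing_iterations < 1 or self.phasing_burnin < 0:
            raise ConfigError("phasing sweep counts invalid")

    @property
    def copy_noise(self) -> float:
        """Copy-noise component nu solving mu = nu + eps - 2*nu*eps."""
        eps = self.genotype_error
        return max((self.mismatch_prob - eps) / (1.0 - 2.0 * eps), 0.0)


@njit(cache=True)
def _fb_fill_gamma(obs, A, rho, mu, breaks, alpha, gamma):  # pragma: no cover
    """Scaled forward-backward; fills gamma (M, H) with state posteriors.

    ``breaks[j] == 1`` marks a free-recombination junction entering
    site j (chromosome boundary): the copying state redraws uniformly.
    """
    H, M = A.shape
    move = rho / H
    stay = 1.0 - rho
    # forward
    for j in range(M):
        if j == 0:
            for s in range(H):
                alpha[0, s] = 1.0 / H
        else:
            tot = 0.0
            for s in range(H):
                tot += alpha[j - 1, s]
            if breaks[j] == 1:
                uni = tot / H
                for s in range(H):
                    alpha[j, s] = uni
            else:
                jump = move * tot
                for s in range(H):
                    alpha[j, s] = stay * alpha[j - 1, s] + jump
        o = obs[j]
        if o >= 0:
            for s in range(H):
                e = 1.0 - mu if A[s, j] == o else mu
                alpha[j, s] *= e
        norm = 0.0
        for s in range(H):
            norm += alpha[j, s]
        inv = 1.0 / norm
        for s in range(H):
            alpha[j, s] *= inv
    # backward, combined into gamma on the fly
    beta = np.empty(H)
    for s in range(H):
        beta[s] = 1.0
    for j in range(M - 1, -1, -1):
        norm = 0.0
        for s in range(H):
            g = alpha[j, s] * beta[s]
            gamma[j, s] = g
            norm += g
        inv = 1.0 / norm
        for s in range(H):
            gamma[j, s] *= inv
        if j > 0:
            # fold emission at site j into beta, then transition back
            o = obs[j]
            tot = 0.0
            for s in range(H):
                if o >= 0:
                    e = 1.0 - mu if A[s, j] == o else mu
                    beta[s] *= e
                tot += beta[s]
            if breaks[j] == 1:
                uni = tot / H
                for s in range(H):
                    beta[s] = uni
                bnorm = tot
            else:
                jump = move * tot
                bnorm = 0.0
                for s in range(H):
                    beta[s] = stay * beta[s] + jump
                    bnorm += beta[s]
            inv = 1.0 / bnorm
            for s in range(H):
                beta[s] *= inv


@njit(cache=True)
def _posteriors_from_gamma(obs, A, mu, gamma, post, loo):  # pragma: no cover
    H, M = A.shape
    for j in range(M):
        p = 0.0
        for s in range(H):
            p += gamma[j, s] * A[s, j]
        post[j] = p
        o = obs[j]
        if o >= 0:
            tot = 0.0
            palt = 0.0
            for s in range(H):
                e = 1.0 - mu if A[s, j] == o else mu
                u = gamma[j, s] / e
                tot += u
                palt += u * A[s, j]
            loo[j] = palt / tot
        else:
            loo[j] = p


@njit(cache=True)
def _fb_batch(obs_batch, A, rho, mu, breaks):  # pragma: no cover - numba
    Q, M = obs_batch.shape
    H = A.shape[0]
    post = np.empty((Q, M))
    loo = np.empty((Q, M))
    alpha = np.empty((M, H))
    gamma = np.empty((M, H))
    for q in range(Q):
        _fb_fill_gamma(obs_batch[q], A, rho, mu, breaks, alpha, gamma)
        _posteriors_from_gamma(obs_batch[q], A, mu, gamma, post[q], loo[q])
    return post, loo


@njit(cache=True)
def _viterbi_alleles(obs, A, rho, mu, breaks, out):  # pragma: no cover - numba
    """Most-likely copying path; writes its alleles into out (M,)."""
    H, M = A.shape
    move = np.log(rho / H)
    stay = np.log((1.0 - rho) + rho / H)
    uni = -np.log(H)
    lmatch = np.log(1.0 - mu)
    lmis = np.log(mu)
    score = np.empty((M, H))
    back = np.empty((M, H), dtype=np.int32)
    for s in range(H):
        score[0, s] = -np.log(H)
    o = obs[0]
    if o >= 0:
        for s in range(H):
            score[0, s] += lmatch if A[s, 0] == o else lmis
    for j in range(1, M):
        best_prev = 0
        for s in range(1, H):
            if score[j - 1, s] > score[j - 1, best_prev]:
                best_prev = s
        if breaks[j] == 1:
            base = score[j - 1, best_prev] + uni
            for s in range(H):
                score[j, s] = base
                back[j, s] = best_prev
        else:
            for s in range(H):
                via_jump = score[j - 1, best_prev] + move
                via_stay = score[j - 1, s] + stay
                if via_stay >= via_jump:
                    score[j, s] = via_stay
                    back[j, s] = s
                else:
                    score[j, s] = via_jump
                    back[j, s] = best_prev
        o = obs[j]
        if o >= 0:
            for s in range(H):
                score[j, s] += lmatch if A[s, j] == o else lmis
    s = 0
    for t in range(1, H):
        if score[M - 1, t] > score[M - 1, s]:
            s = t
    for j in range(M - 1, -1, -1):
        out[j] = A[s, j]
        if j > 0:
            s = back[j, s]


@njit(cache=True)
def _viterbi_batch(obs_batch, A, rho, mu, breaks):  # pragma: no cover - numba
    Q, M = obs_batch.shape
    out = np.empty((Q, M), dtype=np.uint8)
    for q in range(Q):
        _viterbi_alleles(obs_batch[q], A, rho, mu, breaks, out[q])
    return out


def _breaks_array(breaks, m: int) -> np.ndarray:
    if breaks is None:
        return np.zeros(m, dtype=np.int8)
    out = np.ascontiguousarray(breaks, dtype=np.int8)
    if out.shape[0] != m:
        raise ConfigError("chromosome-break mask length mismatch")
    return out


def chromosome_break_mask(variant_table) -> np.ndarray:
    """1 at each site that opens a new chromosome (free recombination)."""
    chrom = variant_table.df["chrom"].to_numpy()
    mask = np.zeros(len(chrom), dtype=np.int8)
    mask[1:] = chrom[1:] != chrom[:-1]
    return mask


def viterbi_alleles_batch(
    obs_batch: np.ndarray,
    reference: np.ndarray,
    params: LsParams,
    breaks: np.ndarray | None = None,
) -> np.ndarray:
    """Alleles along the most-likely copying path for each query."""
    obs = np.ascontiguousarray(obs_batch, dtype=np.int8)
    A = np.ascontiguousarray(reference, dtype=np.uint8)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ConfigError("reference panel must have >= 2 haplotypes")
    if obs.shape[1] != A.shape[1]:
        raise ConfigError("observation length does not match panel sites")
    return _viterbi_batch(
        obs, A, params.switch_prob, params.mismatch_prob, _breaks_array(breaks, A.shape[1])
    )


def _validate(obs: np.ndarray, reference: np.ndarray) -> None:
    if reference.ndim != 2 or reference.shape[0] < 2:
        raise ConfigError("reference panel must have >= 2 haplotypes")
    if obs.shape[-1] != reference.shape[1]:
        raise ConfigError("observation length does not match panel sites")
    if not (np.asarray(obs) >= 0).any():
        raise ConfigError("at least one typed site is required")


def ls_forward_backward(
    observed: np.ndarray,
    reference: np.ndarray,
    params: LsParams,
    breaks: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior decode one partial haplotype against a reference panel.

    Parameters
    ----------
    observed
        int vector over all reference sites; 0/1 at typed sites, -1 at
        untyped sites.
    reference
        (H, M) 0/1 haplotype matrix.

    Returns
    -------
    gamma, post_alt, loo_alt
        Copying-state posteriors (M, H); ALT posterior per site; exact
        leave-one-out ALT posterior (equals ``post_alt`` at untyped
        sites).
    """
    obs = np.ascontiguousarray(observed, dtype=np.int8)
    A = np.ascontiguousarray(reference, dtype=np.uint8)
    _validate(obs, A)
    H, M = A.shape
    alpha = np.empty((M, H))
    gamma = np.empty((M, H))
    post = np.empty(M)
    loo = np.empty(M)
    _fb_fill_gamma(
        obs, A, params.switch_prob, params.mismatch_prob,
        _breaks_array(breaks, M), alpha, gamma,
    )
    _posteriors_from_gamma(obs, A, params.mismatch_prob, gamma, post, loo)
    return gamma, post, loo


def fb_posteriors_batch(
    obs_batch: np.ndarray,
    reference: np.ndarray,
    params: LsParams,
    breaks: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ALT and leave-one-out posteriors for a batch of partial haplotypes.

    ``obs_batch`` is (Q, M) with -1 marking untyped sites per query.
    Returns ``(post_alt, loo_alt)`` each (Q, M).
    """
    obs = np.ascontiguousarray(obs_batch, dtype=np.int8)
    A = np.ascontiguousarray(reference, dtype=np.uint8)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ConfigError("reference panel must have >= 2 haplotypes")
    if obs.shape[1] != A.shape[1]:
        raise ConfigError("observation length does not match panel sites")
    if not (obs >= 0).any(axis=1).all():
        raise ConfigError("every query needs at least one typed site")
    return _fb_batch(
        obs, A, params.switch_prob, params.mismatch_prob,
        _breaks_array(breaks, A.shape[1]),
    )
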