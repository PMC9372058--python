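"""Haplotype phasing by iterative haploid conditional refinement.

Heterozygote phases start uniformly at random.  Each sweep, samples are
split into two blocks; every sample in a block runs a haploid
Li-Stephens decode against a conditioning panel of K haplotypes drawn
from the *other* block's current estimates (so no sample conditions on
itself), with homozygous sites fixed and heterozygous/missing sites
untyped.  Haplotype 1 takes the alleles of the most-likely copying path
(Viterbi) at heterozygous sites -- a coherent path keeps adjacent
heterozygotes phased consistently, where independent per-site posterior
modes flicker -- and haplotype 2 is the genotype complement.  Missing
genotypes take the path allele on both haplotypes.  The final sweep's
estimate is returned; by construction hap1 + hap2 equals the genotype
at every observed site.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import ConfigError, GenotypeMatrix, HaplotypePanel, MISSING
from .lshmm import LsParams, chromosome_break_mask, viterbi_alleles_batch

__all__ = ["phase_cohort", "switch_error_rate"]


def phase_cohort(
    gm: GenotypeMatrix,
    params: LsParams,
    reference: HaplotypePanel | None = None,
) -> HaplotypePanel:
    """Phase an unphased cohort on its variant set.

    When a phased ``reference`` over the same variants is supplied, its
    haplotypes are prepended to every conditioning panel (cohort
    estimates carry their own phase errors, and conditioning on clean
    external haplotypes substantially lowers the switch-error floor, as
    in reference-based phasing services).
    """
    ref_haps = None
    if reference is not None:
        if not reference.variants.equals(gm.variants):
            raise ConfigError("phasing reference variants differ from cohort")
        ref_haps = reference.haplotypes
    n, m = gm.n_samples, gm.n_variants
    if n < 2:
        raise ConfigError("phasing requires at least 2 samples")
    k = params.conditioning_haplotypes
    # each block conditions on the other block's ~n haplotypes
    avail = 2 * (n - (n // 2))
    if k > avail - 2:
        warnings.warn(
            f"conditioning panel reduced from {k} to {max(avail - 2, 2)} "
            f"(only {n} samples)",
            stacklevel=2,
        )
        k = max(avail - 2, 2)

    rng = np.random.default_rng(params.seed)
    breaks = chromosome_break_mask(gm.variants)
    g = gm.values
    het = g == 1
    miss = g == MISSING
    # observation template: hom sites typed, het/missing untyped
    obs = np.full((n, m), -1, dtype=np.int8)
    obs[g == 0] = 0
    obs[g == 2] = 1

    # initial haplotypes: random het phase, allele-frequency draw at missing
    hap1 = (g == 2).astype(np.uint8)
    hap2 = hap1.copy()
    r = rng.random((n, m)) < 0.5
    hap1[het] = r[het]
    hap2[het] = ~r[het]
    freq = gm.alt_frequency()
    freq = np.where(np.isfinite(freq), freq, 0.0)
    fill = rng.random((n, m)) < freq[None, :]
    hap1[miss] = fill[miss]
    hap2[miss] = fill[miss]

    haps = np.empty((2 * n, m), dtype=np.uint8)
    total_sweeps = params.phasing_burnin + params.phasing_iterations
    for sweep in range(total_sweeps):
        haps[0::2] = hap1
        haps[1::2] = hap2
        perm = rng.permutation(n)
        blocks = [perm[: n // 2], perm[n // 2 :]]
        for b in (0, 1):
            rows = blocks[b]
            others = blocks[1 - b]
            pool = np.stack([2 * others, 2 * others + 1], axis=1).ravel()
            sel = rng.choice(pool, size=min(k, pool.size), replace=False)
            panel = haps[sel] if ref_haps is None else np.vstack([ref_haps, haps[sel]])
            # most-likely copying path: coherent within copied segments,
            # so adjacent heterozygotes phase consistently
            vit = viterbi_alleles_batch(obs[rows], panel, params, breaks)
            h = het[rows]
            mi = miss[rows]
            hap1[rows] = np.where(h | mi, vit, hap1[rows])
            hap2[rows] = np.where(h, 1 - vit, np.where(mi, vit, hap2[rows]))

    haps[0::2] = hap1
    haps[1::2] = hap2
    return HaplotypePanel(gm.variants, list(gm.sample_ids), gm.platform, haps)


def switch_error_rate(
    inferred: HaplotypePanel, truth_diplotypes: np.ndarray
) -> float:
    """Mean per-sample switch-error rate against true phased diplotypes.

    Counts phase flips between consecutive heterozygous sites (sites
    heterozygous in both truth and inference), divided by the number of
    such consecutive pairs, averaged over samples with at least one
    informative pair.
    """
    h = inferred.haplotypes
    t = np.asarray(truth_diplotypes, dtype=np.int8)
    n = inferred.n_samples
    rates = []
    for i in range(n):
        ih1 = h[2 * i].astype(np.int8)
        ih2 = h[2 * i + 1].astype(np.int8)
        th1 = t[2 * i]
        th2 = t[2 * i + 1]
        het = (ih1 != ih2) & (th1 != th2)
        idx = np.flatnonzero(het)
        if idx.size < 2:
            continue
        # at each het site: does inferred hap1 carry truth hap1's allele?
        agree = ih1[idx] == th1[idx]
        switches = (agree[1:] != agree[:-1]).sum()
        rates.append(switches / (idx.size - 1))
    if not rates:
        raise ConfigError("no informative heterozygote pairs")
    return float(np.mean(rates))
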