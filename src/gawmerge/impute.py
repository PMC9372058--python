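"""Imputation to a phased reference, R2/ER2 quality metrics, and the
two-round ER2-filtered imputation step.

Each study haplotype is decoded against the reference panel with the
Li-Stephens forward-backward; the sample dosage at a site is the sum of
its two haplotypes' ALT posteriors.  Dosages at typed sites are
model-based (not copied), which is what makes the leave-one-out
empirical R2 (ER2) well defined there: the typed site's emission factor
is divided out of the state posterior, exactly equivalent to re-running
with the site untyped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    ARRAY,
    ConfigError,
    DosageMatrix,
    GenotypeMatrix,
    HaplotypePanel,
    MISSING,
    WGS,
)
from .lshmm import LsParams, chromosome_break_mask, fb_posteriors_batch
from .phase import phase_cohort

__all__ = [
    "ImputeResult",
    "ImputationQc",
    "impute_to_reference",
    "compute_r2",
    "compute_er2",
    "two_round_impute",
]

_CHUNK = 64  # haplotypes decoded per batch call (bounds working memory)


@dataclass
class ImputeResult:
    dosages: DosageMatrix
    loo_dosages: np.ndarray  # (n_samples, n_typed) leave-one-out dosages
    typed_ref_indices: np.ndarray  # reference-site index of each typed site


@dataclass
class ImputationQc:
    """Per-round quality metrics retained across the two-round step."""

    rounds: dict = field(default_factory=dict)

    def record(self, round_no: int, keys, er2, r2_all, r2_array, r2_wgs) -> None:
        self.rounds[round_no] = {
            "variant_keys": list(keys),
            "er2": np.asarray(er2, dtype=float),
            "r2_all": np.asarray(r2_all, dtype=float),
            "r2_array": np.asarray(r2_array, dtype=float),
            "r2_wgs": np.asarray(r2_wgs, dtype=float),
        }


def compute_r2(dosages: np.ndarray, sample_mask: np.ndarray | None = None) -> float:
    """Imputation quality: population dosage variance over 2p(1-p).

    Capped to [0, 1]; monomorphic estimated frequency gives 0.
    """
    d = np.asarray(dosages, dtype=float)
    if sample_mask is not None:
        d = d[np.asarray(sample_mask)]
    if d.size < 2:
        raise ConfigError("R2 needs at least 2 samples")
    p = d.mean() / 2.0
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(min(1.0, d.var() / (2.0 * p * (1.0 - p))))


def compute_er2(observed_genotypes: np.ndarray, loo_dosages: np.ndarray) -> float:
    """Squared Pearson correlation of leave-one-out dosage with observed
    genotype over samples with a non-missing genotype.

    Degenerate inputs (zero variance on either side, or fewer than 3
    informative samples) give 0.
    """
    g = np.asarray(observed_genotypes)
    d = np.asarray(loo_dosages, dtype=float)
    ok = g != MISSING
    g = g[ok].astype(float)
    d = d[ok]
    if g.size < 3:
        return 0.0
    if g.std() == 0.0 or d.std() == 0.0:
        return 0.0
    r = np.corrcoef(g, d)[0, 1]
    return float(r * r)


def _map_typed_sites(study: HaplotypePanel, reference: HaplotypePanel) -> np.ndarray:
    ref_keys = {k: j for j, k in enumerate(reference.variants.keys)}
    idx = []
    absent = []
    for k in study.variants.keys:
        j = ref_keys.get(k)
        if j is None:
            absent.append(k)
        else:
            idx.append(j)
    if absent:
        raise ConfigError(f"study variants absent from reference: {absent[:5]}")
    return np.asarray(idx, dtype=int)


def impute_to_reference(
    study: HaplotypePanel, reference: HaplotypePanel, params: LsParams
) -> ImputeResult:
    """Impute a phased study panel to all reference sites."""
    typed = _map_typed_sites(study, reference)
    n = study.n_samples
    m_ref = reference.n_variants
    ref = np.ascontiguousarray(reference.haplotypes, dtype=np.uint8)

    breaks = chromosome_break_mask(reference.variants)
    obs_template = np.full(m_ref, -1, dtype=np.int8)
    hap_post = np.empty((study.n_haplotypes, m_ref))
    hap_loo = np.empty((study.n_haplotypes, len(typed)))
    q = study.n_haplotypes
    for start in range(0, q, _CHUNK):
        stop = min(start + _CHUNK, q)
        obs = np.tile(obs_template, (stop - start, 1))
        obs[:, typed] = study.haplotypes[start:stop].astype(np.int8)
        post, loo = fb_posteriors_batch(obs, ref, params, breaks)
        hap_post[start:stop] = post
        hap_loo[start:stop] = loo[:, typed]

    # convert copying-state ALT posteriors into study-allele posteriors:
    # untyped sites (and leave-one-out values) marginalise over the copy
    # noise nu; typed sites additionally condition on the observed
    # allele, so observations dominate wherever the context is not
    # overwhelmingly confident (epsilon << nu)
    nu = params.copy_noise
    eps = params.genotype_error
    hap_alt = nu + (1.0 - 2.0 * nu) * hap_post
    hap_loo = nu + (1.0 - 2.0 * nu) * hap_loo
    # P(study allele = 1 | state allele a, observed o)
    w_o1 = ((1 - eps) * (1 - nu)) / ((1 - eps) * (1 - nu) + eps * nu)
    w_o1_a0 = ((1 - eps) * nu) / ((1 - eps) * nu + eps * (1 - nu))
    w_o0 = (eps * (1 - nu)) / (eps * (1 - nu) + (1 - eps) * nu)
    w_o0_a0 = (eps * nu) / (eps * nu + (1 - eps) * (1 - nu))
    p_typed = hap_post[:, typed]
    o = study.haplotypes.astype(bool)
    typed_alt = np.where(
        o,
        w_o1 * p_typed + w_o1_a0 * (1.0 - p_typed),
        w_o0 * p_typed + w_o0_a0 * (1.0 - p_typed),
    )
    hap_alt[:, typed] = typed_alt

    dosage = hap_alt[0::2] + hap_alt[1::2]
    loo_dosage = hap_loo[0::2] + hap_loo[1::2]

    genotyped = np.zeros(m_ref, dtype=bool)
    genotyped[typed] = True
    is_arr = study.platform == ARRAY
    is_wgs = study.platform == WGS
    r2_all = np.array(
        [compute_r2(dosage[:, j]) if n >= 2 else np.nan for j in range(m_ref)]
    )
    r2_arr = np.array(
        [compute_r2(dosage[:, j], is_arr) if is_arr.sum() >= 2 else np.nan
         for j in range(m_ref)]
    )
    r2_wgs = np.array(
        [compute_r2(dosage[:, j], is_wgs) if is_wgs.sum() >= 2 else np.nan
         for j in range(m_ref)]
    )
    er2 = np.full(m_ref, np.nan)

    dm = DosageMatrix(
        reference.variants,
        list(study.sample_ids),
        study.platform,
        dosage,
        genotyped,
        r2_all,
        r2_arr,
        r2_wgs,
        er2,
    )
    return ImputeResult(dm, loo_dosage, typed)


def _er2_for_typed(
    result: ImputeResult, observed: GenotypeMatrix
) -> np.ndarray:
    """ER2 per typed site, using the pre-phasing observed genotypes."""
    obs_keys = {k: j for j, k in enumerate(observed.variants.keys)}
    ref_keys = result.dosages.variants.keys
    er2 = np.empty(len(result.typed_ref_indices))
    for t, j_ref in enumerate(result.typed_ref_indices):
        j_obs = obs_keys[ref_keys[j_ref]]
        er2[t] = compute_er2(observed.values[:, j_obs], result.loo_dosages[:, t])
    return er2


def two_round_impute(
    merged_panel: HaplotypePanel,
    observed: GenotypeMatrix,
    reference: HaplotypePanel,
    params: LsParams,
    er2_threshold: float = 0.9,
    reimpute_only: bool = False,
) -> tuple[DosageMatrix, ImputationQc, list]:
    """Round-1 imputation, ER2 filter on genotyped variants, re-impute.

    Genotyped variants with ER2 strictly below the threshold are
    removed from the typed set; round 2 re-phases the reduced set per
    platform (``reimpute_only=True`` instead drops the columns from the
    phased panel and re-imputes without re-phasing) and re-imputes.
    Returns the round-2 dosages, both rounds' metrics, and the dropped
    variant keys.
    """
    qc = ImputationQc()
    res1 = impute_to_reference(merged_panel, reference, params)
    er2_1 = _er2_for_typed(res1, observed)
    typed_keys = [merged_panel.variants.keys[t] for t in range(merged_panel.n_variants)]
    qc.record(
        1,
        typed_keys,
        er2_1,
        res1.dosages.r2_all[res1.typed_ref_indices],
        res1.dosages.r2_array[res1.typed_ref_indices],
        res1.dosages.r2_wgs[res1.typed_ref_indices],
    )
    dm1 = res1.dosages
    dm1.er2[res1.typed_ref_indices] = er2_1

    drop = np.flatnonzero(er2_1 < er2_threshold)
    dropped_keys = [typed_keys[j] for j in drop]
    if drop.size == merged_panel.n_variants:
        raise ConfigError("all genotyped variants failed the ER2 filter")
    if drop.size == 0:
        # identical typed set and seeds: round 2 would reproduce round 1
        qc.record(
            2,
            typed_keys,
            er2_1,
            res1.dosages.r2_all[res1.typed_ref_indices],
            res1.dosages.r2_array[res1.typed_ref_indices],
            res1.dosages.r2_wgs[res1.typed_ref_indices],
        )
        return dm1, qc, []

    keep = np.setdiff1d(np.arange(merged_panel.n_variants), drop)
    if reimpute_only:
        panel2 = merged_panel.subset_variants(keep)
    else:
        obs2 = observed.subset_variants(
            _observed_indices(observed, [typed_keys[j] for j in keep])
        )
        panel2 = _rephase_per_platform(obs2, params, reference)
    res2 = impute_to_reference(panel2, reference, params)
    er2_2 = _er2_for_typed(res2, observed)
    keep_keys = [typed_keys[j] for j in keep]
    qc.record(
        2,
        keep_keys,
        er2_2,
        res2.dosages.r2_all[res2.typed_ref_indices],
        res2.dosages.r2_array[res2.typed_ref_indices],
        res2.dosages.r2_wgs[res2.typed_ref_indices],
    )
    dm2 = res2.dosages
    dm2.er2[res2.typed_ref_indices] = er2_2
    return dm2, qc, dropped_keys


def _observed_indices(observed: GenotypeMatrix, keys: list) -> np.ndarray:
    lookup = {k: j for j, k in enumerate(observed.variants.keys)}
    return np.asarray([lookup[k] for k in keys], dtype=int)


def _rephase_per_platform(
    observed: GenotypeMatrix,
    params: LsParams,
    reference: HaplotypePanel | None = None,
) -> HaplotypePanel:
    """Phase each platform cohort independently and merge (array first)."""
    from .harmonize import merge_phased

    ref_sub = None
    if reference is not None:
        ref_keys = {k: j for j, k in enumerate(reference.variants.keys)}
        idx = np.asarray([ref_keys[k] for k in observed.variants.keys], dtype=int)
        ref_sub = reference.subset_variants(idx)
    panels = []
    for plat in (ARRAY, WGS):
        idx = np.flatnonzero(observed.platform == plat)
        if idx.size == 0:
            continue
        panels.append(phase_cohort(observed.subset_samples(idx), params, ref_sub))
    if len(panels) == 1:
        return panels[0]
    return merge_phased(panels[0], panels[1])
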