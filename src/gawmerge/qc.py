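"""Cohort quality control: missingness, Hardy-Weinberg, sex check,
FILTER-flag exclusion, PCA and ancestry matching.

Both cohorts of the protocol run through this exact code path with
identical thresholds; exclusions use strict inequalities (a sample
missing exactly 3% is retained, a HWE p exactly 1e-4 is retained).
Every exclusion carries exactly one primary reason code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    MISSING,
    ConfigError,
    GenotypeMatrix,
    VariantTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "QcThresholds",
    "filter_sample_missingness",
    "filter_variant_missingness",
    "hwe_exact_test",
    "hwe_filter",
    "sex_check",
    "drop_flagged_variants",
    "ld_prune",
    "pca_genotypes",
    "ancestry_match",
    "run_qc",
]

#: TOPMed-style FILTER labels excluded by default (consumed, never recomputed)
DEFAULT_FLAG_BLOCKLIST = frozenset({"SVM", "CEN", "DISC", "EXHET", "CHRXHET"})


@dataclass(frozen=True)
class QcThresholds:
    sample_miss: float = 0.03
    variant_miss: float = 0.03
    hwe_p: float = 1e-4
    sex_het_rate: float = 0.05
    sex_min_sites: int = 20
    pca_components: int = 10
    ld_prune_r2: float = 0.2
    flag_blocklist: frozenset = DEFAULT_FLAG_BLOCKLIST


@dataclass
class QcReport:
    """Exclusions with single primary reason codes, plus thresholds used."""

    excluded_samples: dict = field(default_factory=dict)  # sample_id -> reason
    excluded_variants: dict = field(default_factory=dict)  # variant key -> reason
    thresholds: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def add_sample(self, sample_id: str, reason: str) -> None:
        self.excluded_samples.setdefault(sample_id, reason)

    def add_variant(self, key, reason: str) -> None:
        self.excluded_variants.setdefault(key, reason)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def filter_sample_missingness(
    gm: GenotypeMatrix, threshold: float = 0.03, report: QcReport | None = None
) -> np.ndarray:
    """Indices of samples with missing fraction strictly above threshold."""
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ConfigError("empty genotype matrix")
    frac = gm.missing_mask().mean(axis=1)
    bad = np.flatnonzero(frac > threshold)
    if report is not None:
        for i in bad:
            report.add_sample(gm.sample_ids[i], "SAMPLE_MISSINGNESS")
    return bad


def filter_variant_missingness(
    gm: GenotypeMatrix, threshold: float = 0.03, report: QcReport | None = None
) -> np.ndarray:
    """Indices of variants with missing fraction strictly above threshold."""
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ConfigError("empty genotype matrix")
    frac = gm.missing_mask().mean(axis=0)
    bad = np.flatnonzero(frac > threshold)
    if report is not None:
        keys = gm.variants.keys
        for j in bad:
            report.add_variant(keys[j], "VARIANT_MISSINGNESS")
    return bad


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Enumerates every heterozygote count compatible with the observed
    allele counts via the stable mid-point recurrence and sums the
    probabilities of configurations no more likely than the observed
    one.  Monomorphic input gives p = 1.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0 or int(c) != c:
            raise ConfigError("genotype counts must be non-negative integers")
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ConfigError("at least one genotype required")
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if rare == 0:
        return 1.0

    # mid-point of the het distribution, matched to the parity of `rare`
    mid = int(rare * (2 * n - rare) / (2.0 * n))
    if mid % 2 != rare % 2:
        mid += 1
    probs = np.zeros(rare + 1)
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h*(h-1) / (4 * n_r(h-2+..)*..)
    h = mid
    while h > 1:
        n_r = (rare - h) // 2  # rare homozygotes at h hets
        n_c = n - h - n_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (n_r + 1) * (n_c + 1))
        h -= 2
    h = mid
    while h <= rare - 2:
        n_r = (rare - h) // 2
        n_c = n - h - n_r
        probs[h + 2] = probs[h] * 4.0 * n_r * n_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = probs.sum()
    p_obs = probs[n_ab] / total
    p = probs[probs / total <= p_obs * (1 + 1e-12)].sum() / total
    return float(min(1.0, p))


def hwe_filter(
    gm: GenotypeMatrix, p_threshold: float = 1e-4, report: QcReport | None = None
) -> np.ndarray:
    """Indices of variants failing the HWE exact test (p strictly below)."""
    v = gm.values
    bad = []
    for j in range(gm.n_variants):
        col = v[:, j]
        n_bb = int((col == 2).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 0).sum())
        if n_aa + n_ab + n_bb == 0:
            continue
        if hwe_exact_test(n_aa, n_ab, n_bb) < p_threshold:
            bad.append(j)
    bad = np.asarray(bad, dtype=int)
    if report is not None:
        keys = gm.variants.keys
        for j in bad:
            report.add_variant(keys[j], "HWE")
    return bad


# ---------------------------------------------------------------------------
# sex check
# ---------------------------------------------------------------------------

def sex_check(
    gm: GenotypeMatrix,
    reported_sex: np.ndarray,
    het_rate_threshold: float = 0.05,
    min_sites: int = 20,
    report: QcReport | None = None,
) -> np.ndarray:
    """Compare X-chromosome heterozygosity with reported sex (1=M, 2=F).

    Uses variants whose chromosome is ``X`` (or ``chrX``); with no X
    variants the check is a logged no-op.  A sample needs at least
    ``min_sites`` informative (non-missing) X calls to be judged.
    """
    chroms = gm.variants.df["chrom"].to_numpy()
    on_x = np.flatnonzero((chroms == "X") | (chroms == "chrX"))
    if on_x.size == 0:
        logger.info("sex check skipped: no X-chromosome variants")
        if report is not None:
            report.notes.append("SEX_CHECK_SKIPPED_NO_X")
        return np.asarray([], dtype=int)
    x = gm.values[:, on_x]
    observed = x != MISSING
    n_obs = observed.sum(axis=1)
    het = ((x == 1) & observed).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_obs > 0, het / np.maximum(n_obs, 1), 0.0)
    reported_sex = np.asarray(reported_sex)
    informative = n_obs >= min_sites
    male_fail = (reported_sex == 1) & (rate > het_rate_threshold)
    female_fail = (reported_sex == 2) & (rate < het_rate_threshold)
    bad = np.flatnonzero(informative & (male_fail | female_fail))
    if report is not None:
        for i in bad:
            report.add_sample(gm.sample_ids[i], "SEX_CHECK")
    return bad


# ---------------------------------------------------------------------------
# flagged variants
# ---------------------------------------------------------------------------

def drop_flagged_variants(
    table: VariantTable,
    blocklist: frozenset = DEFAULT_FLAG_BLOCKLIST,
    report: QcReport | None = None,
) -> np.ndarray:
    """Indices of variants whose FILTER flags intersect the blocklist."""
    bad = []
    reasons = []
    for j, flags in enumerate(table.df["filter_flags"]):
        hit = sorted(set(flags) & blocklist)
        if hit:
            bad.append(j)
            reasons.append(f"FLAG:{hit[0]}")
    bad = np.asarray(bad, dtype=int)
    if report is not None:
        keys = table.keys
        for j, r in zip(bad, reasons):
            report.add_variant(keys[j], r)
    return bad


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def ld_prune(
    values: np.ndarray, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns kept variant indices.

    Within each window, one variant of any pair with r^2 above
    ``r2_max`` is removed (the later one, keeping the sliding scan
    deterministic); missing genotypes are mean-imputed per variant.
    """
    x = values.astype(float)
    x[values == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    m = x.shape[1]
    keep = np.ones(m, dtype=bool)
    sd = x.std(axis=0)
    keep[sd == 0] = False
    start = 0
    while start < m:
        idx = np.flatnonzero(keep[start : start + window]) + start
        if idx.size > 1:
            sub = x[:, idx]
            c = np.corrcoef(sub, rowvar=False)
            r2 = c**2
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if keep[idx[b]] and r2[a, b] > r2_max:
                        keep[idx[b]] = False
        start += step
        if start + step >= m and start >= m:
            break
    return np.flatnonzero(keep)


def pca_genotypes(
    gm: GenotypeMatrix | np.ndarray,
    n_components: int = 10,
    prune: bool = True,
    ld_prune_r2: float = 0.2,
) -> np.ndarray:
    """Per-sample principal component scores of the genotype matrix.

    Columns are centred at 2p and scaled by sqrt(2p(1-p)) before the
    SVD; missing entries are mean-imputed per variant.  Signs are fixed
    by making the largest-magnitude loading of each component positive.
    """
    values = gm.values if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    if prune:
        kept = ld_prune(values, r2_max=ld_prune_r2)
        values = values[:, kept]
    if values.shape[1] < n_components:
        raise ConfigError(
            f"PCA needs >= {n_components} variants, got {values.shape[1]}"
        )
    x = values.astype(float)
    x[values == MISSING] = np.nan
    obs = np.isfinite(x)
    p = np.nansum(x, axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
    x = np.where(obs, x, 2.0 * p)
    denom = np.sqrt(np.maximum(2.0 * p * (1.0 - p), 1e-12))
    z = (x - 2.0 * p) / denom
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            scores[:, k] *= -1.0
    return scores


def ancestry_match(
    study_scores: np.ndarray,
    reference_scores_by_group: dict,
    declared_group: np.ndarray,
    sample_ids: list[str] | None = None,
    mad_factor: float = 6.0,
    report: QcReport | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid ancestry assignment with outlier exclusion.

    Returns (assigned_group, excluded_sample_indices).  A sample is
    excluded when its assigned group differs from the declared group or
    its distance to the nearest centroid exceeds ``mad_factor`` times
    that group's median absolute deviation of member distances.
    """
    groups = sorted(reference_scores_by_group)
    centroids = {}
    mads = {}
    for g in groups:
        pts = np.asarray(reference_scores_by_group[g], dtype=float)
        if pts.shape[0] < 3:
            raise ConfigError(f"reference group {g!r} has < 3 samples")
        c = pts.mean(axis=0)
        d = np.linalg.norm(pts - c, axis=1)
        centroids[g] = c
        mads[g] = max(np.median(np.abs(d - np.median(d))), 1e-12)
    study = np.asarray(study_scores, dtype=float)
    dists = np.stack(
        [np.linalg.norm(study - centroids[g], axis=1) for g in groups], axis=1
    )
    nearest = np.argmin(dists, axis=1)
    assigned = np.asarray([groups[k] for k in nearest])
    nearest_d = dists[np.arange(len(study)), nearest]
    median_d = {
        g: np.median(
            np.linalg.norm(
                np.asarray(reference_scores_by_group[g]) - centroids[g], axis=1
            )
        )
        for g in groups
    }
    excluded = []
    for i in range(len(study)):
        g = assigned[i]
        mismatch = g != declared_group[i]
        outlier = nearest_d[i] > median_d[g] + mad_factor * mads[g]
        if mismatch or outlier:
            excluded.append(i)
            if report is not None and sample_ids is not None:
                report.add_sample(sample_ids[i], "ANCESTRY_MISMATCH")
    return assigned, np.asarray(excluded, dtype=int)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_qc(
    gm: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    reported_sex: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Full per-cohort QC; identical code path for array and WGS data.

    Order: flagged variants once, then sample missingness, variant
    missingness, HWE and sex check iterated to a fixed point (removing
    a dense-missing variant can push a borderline sample over the 3%
    threshold and vice versa), which makes the stage idempotent:
    re-running on its own output excludes nothing further.
    """
    report = QcReport(thresholds=vars(thresholds).copy())
    bad_v = drop_flagged_variants(gm.variants, thresholds.flag_blocklist, report)
    keep_v = np.setdiff1d(np.arange(gm.n_variants), bad_v)
    gm = gm.subset_variants(keep_v)

    if reported_sex is not None:
        reported_sex = np.asarray(reported_sex)

    changed = True
    while changed:
        changed = False

        bad_s = filter_sample_missingness(gm, thresholds.sample_miss, report)
        if bad_s.size:
            changed = True
            keep_s = np.setdiff1d(np.arange(gm.n_samples), bad_s)
            if reported_sex is not None:
                reported_sex = reported_sex[keep_s]
            gm = gm.subset_samples(keep_s)

        bad_v = filter_variant_missingness(gm, thresholds.variant_miss, report)
        if bad_v.size:
            changed = True
            gm = gm.subset_variants(np.setdiff1d(np.arange(gm.n_variants), bad_v))

        bad_v = hwe_filter(gm, thresholds.hwe_p, report)
        if bad_v.size:
            changed = True
            gm = gm.subset_variants(np.setdiff1d(np.arange(gm.n_variants), bad_v))

        if reported_sex is not None:
            bad_s = sex_check(
                gm,
                reported_sex,
                thresholds.sex_het_rate,
                thresholds.sex_min_sites,
                report,
            )
            if bad_s.size:
                changed = True
                keep_s = np.setdiff1d(np.arange(gm.n_samples), bad_s)
                reported_sex = reported_sex[keep_s]
                gm = gm.subset_samples(keep_s)

    return gm, report
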