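"""Synthetic two-technology cohort simulator.

Emulates the data geometry the merging protocol assumes, without
coalescent machinery: a phased reference panel with linkage
disequilibrium, study cohorts drawn from it, an array platform that
observes a manifest subset of variants with its own error process, a
WGS platform observing every variant, a logistic phenotype driven by
specified causal variants, and optionally two ancestry groups with
shifted allele frequencies.

Haplotypes are founder mosaics: each new haplotype starts on a
uniformly chosen source haplotype, re-draws its source between adjacent
markers with a fixed switch probability, and flips the copied allele
with a fixed mutation probability.  The genetic map is abstract (one
interval between adjacent markers); marker distance is interval count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    ARRAY,
    MISSING,
    WGS,
    ConfigError,
    GenotypeMatrix,
    HaplotypePanel,
    VariantTable,
)

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_reference_panel",
    "simulate_study_cohort",
    "emulate_platform",
    "inject_differential_artifact",
    "array_manifest_indices",
]

_BASES = np.array(list("ACGT"))

# fixed sub-stream tags so each stage has an independent, reproducible stream
_TAG_PANEL, _TAG_COHORT, _TAG_MANIFEST, _TAG_ARRAY, _TAG_WGS = range(5)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with validation."""

    n_founders: int = 10
    n_ref_haplotypes: int = 200
    n_variants: int = 2000
    n_chromosomes: int = 1
    n_samples_array: int = 500
    n_samples_wgs: int = 500
    founder_switch_prob: float = 0.003
    founder_mutation_prob: float = 0.001
    array_variant_fraction: float = 0.5
    array_error_rate: float = 0.002
    wgs_error_rate: float = 0.001
    array_missing_rate: float = 0.002
    wgs_missing_rate: float = 0.001
    causal_effects: dict = field(default_factory=dict)  # variant index -> log OR
    phenotype_intercept: float = 0.0
    ancestry_groups: int = 1
    ancestry_freq_shift: float = 0.15
    founder_freq_overrides: dict = field(default_factory=dict)  # index -> freq
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigError("n_founders must be >= 2")
        if self.n_ref_haplotypes < 2 or self.n_variants < 1:
            raise ConfigError("n_ref_haplotypes/n_variants too small")
        for name in (
            "founder_switch_prob",
            "founder_mutation_prob",
            "array_error_rate",
            "wgs_error_rate",
            "array_missing_rate",
            "wgs_missing_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if not (0.0 < self.array_variant_fraction <= 1.0):
            raise ConfigError("array_variant_fraction must be in (0, 1]")
        if self.ancestry_groups not in (1, 2):
            raise ConfigError("ancestry_groups must be 1 or 2")
        if not (1 <= self.n_chromosomes <= 9) or self.n_chromosomes > self.n_variants:
            raise ConfigError("n_chromosomes must be in [1, 9] and <= n_variants")
        for idx in self.causal_effects:
            if not (0 <= idx < self.n_variants):
                raise ConfigError(f"causal variant index {idx} out of range")
        for idx, f in self.founder_freq_overrides.items():
            if not (0 <= idx < self.n_variants):
                raise ConfigError(f"frequency override index {idx} out of range")
            if not (0.0 < f < 1.0):
                raise ConfigError("frequency override must be in (0, 1)")


@dataclass
class TruthSet:
    """Ground truth for a simulated study cohort."""

    variants: VariantTable
    sample_ids: list[str]
    diplotypes: np.ndarray  # uint8, (2*n_samples, n_variants), phased
    phenotype: np.ndarray  # int8, 1 = case, 0 = control
    sex: np.ndarray  # int8, 1 = male, 2 = female
    ancestry: np.ndarray  # int, group index per sample
    causal_indices: list[int]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def genotypes(self) -> np.ndarray:
        d = self.diplotypes.astype(np.int8)
        return d[0::2] + d[1::2]

    def subset_samples(self, index: np.ndarray) -> "TruthSet":
        idx = np.asarray(index)
        hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return TruthSet(
            variants=self.variants,
            sample_ids=[self.sample_ids[i] for i in idx],
            diplotypes=self.diplotypes[hap_idx],
            phenotype=self.phenotype[idx],
            sex=self.sex[idx],
            ancestry=self.ancestry[idx],
            causal_indices=list(self.causal_indices),
        )


def _rng(cfg: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def _mosaic(
    rng: np.random.Generator,
    source: np.ndarray,
    n_haps: int,
    switch: float,
    mutation: float,
    chrom_start: np.ndarray | None = None,
) -> np.ndarray:
    """Draw mosaic haplotypes from a source panel (vectorised over rows).

    ``chrom_start`` marks sites opening a new chromosome: the copied
    source is redrawn there, so chromosomes segregate independently.
    """
    n_src, m = source.shape
    states = np.empty((n_haps, m), dtype=np.int64)
    states[:, 0] = rng.integers(0, n_src, n_haps)
    if m > 1:
        do_switch = rng.random((n_haps, m - 1)) < switch
        if chrom_start is not None:
            do_switch |= chrom_start[1:][None, :]
        proposals = rng.integers(0, n_src, (n_haps, m - 1))
        for j in range(1, m):
            states[:, j] = np.where(
                do_switch[:, j - 1], proposals[:, j - 1], states[:, j - 1]
            )
    alleles = source[states, np.arange(m)]
    if mutation > 0:
        flips = rng.random((n_haps, m)) < mutation
        alleles = alleles ^ flips
    return alleles.astype(np.uint8)


def chromosome_assignment(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(chrom label index per variant, is-chromosome-start flag per variant)."""
    sizes = np.full(cfg.n_chromosomes, cfg.n_variants // cfg.n_chromosomes)
    sizes[: cfg.n_variants % cfg.n_chromosomes] += 1
    chrom_idx = np.repeat(np.arange(cfg.n_chromosomes), sizes)
    starts = np.zeros(cfg.n_variants, dtype=bool)
    starts[np.cumsum(sizes)[:-1]] = True
    return chrom_idx, starts


def _make_variant_table(cfg: SimConfig, rng: np.random.Generator) -> VariantTable:
    chrom_idx, starts = chromosome_assignment(cfg)
    # positions restart per chromosome, abstract 1 kb spacing
    within = np.zeros(cfg.n_variants, dtype=np.int64)
    counter = 0
    for j in range(cfg.n_variants):
        if starts[j]:
            counter = 0
        within[j] = counter
        counter += 1
    pos = (within + 1) * 1000
    ref_idx = rng.integers(0, 4, cfg.n_variants)
    # skip the strand-complement base so no simulated SNP is palindromic
    # (A/T, C/G pairs are unresolvable after a strand flip and would be
    # discarded at the harmonization step; real manifests avoid them)
    offset = rng.integers(1, 3, cfg.n_variants)
    candidates = np.stack([(ref_idx + 1) % 4, (ref_idx + 2) % 4, (ref_idx + 3) % 4])
    complement_idx = 3 - ref_idx
    alt_idx = np.empty(cfg.n_variants, dtype=np.int64)
    for j in range(cfg.n_variants):
        opts = [b for b in candidates[:, j] if b != complement_idx[j]]
        alt_idx[j] = opts[offset[j] - 1]
    return VariantTable.from_arrays(
        chrom=[str(c + 1) for c in chrom_idx],
        pos=pos,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        ids=[f"var{j}" for j in range(cfg.n_variants)],
    )


def _founder_freqs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-group founder allele frequencies, shape (groups, n_variants)."""
    f = rng.uniform(0.05, 0.95, cfg.n_variants)
    for idx, freq in cfg.founder_freq_overrides.items():
        f[idx] = freq
    freqs = [f]
    if cfg.ancestry_groups == 2:
        shift = cfg.ancestry_freq_shift * rng.choice([-1.0, 1.0], cfg.n_variants)
        f2 = np.clip(f + shift, 0.02, 0.98)
        for idx, freq in cfg.founder_freq_overrides.items():
            f2[idx] = freq
        freqs.append(f2)
    return np.stack(freqs)


def simulate_reference_panel(
    cfg: SimConfig,
) -> tuple[HaplotypePanel, VariantTable, np.ndarray]:
    """Generate a phased reference haplotype panel with LD.

    Returns the panel, its variant table, and the ancestry-group index
    of each reference sample (haplotype pair).  With two ancestry
    groups the panel is split evenly between them.
    """
    rng = _rng(cfg, _TAG_PANEL)
    table = _make_variant_table(cfg, rng)
    freqs = _founder_freqs(cfg, rng)

    panels = []
    groups = []
    n_groups = cfg.ancestry_groups
    per_group = cfg.n_ref_haplotypes // n_groups
    counts = [per_group] * n_groups
    counts[-1] += cfg.n_ref_haplotypes - per_group * n_groups
    for g in range(n_groups):
        founders = (rng.random((cfg.n_founders, cfg.n_variants)) < freqs[g]).astype(
            np.uint8
        )
        # every simulated site is a polymorphic SNP (as on a real array
        # manifest): force fixed sites to segregate among the founders
        fixed_ref = founders.sum(axis=0) == 0
        fixed_alt = founders.sum(axis=0) == cfg.n_founders
        flip_at = rng.integers(0, cfg.n_founders, cfg.n_variants)
        for j in np.flatnonzero(fixed_ref):
            founders[flip_at[j], j] = 1
        for j in np.flatnonzero(fixed_alt):
            founders[flip_at[j], j] = 0
        # overridden sites get an exact founder allele count: with few
        # founders, Bernoulli drift (sd ~ 0.14 at 10 founders) would
        # otherwise swamp a requested frequency
        for idx, f in cfg.founder_freq_overrides.items():
            k = min(max(int(round(f * cfg.n_founders)), 1), cfg.n_founders - 1)
            perm = rng.permutation(cfg.n_founders)
            founders[:, idx] = 0
            founders[perm[:k], idx] = 1
        haps = _mosaic(
            rng,
            founders,
            counts[g],
            cfg.founder_switch_prob,
            cfg.founder_mutation_prob,
            chrom_start=chromosome_assignment(cfg)[1],
        )
        panels.append(haps)
        groups.extend([g] * (counts[g] // 2))
    haplotypes = np.vstack(panels)
    if haplotypes.shape[0] % 2 != 0:
        haplotypes = haplotypes[:-1]
    n_samples = haplotypes.shape[0] // 2
    panel = HaplotypePanel(
        variants=table,
        sample_ids=[f"REF{i}" for i in range(n_samples)],
        platform=np.array([WGS] * n_samples, dtype=object),
        haplotypes=haplotypes,
    )
    return panel, table, np.asarray(groups[:n_samples])


def simulate_study_cohort(
    panel: HaplotypePanel,
    cfg: SimConfig,
    n_samples: int | None = None,
    panel_groups: np.ndarray | None = None,
    id_prefix: str = "S",
    stream: int = 0,
) -> TruthSet:
    """Draw a study cohort as mosaics of the reference panel.

    Each sample's two haplotypes are independent mosaics of the panel
    haplotypes belonging to the sample's ancestry group; the phenotype
    is Bernoulli(logistic(intercept + sum beta_v * g_v)).  ``stream``
    lets callers draw several independent cohorts from one config.
    """
    if panel.n_haplotypes == 0:
        raise ConfigError("empty reference panel")
    rng = np.random.default_rng([cfg.seed, _TAG_COHORT, stream])
    if n_samples is None:
        n_samples = cfg.n_samples_array + cfg.n_samples_wgs

    n_groups = cfg.ancestry_groups
    ancestry = np.arange(n_samples) % n_groups
    if panel_groups is None:
        panel_groups = np.zeros(panel.n_samples, dtype=int)
    hap_groups = np.repeat(panel_groups, 2)

    diplotypes = np.empty((2 * n_samples, panel.n_variants), dtype=np.uint8)
    for g in range(n_groups):
        src = panel.haplotypes[hap_groups == g]
        if src.shape[0] == 0:
            raise ConfigError(f"reference panel has no haplotypes for group {g}")
        sample_idx = np.flatnonzero(ancestry == g)
        hap_idx = np.stack([2 * sample_idx, 2 * sample_idx + 1], axis=1).ravel()
        diplotypes[hap_idx] = _mosaic(
            rng,
            src,
            2 * len(sample_idx),
            cfg.founder_switch_prob,
            cfg.founder_mutation_prob,
            chrom_start=chromosome_assignment(cfg)[1],
        )

    geno = diplotypes[0::2].astype(np.int64) + diplotypes[1::2]
    logit = np.full(n_samples, cfg.phenotype_intercept, dtype=float)
    for idx, beta in cfg.causal_effects.items():
        logit += beta * geno[:, idx]
    p_case = 1.0 / (1.0 + np.exp(-logit))
    phenotype = (rng.random(n_samples) < p_case).astype(np.int8)
    sex = rng.integers(1, 3, n_samples).astype(np.int8)

    return TruthSet(
        variants=panel.variants,
        sample_ids=[f"{id_prefix}{i}" for i in range(n_samples)],
        diplotypes=diplotypes,
        phenotype=phenotype,
        sex=sex,
        ancestry=ancestry,
        causal_indices=sorted(cfg.causal_effects),
    )


def array_manifest_indices(cfg: SimConfig) -> np.ndarray:
    """Seeded random subset of variant indices forming the array manifest."""
    rng = _rng(cfg, _TAG_MANIFEST)
    n_on_array = max(1, int(round(cfg.array_variant_fraction * cfg.n_variants)))
    idx = rng.choice(cfg.n_variants, size=n_on_array, replace=False)
    return np.sort(idx)


def _apply_errors(
    rng: np.random.Generator, values: np.ndarray, error_rate: float, missing_rate: float
) -> np.ndarray:
    out = values.astype(np.int8).copy()
    if error_rate > 0:
        err = rng.random(out.shape) < error_rate
        shift = rng.integers(1, 3, out.shape)
        out = np.where(err, (out + shift) % 3, out).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(out.shape) < missing_rate
        out[miss] = MISSING
    return out


def emulate_platform(
    truth: TruthSet, platform: str, cfg: SimConfig, stream: int = 0
) -> GenotypeMatrix:
    """Pass true genotypes through a platform's observation process.

    The array platform observes only the manifest subset of variants;
    WGS observes all.  Each genotype independently moves to a uniformly
    chosen different value in {0,1,2} with the platform's error rate,
    then is set missing with the platform's missingness rate.
    """
    if platform not in (ARRAY, WGS):
        raise ConfigError(f"unknown platform {platform!r}")
    geno = truth.genotypes()
    if platform == ARRAY:
        manifest = array_manifest_indices(cfg)
        geno = geno[:, manifest]
        table = truth.variants.subset(manifest)
        rng = np.random.default_rng([cfg.seed, _TAG_ARRAY, stream])
        values = _apply_errors(rng, geno, cfg.array_error_rate, cfg.array_missing_rate)
    else:
        table = truth.variants
        rng = np.random.default_rng([cfg.seed, _TAG_WGS, stream])
        values = _apply_errors(rng, geno, cfg.wgs_error_rate, cfg.wgs_missing_rate)
    n = truth.n_samples
    return GenotypeMatrix(
        variants=table,
        sample_ids=list(truth.sample_ids),
        platform=np.array([platform] * n, dtype=object),
        values=values,
    )


def inject_differential_artifact(
    gm: GenotypeMatrix,
    variant_indices,
    extra_error: float,
    seed: int,
) -> GenotypeMatrix:
    """Add a platform-specific systematic error at selected variants.

    Each allele of the genotype flips independently with probability
    ``extra_error`` (an allele-level miscall, as produced by systematic
    strand or cluster artifacts).  This perturbs the allele frequency
    toward 0.5 while keeping alleles independent, so the damaged
    variant reaches the imputation stage where the ER2 filter is meant
    to catch it.  Only the listed variants of this matrix are touched.
    """
    idx = np.asarray(variant_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= gm.n_variants):
        raise ConfigError("artifact variant index out of range")
    if not (0.0 <= extra_error <= 1.0):
        raise ConfigError("extra_error must be in [0, 1]")
    values = gm.values.copy()
    if extra_error > 0 and idx.size:
        rng = np.random.default_rng(seed)
        block = values[:, idx]
        observed = block != MISSING
        g = np.clip(block, 0, 2).astype(np.int64)
        new = rng.binomial(g, 1.0 - extra_error) + rng.binomial(2 - g, extra_error)
        values[:, idx] = np.where(observed, new.astype(np.int8), MISSING)
    return GenotypeMatrix(gm.variants, list(gm.sample_ids), gm.platform, values)
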