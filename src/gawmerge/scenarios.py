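"""Frozen study designs for the three validation experiments.

These are the synthetic analogues of the protocol's evaluation designs:
a technical comparison (same samples on both platforms, platform as
outcome), a filter-necessity experiment (differential artifacts with
the quality filters toggled), a type-I-error suite (independent null
cohorts), a signal-recovery suite (known causal variant, three studies
meta-analysed), and a phasing-quality benchmark.  Sizes are desk-scale:
hundreds of samples and a few thousand markers over several independent
chromosomes, with a dense LD map (switch 0.003 per 1-kb interval)
except where noted.  The engine's switch probability is matched to the
simulated map; the emission mismatch 0.004 with genotyping-error
component 0.0005 makes typed-site dosages track observed genotypes, as
production imputation engines do.
"""

from __future__ import annotations

import numpy as np

from .lshmm import LsParams
from .pipeline import PipelineConfig
from .qc import QcThresholds
from .simulate import SimConfig, TruthSet, array_manifest_indices

__all__ = [
    "engine_params",
    "technical_null_scenario",
    "filter_necessity_scenario",
    "choose_artifact_variants",
    "type1_scenario",
    "recovery_scenario",
    "phasing_scenario",
]


def engine_params(seed: int, switch: float = 0.003) -> LsParams:
    return LsParams(
        seed=seed, switch_prob=switch, mismatch_prob=0.004, genotype_error=0.0005
    )


def technical_null_scenario(seed: int) -> tuple[SimConfig, PipelineConfig]:
    """Same 500 samples through both platforms, 5000 markers, clean null."""
    sim = SimConfig(
        n_variants=5000,
        n_chromosomes=5,
        n_samples_array=500,
        n_samples_wgs=500,
        n_ref_haplotypes=120,
        seed=seed,
    )
    cfg = PipelineConfig(ls=engine_params(seed), qc=QcThresholds(pca_components=10))
    return sim, cfg


def filter_necessity_scenario(seed: int) -> tuple[SimConfig, PipelineConfig]:
    """400 samples on both platforms, 1500 markers; artifacts injected."""
    sim = SimConfig(
        n_variants=1500,
        n_chromosomes=5,
        n_samples_array=400,
        n_samples_wgs=400,
        n_ref_haplotypes=120,
        seed=seed,
    )
    cfg = PipelineConfig(ls=engine_params(seed), qc=QcThresholds(pca_components=10))
    return sim, cfg


def choose_artifact_variants(
    sim: SimConfig, truth: TruthSet, n: int = 20, maf_range=(0.15, 0.3), seed: int = 1
) -> np.ndarray:
    """Manifest variants (array-matrix indices) to corrupt.

    Mid-frequency sites are chosen: an allele-level flip moves their
    frequency measurably toward 0.5, while near-0.5 sites would shift
    nowhere and rare sites are uninformative.
    """
    man = array_manifest_indices(sim)
    freq = truth.genotypes()[:, man].mean(axis=0) / 2
    maf = np.minimum(freq, 1 - freq)
    candidates = np.flatnonzero((maf > maf_range[0]) & (maf < maf_range[1]))
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(candidates, size=n, replace=False))


def type1_scenario(seed: int) -> tuple[SimConfig, PipelineConfig]:
    """Independent null cohorts (250 array + 250 WGS), 500 markers."""
    sim = SimConfig(
        n_variants=500,
        n_chromosomes=5,
        n_samples_array=250,
        n_samples_wgs=250,
        n_ref_haplotypes=120,
        seed=seed,
    )
    cfg = PipelineConfig(ls=engine_params(seed), qc=QcThresholds(pca_components=5))
    return sim, cfg


def recovery_scenario(seed: int) -> tuple[SimConfig, PipelineConfig]:
    """Signal recovery: 250 markers over 6 chromosomes, causal variant
    placed mid-chromosome by the suite (OR 1.5, MAF 0.3).

    Two principal components are used here: the cohort has a single
    ancestry, and with few independent chromosomes additional PCs stop
    modelling structure and start absorbing per-chromosome haplotype
    axes -- including the causal variant's own LD block, a desk-scale
    artifact that genome-wide data does not show.
    """
    sim = SimConfig(
        n_variants=250,
        n_chromosomes=6,
        n_ref_haplotypes=200,
        array_variant_fraction=0.6,
        seed=seed,
    )
    cfg = PipelineConfig(ls=engine_params(seed), qc=QcThresholds(pca_components=2))
    return sim, cfg


def phasing_scenario(seed: int) -> tuple[SimConfig, LsParams]:
    """High-LD phasing benchmark: 500 markers, 200 samples, switch 0.005."""
    sim = SimConfig(
        n_variants=500,
        n_samples_array=200,
        n_samples_wgs=0,
        n_ref_haplotypes=100,
        founder_switch_prob=0.005,
        array_variant_fraction=1.0,
        array_error_rate=0.0,
        array_missing_rate=0.0,
        seed=seed,
    )
    return sim, engine_params(seed, switch=0.005)
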