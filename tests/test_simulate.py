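"""Mosaic cohort simulator: LD structure, phenotype model, platforms."""

import numpy as np
import pytest

from gawmerge.datatypes import ConfigError, MISSING
from gawmerge.qc import hwe_exact_test, pca_genotypes
from gawmerge.simulate import (
    SimConfig,
    array_manifest_indices,
    emulate_platform,
    inject_differential_artifact,
    simulate_reference_panel,
    simulate_study_cohort,
)


def adjacent_r2(haps: np.ndarray, lag: int = 1) -> float:
    """Mean squared correlation between allele columns `lag` apart."""
    x = haps.astype(float)
    keep = x.std(axis=0) > 0
    r2 = []
    for j in range(x.shape[1] - lag):
        if keep[j] and keep[j + lag]:
            r = np.corrcoef(x[:, j], x[:, j + lag])[0, 1]
            r2.append(r * r)
    return float(np.mean(r2))


def test_identical_config_gives_bit_identical_outputs():
    cfg = SimConfig(n_variants=200, n_ref_haplotypes=40, seed=7)
    p1, t1, g1 = simulate_reference_panel(cfg)
    p2, t2, g2 = simulate_reference_panel(cfg)
    assert np.array_equal(p1.haplotypes, p2.haplotypes)
    c1 = simulate_study_cohort(p1, cfg, n_samples=30)
    c2 = simulate_study_cohort(p2, cfg, n_samples=30)
    assert np.array_equal(c1.diplotypes, c2.diplotypes)
    assert np.array_equal(c1.phenotype, c2.phenotype)
    m1 = emulate_platform(c1, "array", cfg)
    m2 = emulate_platform(c2, "array", cfg)
    assert np.array_equal(m1.values, m2.values)


def test_degenerate_mosaic_copies_founders_exactly():
    """No switching, no mutation: every panel haplotype is one founder."""
    cfg = SimConfig(
        n_founders=4,
        n_ref_haplotypes=40,
        n_variants=150,
        founder_switch_prob=0.0,
        founder_mutation_prob=0.0,
        seed=2,
    )
    panel, _, _ = simulate_reference_panel(cfg)
    distinct = {tuple(h) for h in panel.haplotypes}
    assert len(distinct) <= cfg.n_founders


def test_full_mutation_noise_destroys_ld():
    cfg = SimConfig(
        n_founders=4,
        n_ref_haplotypes=200,
        n_variants=1200,
        founder_switch_prob=0.02,
        founder_mutation_prob=0.5,
        seed=3,
    )
    panel, _, _ = simulate_reference_panel(cfg)
    assert adjacent_r2(panel.haplotypes) < 0.02


def test_ld_decays_with_marker_distance():
    cfg = SimConfig(
        n_founders=4,
        n_ref_haplotypes=200,
        n_variants=2000,
        founder_switch_prob=0.02,
        founder_mutation_prob=0.001,
        seed=1,
    )
    panel, _, _ = simulate_reference_panel(cfg)
    assert adjacent_r2(panel.haplotypes, lag=1) > adjacent_r2(panel.haplotypes, lag=50)


def test_ld_nonincreasing_over_distance_bins():
    cfg = SimConfig(
        n_ref_haplotypes=200, n_variants=1500, founder_switch_prob=0.05, seed=5
    )
    panel, _, _ = simulate_reference_panel(cfg)
    means = [adjacent_r2(panel.haplotypes, lag) for lag in (1, 5, 20, 80)]
    assert all(a >= b - 0.01 for a, b in zip(means, means[1:]))


def test_null_phenotype_has_half_cases():
    cfg = SimConfig(n_variants=100, n_ref_haplotypes=60, phenotype_intercept=0.0, seed=4)
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=1000)
    frac = truth.phenotype.mean()
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 1000)


def test_causal_variant_enriched_in_cases():
    cfg = SimConfig(
        n_variants=100,
        n_ref_haplotypes=60,
        causal_effects={50: float(np.log(2.0))},
        founder_freq_overrides={50: 0.3},
        seed=4,
    )
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=1000)
    g = truth.genotypes()[:, 50]
    f_case = g[truth.phenotype == 1].mean() / 2
    f_ctrl = g[truth.phenotype == 0].mean() / 2
    n1 = (truth.phenotype == 1).sum()
    n0 = (truth.phenotype == 0).sum()
    pool = g.mean() / 2
    se = np.sqrt(pool * (1 - pool) * (1 / (2 * n1) + 1 / (2 * n0)))
    z = (f_case - f_ctrl) / se
    from scipy.stats import norm

    assert norm.sf(z) < 0.01  # one-sided


def test_extreme_negative_intercept_gives_no_cases():
    cfg = SimConfig(n_variants=50, n_ref_haplotypes=40, phenotype_intercept=-10.0, seed=6)
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=500)
    assert truth.phenotype.sum() <= 2


def test_errorless_platform_is_identity():
    cfg = SimConfig(
        n_variants=120,
        n_ref_haplotypes=40,
        array_variant_fraction=1.0,
        array_error_rate=0.0,
        array_missing_rate=0.0,
        seed=8,
    )
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=40)
    gm = emulate_platform(truth, "array", cfg)
    assert np.array_equal(gm.values, truth.genotypes())


def test_total_missingness():
    cfg = SimConfig(
        n_variants=60, n_ref_haplotypes=40, wgs_missing_rate=1.0, seed=8
    )
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=20)
    gm = emulate_platform(truth, "wgs", cfg)
    assert (gm.values == MISSING).all()


def test_platform_error_rate_calibrated():
    cfg = SimConfig(
        n_variants=2000,
        n_ref_haplotypes=60,
        wgs_error_rate=0.01,
        wgs_missing_rate=0.0,
        seed=9,
    )
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=500)
    gm = emulate_platform(truth, "wgs", cfg)
    disc = (gm.values != truth.genotypes()).mean()
    n = gm.values.size
    assert abs(disc - 0.01) < 3 * np.sqrt(0.01 * 0.99 / n)


def test_array_manifest_is_seeded_subset():
    cfg = SimConfig(n_variants=400, n_ref_haplotypes=40, array_variant_fraction=0.5, seed=1)
    man = array_manifest_indices(cfg)
    assert len(man) == 200
    assert np.array_equal(man, array_manifest_indices(cfg))
    assert np.array_equal(man, np.sort(man))


@pytest.mark.parametrize("extra", [0.0, 0.3])
def test_artifact_injection_shifts_frequency_only_when_nonzero(extra):
    cfg = SimConfig(n_variants=300, n_ref_haplotypes=60, seed=10)
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=300)
    gm = emulate_platform(truth, "wgs", cfg)
    out = inject_differential_artifact(gm, [10, 20, 30], extra, seed=5)
    if extra == 0.0:
        assert np.array_equal(out.values, gm.values)
    else:
        shift = np.abs(
            out.alt_frequency()[[10, 20, 30]] - gm.alt_frequency()[[10, 20, 30]]
        )
        assert (shift > 0).all()
        untouched = np.delete(np.arange(300), [10, 20, 30])
        assert np.array_equal(out.values[:, untouched], gm.values[:, untouched])
        out2 = inject_differential_artifact(gm, [10, 20, 30], extra, seed=5)
        assert np.array_equal(out.values, out2.values)


def test_artifact_injection_empty_list_and_bad_index():
    cfg = SimConfig(n_variants=50, n_ref_haplotypes=40, seed=10)
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=20)
    gm = emulate_platform(truth, "wgs", cfg)
    out = inject_differential_artifact(gm, [], 0.5, seed=1)
    assert np.array_equal(out.values, gm.values)
    with pytest.raises(ConfigError):
        inject_differential_artifact(gm, [50], 0.5, seed=1)


def test_hardy_weinberg_holds_without_selection():
    """Single ancestry, no phenotype selection: >=99% of variants pass HWE."""
    cfg = SimConfig(n_variants=500, n_ref_haplotypes=200, seed=12)
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=1000)
    g = truth.genotypes()
    n_pass = 0
    tested = 0
    for j in range(g.shape[1]):
        col = g[:, j]
        p = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
        tested += 1
        if p > 1e-4:
            n_pass += 1
    assert n_pass / tested >= 0.99


def test_two_ancestry_groups_separate_on_pc1():
    cfg = SimConfig(
        n_variants=400,
        n_ref_haplotypes=120,
        ancestry_groups=2,
        ancestry_freq_shift=0.2,
        seed=13,
    )
    panel, _, groups = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=200, panel_groups=groups)
    scores = pca_genotypes(truth.genotypes(), n_components=2)
    pc1 = scores[:, 0]
    g0, g1 = pc1[truth.ancestry == 0], pc1[truth.ancestry == 1]
    within = 0.5 * (g0.std() + g1.std())
    assert abs(g0.mean() - g1.mean()) > 5 * within


def test_config_validation_names_field():
    with pytest.raises(ConfigError, match="array_variant_fraction"):
        SimConfig(array_variant_fraction=0.0)
    with pytest.raises(ConfigError, match="n_founders"):
        SimConfig(n_founders=1)
    with pytest.raises(ConfigError, match="causal"):
        SimConfig(n_variants=10, causal_effects={10: 0.5})
    with pytest.raises(ConfigError, match="error_rate"):
        SimConfig(array_error_rate=1.5)
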