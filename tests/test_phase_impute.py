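"""Phasing contract, imputation accuracy, R2/ER2, and the two-round
ER2-filtered imputation."""

import dataclasses

import numpy as np
import pytest

from gawmerge.datatypes import (
    ConfigError,
    GenotypeMatrix,
    HaplotypePanel,
    VariantTable,
)
from gawmerge.impute import (
    compute_er2,
    compute_r2,
    impute_to_reference,
    two_round_impute,
    _er2_for_typed,
)
from gawmerge.lshmm import LsParams
from gawmerge.phase import phase_cohort, switch_error_rate
from gawmerge.simulate import (
    SimConfig,
    array_manifest_indices,
    emulate_platform,
    inject_differential_artifact,
    simulate_reference_panel,
    simulate_study_cohort,
)

PARAMS = LsParams(seed=1, switch_prob=0.003, mismatch_prob=0.004, genotype_error=0.0005)


def small_world(seed=51, n_variants=200, n_samples=60, **over):
    cfg = SimConfig(
        n_variants=n_variants, n_ref_haplotypes=80,
        array_error_rate=0.0, array_missing_rate=0.0,
        wgs_error_rate=0.0, wgs_missing_rate=0.0,
        seed=seed, **over,
    )
    panel, table, groups = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=n_samples, panel_groups=groups)
    return cfg, panel, table, truth


def truth_panel(truth, table, cols=None, platform="wgs"):
    haps = truth.diplotypes if cols is None else truth.diplotypes[:, cols]
    t = table if cols is None else table.subset(cols)
    return HaplotypePanel(
        t,
        list(truth.sample_ids),
        np.array([platform] * truth.n_samples, dtype=object),
        haps,
    )


# -- phasing ---------------------------------------------------------------

def test_phasing_consistency_and_determinism():
    cfg, panel, table, truth = small_world()
    gm = emulate_platform(truth, "wgs", cfg)
    ph1 = phase_cohort(gm, PARAMS)
    ph2 = phase_cohort(gm, PARAMS)
    assert np.array_equal(ph1.haplotypes, ph2.haplotypes)
    g = gm.values
    np.testing.assert_array_equal(ph1.genotypes()[g >= 0], g[g >= 0])


def test_sample_without_heterozygotes_has_unique_phase():
    cfg, panel, table, truth = small_world(n_samples=40)
    gm = emulate_platform(truth, "wgs", cfg)
    forced = gm.values.copy()
    forced[0] = np.where(forced[0] == 1, 0, forced[0])  # kill sample 0's hets
    gm = GenotypeMatrix(gm.variants, gm.sample_ids, gm.platform, forced)
    for seed in (1, 2):
        ph = phase_cohort(gm, dataclasses.replace(PARAMS, seed=seed))
        assert np.array_equal(ph.haplotypes[0], ph.haplotypes[1])
        assert np.array_equal(ph.haplotypes[0] * 2, forced[0].astype(np.uint8) )


def test_phasing_reduces_conditioning_panel_with_warning():
    cfg, panel, table, truth = small_world(n_samples=6)
    gm = emulate_platform(truth, "wgs", cfg)
    with pytest.warns(UserWarning, match="reduced"):
        phase_cohort(gm, dataclasses.replace(PARAMS, conditioning_haplotypes=40))


def test_phasing_single_sample_rejected():
    cfg, panel, table, truth = small_world(n_samples=12)
    gm = emulate_platform(truth, "wgs", cfg).subset_samples(np.array([0]))
    with pytest.raises(ConfigError):
        phase_cohort(gm, PARAMS)


def test_switch_error_low_on_moderate_scenario():
    cfg, panel, table, truth = small_world(
        seed=52, n_variants=300, n_samples=100, founder_switch_prob=0.005
    )
    gm = emulate_platform(truth, "wgs", cfg)
    ph = phase_cohort(gm, dataclasses.replace(PARAMS, switch_prob=0.005), reference=panel)
    assert switch_error_rate(ph, truth.diplotypes) < 0.05


# -- imputation ------------------------------------------------------------

def test_exact_copy_study_recovers_untyped_sites():
    cfg, panel, table, truth = small_world(seed=53, n_variants=150, n_samples=30)
    man = array_manifest_indices(cfg)
    study = truth_panel(truth, table, man)
    pure = LsParams(seed=1, switch_prob=0.003, mismatch_prob=1e-4, genotype_error=1e-4)
    res = impute_to_reference(study, panel, pure)
    untyped = np.setdiff1d(np.arange(cfg.n_variants), man)
    td = truth.genotypes()[:, untyped].astype(float)
    dd = res.dosages.dosages[:, untyped]
    assert np.abs(dd - td).mean() < 0.05


def test_monomorphic_reference_site_imputes_to_two():
    table = VariantTable.from_arrays(["1"] * 4, [10, 20, 30, 40], ["A"] * 4, ["G"] * 4)
    ref = np.array(
        [[1, 0, 1, 1], [1, 1, 1, 0], [1, 0, 1, 1], [1, 1, 1, 0]], dtype=np.uint8
    )  # site 0 and 2 monomorphic ALT
    reference = HaplotypePanel(
        table, ["R0", "R1"], np.array(["wgs"] * 2, dtype=object), ref
    )
    study = HaplotypePanel(
        table.subset(np.array([1, 3])),
        ["S0"],
        np.array(["wgs"], dtype=object),
        np.array([[0, 1], [1, 0]], dtype=np.uint8),
    )
    pure = LsParams(switch_prob=0.01, mismatch_prob=1e-4, genotype_error=1e-4)
    res = impute_to_reference(study, reference, pure)
    assert res.dosages.dosages[0, 0] == pytest.approx(2.0, abs=1e-6)
    assert res.dosages.dosages[0, 2] == pytest.approx(2.0, abs=1e-6)


def test_dosage_bounds():
    cfg, panel, table, truth = small_world(seed=54, n_variants=100, n_samples=20)
    man = array_manifest_indices(cfg)
    res = impute_to_reference(truth_panel(truth, table, man), panel, PARAMS)
    d = res.dosages.dosages
    assert d.min() >= 0.0 and d.max() <= 2.0


def test_study_variant_absent_from_reference_rejected():
    cfg, panel, table, truth = small_world(seed=55, n_variants=50, n_samples=10)
    other = VariantTable.from_arrays(["2"], [999], ["A"], ["G"])
    study = HaplotypePanel(
        other, ["S0"], np.array(["wgs"], dtype=object),
        np.zeros((2, 1), dtype=np.uint8),
    )
    with pytest.raises(ConfigError, match="absent"):
        impute_to_reference(study, panel, PARAMS)


def test_monotone_accuracy_in_reference_panel_size():
    """Masked-site dosage error is non-increasing as the panel grows."""
    sizes = [10, 50, 200]
    errors = {s: [] for s in sizes}
    for seed in range(20):
        cfg = SimConfig(
            n_variants=100, n_ref_haplotypes=200,
            array_error_rate=0, array_missing_rate=0,
            wgs_error_rate=0, wgs_missing_rate=0, seed=600 + seed,
        )
        panel, table, _ = simulate_reference_panel(cfg)
        truth = simulate_study_cohort(panel, cfg, n_samples=10)
        man = array_manifest_indices(cfg)
        untyped = np.setdiff1d(np.arange(cfg.n_variants), man)
        td = truth.genotypes()[:, untyped].astype(float)
        for s in sizes:
            sub = HaplotypePanel(
                table,
                panel.sample_ids[: s // 2],
                panel.platform[: s // 2],
                panel.haplotypes[:s],
            )
            res = impute_to_reference(truth_panel(truth, table, man), sub, PARAMS)
            errors[s].append(((res.dosages.dosages[:, untyped] - td) ** 2).mean())
    means = [np.mean(errors[s]) for s in sizes]
    assert means[0] >= means[1] >= means[2]


# -- R2 / ER2 --------------------------------------------------------------

def test_r2_hwe_hard_calls_is_one():
    d = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
    assert compute_r2(d) == pytest.approx(1.0)


def test_r2_constant_dosage_is_zero():
    assert compute_r2(np.full(50, 1.3)) == 0.0
    assert compute_r2(np.full(50, 2.0)) == 0.0  # p=1 edge


def test_r2_shrunk_dosages():
    g = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
    d = 1 + 0.5 * (g - 1)
    assert compute_r2(d) == pytest.approx(0.25)


def test_er2_identity_and_degenerate_cases():
    g = np.array([0, 1, 2, 1, 0])
    assert compute_er2(g, g.astype(float)) == pytest.approx(1.0)
    assert compute_er2(g, np.full(5, 0.7)) == 0.0
    assert compute_er2(np.array([1, 1, -1]), np.array([0.5, 0.9, 0.1])) == 0.0


def test_er2_matches_pearson_oracle():
    g = np.array([0, 1, 2, 1])
    d = np.array([0.1, 0.9, 1.8, 1.2])
    expected = np.corrcoef(g.astype(float), d)[0, 1] ** 2
    assert compute_er2(g, d) == pytest.approx(expected, abs=1e-12)


def test_er2_calibration_decreases_with_injected_error():
    """Mean ER2 at a corrupted variant falls monotonically in error rate."""
    cfg, panel, table, truth = small_world(seed=57, n_variants=200, n_samples=80)
    man = array_manifest_indices(cfg)
    gm = emulate_platform(truth, "wgs", cfg).subset_variants(man)
    target = 40  # column index within the manifest subset
    means = []
    for err in (0.0, 0.1, 0.2, 0.4):
        er2s = []
        for rep in range(3):
            noisy = inject_differential_artifact(gm, [target], err, seed=rep)
            ph = phase_cohort(noisy, PARAMS, reference=panel.subset_variants(man))
            res = impute_to_reference(ph, panel, PARAMS)
            er2s.append(_er2_for_typed(res, noisy)[target])
        means.append(np.mean(er2s))
    assert all(a > b for a, b in zip(means, means[1:]))


# -- two-round imputation --------------------------------------------------

def run_two_round(cfg, panel, truth, er2_threshold=0.9, inject=None, **kw):
    man = array_manifest_indices(cfg)
    gm = emulate_platform(truth, "wgs", cfg).subset_variants(man)
    if inject is not None:
        gm = inject_differential_artifact(gm, [inject], 0.4, seed=9)
    ph = phase_cohort(gm, PARAMS, reference=panel.subset_variants(man))
    return gm, two_round_impute(ph, gm, panel, PARAMS, er2_threshold=er2_threshold, **kw)


def test_two_round_zero_error_keeps_nearly_all_variants():
    cfg, panel, table, truth = small_world(seed=58, n_variants=300, n_samples=100)
    gm, (dm, qc, dropped) = run_two_round(cfg, panel, truth)
    n_typed = len(qc.rounds[1]["er2"])
    assert 1 - len(dropped) / n_typed >= 0.95


def test_two_round_drops_heavily_corrupted_variant():
    cfg, panel, table, truth = small_world(seed=59, n_variants=200, n_samples=100)
    man = array_manifest_indices(cfg)
    freq = truth.genotypes()[:, man].mean(0) / 2
    target = int(np.argmin(np.abs(freq - 0.5)))
    gm, (dm, qc, dropped) = run_two_round(cfg, panel, truth, inject=target)
    key = gm.variants.keys[target]
    assert qc.rounds[1]["er2"][target] < 0.9
    assert key in dropped
    # the dropped variant is no longer genotyped in round 2
    j_ref = [i for i, k in enumerate(dm.variants.keys) if k == key][0]
    assert not dm.genotyped[j_ref]


def test_two_round_threshold_zero_is_identity():
    cfg, panel, table, truth = small_world(seed=60, n_variants=120, n_samples=50)
    gm, (dm, qc, dropped) = run_two_round(cfg, panel, truth, er2_threshold=0.0)
    assert dropped == []
    np.testing.assert_array_equal(qc.rounds[1]["er2"], qc.rounds[2]["er2"])


def test_two_round_reimpute_only_skips_rephasing():
    cfg, panel, table, truth = small_world(seed=61, n_variants=150, n_samples=60)
    man = array_manifest_indices(cfg)
    freq = truth.genotypes()[:, man].mean(0) / 2
    target = int(np.argmin(np.abs(freq - 0.5)))
    gm, (dm, qc, dropped) = run_two_round(
        cfg, panel, truth, inject=target, reimpute_only=True
    )
    assert gm.variants.keys[target] in dropped


def test_two_round_all_dropped_is_error():
    cfg, panel, table, truth = small_world(seed=62, n_variants=80, n_samples=40)
    man = array_manifest_indices(cfg)
    gm = emulate_platform(truth, "wgs", cfg).subset_variants(man)
    ph = phase_cohort(gm, PARAMS, reference=panel.subset_variants(man))
    with pytest.raises(ConfigError, match="ER2"):
        two_round_impute(ph, gm, panel, PARAMS, er2_threshold=1.01)


def test_imputation_deterministic_across_runs():
    cfg, panel, table, truth = small_world(seed=63, n_variants=100, n_samples=30)
    man = array_manifest_indices(cfg)
    study = truth_panel(truth, table, man)
    r1 = impute_to_reference(study, panel, PARAMS)
    r2 = impute_to_reference(study, panel, PARAMS)
    np.testing.assert_allclose(r1.dosages.dosages, r2.dosages.dosages, atol=1e-12)
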