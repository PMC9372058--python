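"""QC filters: missingness, HWE exact test, sex check, flags, PCA,
ancestry matching, and idempotence of the whole stage."""

import numpy as np
import pytest

from gawmerge.datatypes import ConfigError, GenotypeMatrix, MISSING, VariantTable
from gawmerge.qc import (
    QcReport,
    QcThresholds,
    ancestry_match,
    drop_flagged_variants,
    filter_sample_missingness,
    filter_variant_missingness,
    hwe_exact_test,
    pca_genotypes,
    run_qc,
    sex_check,
)
from gawmerge.simulate import SimConfig, simulate_reference_panel, simulate_study_cohort

from oracles import hwe_exact_p_bruteforce


def make_gm(values, chrom="1"):
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    table = VariantTable.from_arrays(
        [chrom] * m, list(range(100, 100 + m)), ["A"] * m, ["G"] * m
    )
    return GenotypeMatrix(
        table,
        [f"S{i}" for i in range(n)],
        np.array(["wgs"] * n, dtype=object),
        values,
    )


# -- missingness -----------------------------------------------------------

def test_sample_missingness_strict_boundary():
    vals = np.zeros((3, 100), dtype=np.int8)
    vals[0, :4] = MISSING  # 4% -> excluded
    vals[1, :3] = MISSING  # exactly 3% -> retained
    vals[2, :] = MISSING  # all missing -> excluded
    rep = QcReport()
    bad = filter_sample_missingness(make_gm(vals), 0.03, rep)
    assert bad.tolist() == [0, 2]
    assert rep.excluded_samples == {"S0": "SAMPLE_MISSINGNESS", "S2": "SAMPLE_MISSINGNESS"}


def test_variant_missingness_recomputed_after_sample_exclusion():
    """Hand-derived 5x5 toy: missingness changes once a bad sample leaves."""
    vals = np.zeros((5, 5), dtype=np.int8)
    vals[0, :] = MISSING  # sample 0: all missing
    vals[1, 1] = MISSING  # variant 1 missing in sample 1 only
    gm = make_gm(vals)
    # before sample exclusion: variant 1 missing in 2/5 = 40%
    assert filter_variant_missingness(gm, 0.03).tolist() == list(range(5))
    # after dropping sample 0: variants 0,2,3,4 fully observed; variant 1 at 25%
    gm2 = gm.subset_samples(np.array([1, 2, 3, 4]))
    assert filter_variant_missingness(gm2, 0.03).tolist() == [1]
    assert filter_variant_missingness(gm2, 0.30).tolist() == []


# -- Hardy-Weinberg --------------------------------------------------------

def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(50, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 17) == 1.0


def test_hwe_all_heterozygote_extreme():
    assert hwe_exact_test(0, 100, 0) < 1e-4


def test_hwe_matches_bruteforce_oracle_examples():
    for counts in [(5, 10, 5), (20, 10, 3), (1, 1, 1), (12, 0, 9), (7, 23, 4)]:
        expected = hwe_exact_p_bruteforce(*counts)
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)


def test_hwe_rejects_negative_counts():
    with pytest.raises(ConfigError):
        hwe_exact_test(-1, 2, 3)
    with pytest.raises(ConfigError):
        hwe_exact_test(0, 0, 0)


# -- sex check -------------------------------------------------------------

def test_sex_check_no_x_variants_is_noop():
    rep = QcReport()
    bad = sex_check(make_gm(np.zeros((3, 30))), np.array([1, 2, 1]), report=rep)
    assert bad.size == 0
    assert "SEX_CHECK_SKIPPED_NO_X" in rep.notes


def test_sex_check_het_rates():
    m = 40
    vals = np.zeros((3, m), dtype=np.int8)
    vals[0, :] = 0          # male, zero het -> retained
    vals[1, :12] = 1        # het rate 0.3
    vals[2, :12] = 1        # same data, reported male -> excluded
    gm = make_gm(vals, chrom="X")
    bad = sex_check(gm, np.array([1, 2, 1]))
    assert bad.tolist() == [2]


def test_sex_check_requires_min_informative_sites():
    vals = np.full((1, 10), 1, dtype=np.int8)  # het everywhere but only 10 sites
    gm = make_gm(vals, chrom="X")
    assert sex_check(gm, np.array([1]), min_sites=20).size == 0


# -- flagged variants ------------------------------------------------------

def test_flag_blocklist_exclusions():
    table = VariantTable.from_arrays(
        ["1"] * 3,
        [100, 200, 300],
        ["A"] * 3,
        ["G"] * 3,
        filter_flags=[{"PASS"}, {"SVM"}, {"EXHET"}],
    )
    rep = QcReport()
    bad = drop_flagged_variants(table, report=rep)
    assert bad.tolist() == [1, 2]
    keys = table.keys
    assert rep.excluded_variants[keys[1]] == "FLAG:SVM"
    assert rep.excluded_variants[keys[2]] == "FLAG:EXHET"


# -- PCA -------------------------------------------------------------------

def test_pca_separates_simulated_ancestry_groups():
    cfg = SimConfig(
        n_variants=400, n_ref_haplotypes=120, ancestry_groups=2,
        ancestry_freq_shift=0.2, seed=31,
    )
    panel, _, groups = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=200, panel_groups=groups)
    scores = pca_genotypes(truth.genotypes(), n_components=4)
    label = truth.ancestry.astype(float)
    r = np.corrcoef(scores[:, 0], label)[0, 1]
    assert abs(r) > 0.9


def test_pca_no_structure_in_single_ancestry():
    cfg = SimConfig(n_variants=400, n_ref_haplotypes=120, seed=32)
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=500)
    scores = pca_genotypes(truth.genotypes(), n_components=4)
    rng = np.random.default_rng(0)
    label = rng.integers(0, 2, 500).astype(float)
    for k in range(scores.shape[1]):
        assert abs(np.corrcoef(scores[:, k], label)[0, 1]) < 0.2


def test_pca_duplicated_samples_get_identical_scores():
    cfg = SimConfig(n_variants=200, n_ref_haplotypes=60, seed=33)
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=40)
    g = truth.genotypes()
    doubled = np.vstack([g, g])
    scores = pca_genotypes(doubled, n_components=3)
    np.testing.assert_allclose(scores[:40], scores[40:], atol=1e-8)


def test_pca_requires_enough_variants():
    with pytest.raises(ConfigError):
        pca_genotypes(np.zeros((10, 4), dtype=np.int8), n_components=10, prune=False)


# -- ancestry matching -----------------------------------------------------

def _ref_scores(rng, center, n=30, spread=0.5):
    return center + spread * rng.standard_normal((n, 2))


def test_ancestry_match_declared_and_mismatched():
    rng = np.random.default_rng(1)
    ref = {"A": _ref_scores(rng, np.array([0.0, 0.0])),
           "B": _ref_scores(rng, np.array([10.0, 0.0]))}
    study = np.array([[0.2, -0.1], [9.8, 0.3]])
    declared = np.array(["A", "A"])
    assigned, excluded = ancestry_match(study, ref, declared)
    assert assigned.tolist() == ["A", "B"]
    assert excluded.tolist() == [1]


def test_ancestry_match_single_group_distance_outliers_only():
    rng = np.random.default_rng(2)
    ref = {"A": _ref_scores(rng, np.array([0.0, 0.0]))}
    study = np.array([[0.1, 0.1], [40.0, 40.0]])
    assigned, excluded = ancestry_match(study, ref, np.array(["A", "A"]))
    assert assigned.tolist() == ["A", "A"]
    assert excluded.tolist() == [1]


def test_ancestry_match_needs_three_reference_samples():
    with pytest.raises(ConfigError):
        ancestry_match(
            np.zeros((1, 2)), {"A": np.zeros((2, 2))}, np.array(["A"])
        )


# -- orchestration ---------------------------------------------------------

def test_run_qc_is_idempotent():
    cfg = SimConfig(
        n_variants=300, n_ref_haplotypes=80, wgs_missing_rate=0.02, seed=34
    )
    panel, _, _ = simulate_reference_panel(cfg)
    truth = simulate_study_cohort(panel, cfg, n_samples=120)
    from gawmerge.simulate import emulate_platform

    gm = emulate_platform(truth, "wgs", cfg)
    out1, rep1 = run_qc(gm, QcThresholds())
    out2, rep2 = run_qc(out1, QcThresholds())
    assert not rep2.excluded_samples and not rep2.excluded_variants
    assert np.array_equal(out1.values, out2.values)
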