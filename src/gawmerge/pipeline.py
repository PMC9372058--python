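"""End-to-end orchestration of the eight-step merging protocol, plus
the three validation experiments (technical comparison, type-I error,
signal recovery) run on simulated two-technology cohorts.

The pipeline is a pure function of (inputs, config, seed): manifests
record per-step sample/variant counts and content checksums, and
variant counts never increase from intersection to the final filtered
table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import qc as qc_mod
from .datatypes import ARRAY, WGS, ConfigError, GenotypeMatrix, HaplotypePanel
from .harmonize import intersect_variants, merge_phased, subset_to_matches
from .impute import two_round_impute
from .lshmm import LsParams
from .meta import combine_analyses
from .phase import phase_cohort
from .simulate import (
    SimConfig,
    TruthSet,
    emulate_platform,
    inject_differential_artifact,
    simulate_reference_panel,
    simulate_study_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_gawmerge",
    "run_technical_comparison",
    "run_type1_suite",
    "run_recovery_suite",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Protocol thresholds and switches (each printed constant is a key)."""

    er2_threshold: float = 0.9
    maf_min: float = 0.01
    r2_min: float = 0.8
    r2diff_max: float = 0.1
    gw_sig: float = 5e-8
    use_er2_filter: bool = True
    use_r2diff_filter: bool = True
    common_variant_phasing: bool = True
    reimpute_only: bool = False
    mode: str = "gwas"  # or "technical_comparison"
    qc: qc_mod.QcThresholds = field(default_factory=qc_mod.QcThresholds)
    ls: LsParams = field(default_factory=LsParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("gwas", "technical_comparison"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for name in ("er2_threshold", "maf_min", "r2_min", "r2diff_max", "gw_sig"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) and name != "gw_sig":
                raise ConfigError(f"{name} out of range")


@dataclass
class RunManifest:
    steps: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def record(self, step: str, **counts) -> None:
        self.steps.append({"step": step, **counts})

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "config": self.config,
            "wall_clock_s": self.wall_clock_s,
        }


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        if isinstance(a, pd.DataFrame):
            h.update(a.to_csv(index=False).encode())
        else:
            h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _config_snapshot(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["qc"]["flag_blocklist"] = sorted(d["qc"]["flag_blocklist"])
    return d


@dataclass
class PipelineResult:
    manifest: RunManifest
    assoc_table: pd.DataFrame  # with FILTER verdicts
    dosages: "object"  # DosageMatrix of round 2
    qc_reports: dict
    imputation_qc: "object"
    dropped_er2: list
    pc_scores: np.ndarray

    @property
    def passed(self) -> pd.DataFrame:
        return self.assoc_table[self.assoc_table["FILTER"] == "PASS"]


def run_gawmerge(
    array_gm: GenotypeMatrix,
    wgs_gm: GenotypeMatrix,
    phenotype: pd.Series | None,
    reference: HaplotypePanel,
    cfg: PipelineConfig,
    reported_sex: dict | None = None,
) -> PipelineResult:
    """Execute protocol steps 2-8 on prepared cohort matrices.

    ``phenotype`` maps sample_id -> 0/1 and is required in gwas mode;
    in technical_comparison mode the outcome is the platform label.
    """
    t0 = time.time()
    manifest = RunManifest(config=_config_snapshot(cfg))
    manifest.record(
        "input",
        array_samples=array_gm.n_samples,
        array_variants=array_gm.n_variants,
        wgs_samples=wgs_gm.n_samples,
        wgs_variants=wgs_gm.n_variants,
    )

    # step 2: intersect variant sets, re-orient array records to WGS
    matches, overlap_rate = intersect_variants(array_gm.variants, wgs_gm.variants)
    array_gm = subset_to_matches(array_gm, matches, "array", wgs_gm.variants)
    wgs_gm = subset_to_matches(wgs_gm, matches, "wgs", wgs_gm.variants)
    manifest.record(
        "intersect", common_variants=array_gm.n_variants, overlap_rate=overlap_rate
    )

    # step 3: identical, independent QC of the two cohorts
    sex_a = sex_w = None
    if reported_sex is not None:
        sex_a = np.array([reported_sex[s] for s in array_gm.sample_ids])
        sex_w = np.array([reported_sex[s] for s in wgs_gm.sample_ids])
    array_gm, rep_a = qc_mod.run_qc(array_gm, cfg.qc, sex_a)
    wgs_gm, rep_w = qc_mod.run_qc(wgs_gm, cfg.qc, sex_w)
    manifest.record(
        "qc",
        array_samples=array_gm.n_samples,
        array_variants=array_gm.n_variants,
        wgs_samples=wgs_gm.n_samples,
        wgs_variants=wgs_gm.n_variants,
    )

    # the protocol continues on variants that survived QC in both cohorts
    # and are present in the imputation reference
    ref_keys = {k: j for j, k in enumerate(reference.variants.keys)}
    keys_a = {k: j for j, k in enumerate(array_gm.variants.keys)}
    common = [k for k in wgs_gm.variants.keys if k in keys_a and k in ref_keys]
    idx_w = [j for j, k in enumerate(wgs_gm.variants.keys) if k in keys_a and k in ref_keys]
    idx_a = [keys_a[k] for k in common]
    array_common = array_gm.subset_variants(np.asarray(idx_a, dtype=int))
    wgs_common = wgs_gm.subset_variants(np.asarray(idx_w, dtype=int))
    manifest.record("common_post_qc", common_variants=len(common))
    if len(common) == 0:
        raise ConfigError("no variants survived QC in both cohorts")

    # step 4: phase both cohorts with the same engine and parameters,
    # conditioning on the imputation reference restricted to the same sites
    ref_common = reference.subset_variants(
        np.asarray([ref_keys[k] for k in common], dtype=int)
    )
    if cfg.common_variant_phasing:
        panel_a = phase_cohort(array_common, cfg.ls, ref_common)
        panel_w = phase_cohort(wgs_common, cfg.ls, ref_common)
    else:
        # ablation: phase each cohort on its own full post-QC variant set
        panel_a_full = phase_cohort(array_gm, cfg.ls)
        panel_w_full = phase_cohort(wgs_gm, cfg.ls)
        panel_a = panel_a_full.subset_variants(np.asarray(idx_a, dtype=int))
        panel_w = panel_w_full.subset_variants(np.asarray(idx_w, dtype=int))

    # step 5: merge phased cohorts (array samples first)
    merged = merge_phased(panel_a, panel_w)
    observed = GenotypeMatrix(
        array_common.variants,
        list(array_common.sample_ids) + list(wgs_common.sample_ids),
        np.concatenate([array_common.platform, wgs_common.platform]),
        np.vstack([array_common.values, wgs_common.values]),
    )
    manifest.record("merge", samples=merged.n_samples, typed_variants=merged.n_variants)

    # steps 5-6: impute, ER2-filter genotyped variants, re-impute
    er2_threshold = cfg.er2_threshold if cfg.use_er2_filter else 0.0
    dosages, imp_qc, dropped = two_round_impute(
        merged,
        observed,
        reference,
        cfg.ls,
        er2_threshold=er2_threshold,
        reimpute_only=cfg.reimpute_only,
    )
    manifest.record(
        "impute",
        er2_dropped=len(dropped),
        imputed_variants=dosages.n_variants,
        genotyped_variants=int(dosages.genotyped.sum()),
    )

    # step 7: association with principal-component covariates
    pcs = qc_mod.pca_genotypes(
        observed,
        n_components=cfg.qc.pca_components,
        ld_prune_r2=cfg.qc.ld_prune_r2,
    )
    if cfg.mode == "technical_comparison":
        table = assoc_mod.platform_association_mode(dosages, pcs)
    else:
        if phenotype is None:
            raise ConfigError("gwas mode requires a phenotype series")
        y = np.asarray([phenotype[s] for s in dosages.sample_ids], dtype=float)
        table = assoc_mod.assoc_scan(dosages, y, pcs)
    manifest.record("assoc", tested_variants=len(table))

    # step 8: result filters
    r2diff_max = cfg.r2diff_max if cfg.use_r2diff_filter else np.inf
    table, counts = assoc_mod.apply_result_filters(
        table, maf_min=cfg.maf_min, r2_min=cfg.r2_min, r2diff_max=r2diff_max
    )
    manifest.record("filters", **{str(k): int(v) for k, v in counts.items()})
    manifest.record(
        "output",
        checksum=_checksum(dosages.dosages, table),
        pass_variants=int((table["FILTER"] == "PASS").sum()),
    )
    manifest.wall_clock_s = time.time() - t0
    return PipelineResult(
        manifest=manifest,
        assoc_table=table,
        dosages=dosages,
        qc_reports={"array": rep_a, "wgs": rep_w},
        imputation_qc=imp_qc,
        dropped_er2=dropped,
        pc_scores=pcs,
    )


def preflight_report(
    array_gm: GenotypeMatrix, wgs_gm: GenotypeMatrix, n_components: int = 2
) -> dict:
    """Control-selection pre-flight: do the cohorts overlap in PC space?

    Ancestry/covariate matching of public controls is a judgment call;
    this report warns (never blocks) when the cohorts' PC centroids are
    far apart relative to the within-cohort spread.
    """
    matches, _ = intersect_variants(array_gm.variants, wgs_gm.variants)
    a = subset_to_matches(array_gm, matches, "array", wgs_gm.variants)
    w = subset_to_matches(wgs_gm, matches, "wgs", wgs_gm.variants)
    merged = np.vstack([a.values, w.values])
    pcs = qc_mod.pca_genotypes(merged, n_components=n_components)
    na = a.n_samples
    ca, cw = pcs[:na].mean(axis=0), pcs[na:].mean(axis=0)
    spread = 0.5 * (pcs[:na].std(axis=0).mean() + pcs[na:].std(axis=0).mean())
    dist = float(np.linalg.norm(ca - cw))
    report = {
        "centroid_distance": dist,
        "within_cohort_spread": float(spread),
        "separation_ratio": dist / max(spread, 1e-12),
        "warning": bool(dist > 3 * spread),
    }
    if report["warning"]:
        logger.warning(
            "cohort PC centroids separated by %.2f (spread %.2f): control "
            "ancestry may not match cases", dist, spread
        )
    return report


# ---------------------------------------------------------------------------
# validation experiments
# ---------------------------------------------------------------------------

def _rep_seed(base: int, rep: int) -> int:
    return int(np.random.SeedSequence([base, rep]).generate_state(1)[0] % (2**31))


def run_technical_comparison(
    sim_cfg: SimConfig,
    cfg: PipelineConfig,
    truth: TruthSet | None = None,
    artifact_variants: np.ndarray | None = None,
    artifact_error: float = 0.0,
) -> dict:
    """Same samples through both platform emulators, platform as outcome.

    Optionally injects a differential artifact into the array matrix at
    the given (array-matrix) variant indices before QC.
    """
    panel, _, groups = simulate_reference_panel(sim_cfg)
    if truth is None:
        truth = simulate_study_cohort(
            panel, sim_cfg, n_samples=sim_cfg.n_samples_array, panel_groups=groups
        )
    array_gm = emulate_platform(truth, ARRAY, sim_cfg)
    wgs_gm = emulate_platform(truth, WGS, sim_cfg)
    if artifact_variants is not None and artifact_error > 0:
        array_gm = inject_differential_artifact(
            array_gm, artifact_variants, artifact_error, seed=_rep_seed(sim_cfg.seed, 77)
        )
    # same individuals appear on both platforms: disambiguate IDs
    array_gm = GenotypeMatrix(
        array_gm.variants,
        [f"{s}_arr" for s in array_gm.sample_ids],
        array_gm.platform,
        array_gm.values,
    )
    wgs_gm = GenotypeMatrix(
        wgs_gm.variants,
        [f"{s}_wgs" for s in wgs_gm.sample_ids],
        wgs_gm.platform,
        wgs_gm.values,
    )
    cfg = dataclasses.replace(cfg, mode="technical_comparison")
    result = run_gawmerge(array_gm, wgs_gm, None, panel, cfg)
    passed = result.passed
    lam = (
        assoc_mod.genomic_lambda(passed["P"].to_numpy())
        if len(passed) >= 100
        else np.nan
    )
    return {
        "result": result,
        "n_tested": len(result.assoc_table),
        "n_pass": len(passed),
        "lambda": lam,
        "n_genome_wide": int((passed["P"] < cfg.gw_sig).sum()),
        "artifact_keys": (
            [array_gm.variants.keys[j] for j in artifact_variants]
            if artifact_variants is not None
            else []
        ),
    }


def run_type1_suite(
    sim_cfg: SimConfig,
    cfg: PipelineConfig,
    n_replicates: int = 20,
    alphas: tuple = (0.05, 1e-4, 5e-8),
) -> dict:
    """Repeated null pipelines: distinct array and WGS cohorts, no
    phenotype effect, cohort membership as the tested outcome."""
    rejections = {a: [] for a in alphas}
    lambdas = []
    gw_hits = []
    n_tests = []
    for rep in range(n_replicates):
        rep_cfg = dataclasses.replace(sim_cfg, seed=_rep_seed(sim_cfg.seed, rep))
        panel, _, groups = simulate_reference_panel(rep_cfg)
        truth = simulate_study_cohort(panel, rep_cfg, panel_groups=groups)
        n_arr = rep_cfg.n_samples_array
        truth_a = truth.subset_samples(np.arange(n_arr))
        truth_w = truth.subset_samples(np.arange(n_arr, truth.n_samples))
        array_gm = emulate_platform(truth_a, ARRAY, rep_cfg)
        wgs_gm = emulate_platform(truth_w, WGS, rep_cfg)
        rep_pipe_cfg = dataclasses.replace(
            cfg,
            mode="technical_comparison",
            ls=dataclasses.replace(cfg.ls, seed=_rep_seed(cfg.ls.seed, rep)),
        )
        result = run_gawmerge(array_gm, wgs_gm, None, panel, rep_pipe_cfg)
        p = result.passed["P"].to_numpy()
        for a in alphas:
            rejections[a].append(float((p < a).mean()) if p.size else np.nan)
        gw_hits.append(int((p < cfg.gw_sig).sum()))
        n_tests.append(p.size)
        if p.size >= 100:
            lambdas.append(assoc_mod.genomic_lambda(p))
    total = int(np.sum(n_tests))
    out = {
        "n_replicates": n_replicates,
        "n_tests_total": total,
        "rejection_rates": {a: float(np.nanmean(rejections[a])) for a in alphas},
        "per_replicate_rejection": {a: rejections[a] for a in alphas},
        "binomial_se_05": float(np.sqrt(0.05 * 0.95 / max(total, 1))),
        "genome_wide_hits_per_replicate": gw_hits,
        "lambdas": lambdas,
        "lambda_mean": float(np.mean(lambdas)) if lambdas else np.nan,
    }
    return out


def run_recovery_suite(
    sim_cfg: SimConfig,
    cfg: PipelineConfig,
    n_replicates: int = 50,
    n_studies: int = 3,
    n_cases: int = 334,
    n_controls: int = 334,
    detect_p: float = 1e-4,
    causal_or: float = 1.5,
    causal_maf: float = 0.3,
) -> dict:
    """Known-hit recovery: per replicate, several case/control GWAS
    (cases on the array platform, controls on WGS) are meta-analysed
    and the causal variant's detection, direction, and meta-vs-single
    p-values are recorded.

    The causal variant (per-allele OR ``causal_or`` at frequency
    ``causal_maf``) is placed mid-manifest, emulating a known GWAS hit
    targeted by the array design.
    """
    beta = float(np.log(causal_or))
    true_sign = np.sign(beta)

    detected = []
    direction_ok = []
    meta_beats_all = []
    meta_ps = []
    for rep in range(n_replicates):
        rep_cfg = dataclasses.replace(sim_cfg, seed=_rep_seed(sim_cfg.seed, 500 + rep))
        from .simulate import array_manifest_indices, chromosome_assignment

        manifest = array_manifest_indices(rep_cfg)
        # mid-chromosome placement: a known GWAS hit sits inside well
        # covered LD, not at a coverage edge
        chrom_idx, _ = chromosome_assignment(rep_cfg)
        on_first = manifest[chrom_idx[manifest] == 0]
        causal_idx = int(on_first[len(on_first) // 2])
        rep_cfg = dataclasses.replace(
            rep_cfg,
            causal_effects={causal_idx: beta},
            founder_freq_overrides={causal_idx: causal_maf},
        )
        panel, _, groups = simulate_reference_panel(rep_cfg)
        causal_key = panel.variants.keys[causal_idx]
        tables = []
        study_ps = []
        for s in range(n_studies):
            pool = simulate_study_cohort(
                panel,
                rep_cfg,
                n_samples=int(2.8 * max(n_cases, n_controls)),
                panel_groups=groups,
                id_prefix=f"R{rep}S{s}_",
                stream=s,
            )
            cases = np.flatnonzero(pool.phenotype == 1)[:n_cases]
            controls = np.flatnonzero(pool.phenotype == 0)[:n_controls]
            if len(cases) < n_cases or len(controls) < n_controls:
                raise ConfigError("simulated pool too small for requested study size")
            truth_a = pool.subset_samples(cases)
            truth_w = pool.subset_samples(controls)
            array_gm = emulate_platform(truth_a, ARRAY, rep_cfg, stream=2 * s)
            wgs_gm = emulate_platform(truth_w, WGS, rep_cfg, stream=2 * s + 1)
            pheno = pd.Series(
                {**{sid: 1 for sid in array_gm.sample_ids},
                 **{sid: 0 for sid in wgs_gm.sample_ids}}
            )
            study_cfg = dataclasses.replace(
                cfg,
                ls=dataclasses.replace(cfg.ls, seed=_rep_seed(cfg.ls.seed, 97 * rep + s)),
            )
            result = run_gawmerge(array_gm, wgs_gm, pheno, panel, study_cfg)
            tables.append(result.assoc_table)
            hit = result.assoc_table[
                (result.assoc_table["CHROM"] == causal_key[0])
                & (result.assoc_table["POS"] == causal_key[1])
                & (result.assoc_table["FILTER"] == "PASS")
            ]
            study_ps.append(float(hit["P"].iloc[0]) if len(hit) else np.nan)
        meta_table = combine_analyses(tables)
        mrow = meta_table[
            (meta_table["CHROM"] == causal_key[0]) & (meta_table["POS"] == causal_key[1])
        ]
        if len(mrow):
            mp = float(mrow["P"].iloc[0])
            mbeta = float(mrow["BETA"].iloc[0])
            detected.append(mp < detect_p)
            if mp < detect_p:
                direction_ok.append(np.sign(mbeta) == true_sign)
            finite = [p for p in study_ps if np.isfinite(p)]
            meta_beats_all.append(bool(finite) and all(mp < p for p in finite))
            meta_ps.append(mp)
        else:
            detected.append(False)
            meta_beats_all.append(False)
            meta_ps.append(np.nan)
    return {
        "n_replicates": n_replicates,
        "detection_rate": float(np.mean(detected)),
        "direction_concordance": float(np.mean(direction_ok)) if direction_ok else np.nan,
        "meta_beats_singles_rate": float(np.mean(meta_beats_all)),
        "meta_p_values": meta_ps,
    }
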