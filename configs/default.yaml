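# Full default configuration for the gawmerge CLI.
# Every protocol threshold is a named key here; code contains no literals.

simulation:
  n_founders: 10
  n_ref_haplotypes: 200
  n_variants: 2000
  n_chromosomes: 1
  n_samples_array: 500
  n_samples_wgs: 500
  founder_switch_prob: 0.003      # per inter-marker interval
  founder_mutation_prob: 0.001    # per copied allele
  array_variant_fraction: 0.5     # manifest size relative to all variants
  array_error_rate: 0.002         # per-genotype uniform miscall
  wgs_error_rate: 0.001
  array_missing_rate: 0.002
  wgs_missing_rate: 0.001
  causal_effects: {}              # variant index -> log odds ratio per ALT allele
  phenotype_intercept: 0.0
  ancestry_groups: 1
  ancestry_freq_shift: 0.15
  seed: 0

pipeline:
  er2_threshold: 0.9              # drop genotyped variants with ER2 below this
  maf_min: 0.01                   # result filter: MAF strictly above
  r2_min: 0.8                     # result filter: imputation R2 strictly above
  r2diff_max: 0.1                 # |R2_array - R2_WGS| at or above this fails
  gw_sig: 5.0e-8                  # genome-wide significance (strict <)
  use_er2_filter: true
  use_r2diff_filter: true
  common_variant_phasing: true    # phase both cohorts on the common variant set
  reimpute_only: false            # true: round 2 re-imputes without re-phasing
  mode: gwas                      # or technical_comparison
  qc:
    sample_miss: 0.03             # samples with missingness strictly above are dropped
    variant_miss: 0.03
    hwe_p: 1.0e-4                 # HWE exact-test exclusion (strict <)
    sex_het_rate: 0.05            # X-heterozygosity threshold for the sex check
    sex_min_sites: 20
    pca_components: 10
    ld_prune_r2: 0.2
  ls:
    switch_prob: 0.01             # copying-state switch per interval
    mismatch_prob: 0.001          # total emission mismatch
    genotype_error: 0.0001        # genotyping-error component of the mismatch
    phasing_iterations: 10
    phasing_burnin: 5
    conditioning_haplotypes: 40
    seed: 0
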