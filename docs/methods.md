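# Methods

## The problem

A case-only cohort genotyped on a SNP array can be turned into a full
case/control GWAS by borrowing controls from a public whole-genome
sequencing (WGS) resource. Doing this naively produces false positives:
the two technologies observe different variant sets with different
error processes, and any systematic difference between them is
perfectly confounded with case/control status. `gawmerge` implements an
eight-step protocol that makes the two data sources comparable:

1. select a WGS control dataset;
2. extract from it the variants on the case cohort's array manifest
   (intersection by chromosome and position, alleles reconciled to the
   WGS orientation; strand-ambiguous A/T and C/G pairs dropped);
3. run identical, independent QC on both cohorts;
4. phase both cohorts on the common variant set with the same engine
   and parameters;
5. merge the phased panels and impute everything to a phased reference
   panel;
6. drop genotyped variants with leave-one-out empirical R² (ER²)
   below 0.9 and re-impute;
7. test per-variant association (logistic on dosage, principal
   components as covariates);
8. filter results on MAF > 0.01, imputation R² > 0.8, and
   |R²_array − R²_WGS| < 0.1 (a difference of 0.1 or more fails).

All thresholds use strict inequalities exactly as stated; boundary
values are retained.

## The haplotype-copying engine

Phasing and imputation both use a Li–Stephens copying model: the hidden
state at each site is the reference haplotype being copied; the state
is kept between adjacent sites with probability (1 − ρ) + ρ/H and
switches to each other state with probability ρ/H; the observed allele
matches the copied one with probability 1 − μ. The genetic map is
abstract — one interval between adjacent markers, constant ρ — and a
chromosome boundary is a free-recombination break (the state redraws
uniformly). Forward–backward recursions are scaled per site, so panels
of 10⁴+ markers do not underflow; the hot loops are numba-compiled.

**Emission split.** μ lumps two layers: *copy noise* ν (the study
haplotype genuinely deviating from its reference template) and
*genotyping error* ε, with μ = ν + ε − 2νε. The split does not affect
the recursions, only how posteriors become dosages:

* untyped site: dosage = ν + (1 − 2ν)·P(state allele = ALT | data);
* typed site: dosage = posterior of the *study* allele given both the
  copying context and the observed allele. With ε ≪ ν the observation
  dominates unless the context is overwhelmingly confident — matching
  production imputation engines, whose typed-site dosages track the
  input genotypes. This is what makes a systematically corrupted
  genotyped variant visible downstream (and catchable by ER²) rather
  than silently "repaired" by LD.

**ER².** For a genotyped variant, the site's emission factor is divided
out of the state posterior — algebraically identical to re-running with
the site untyped, because emissions factorise by site — and ER² is the
squared Pearson correlation between these leave-one-out dosages and the
observed genotypes. ER² is defined only at genotyped sites; zero
variance on either side gives ER² = 0.

**Phasing** is iterative haploid conditional refinement: heterozygote
phases start random; each sweep splits samples into two blocks, and
each sample decodes against a conditioning panel of K = 40 haplotypes
drawn from the *other* block's current estimates (no sample conditions
on itself), with homozygous sites typed and heterozygous/missing sites
untyped. Haplotype 1 takes the Viterbi path's alleles at heterozygous
sites — the coherent path keeps adjacent heterozygotes consistent,
where independent per-site posterior modes flicker and plateau at 6–10%
switch error — and haplotype 2 is the genotype complement, so
hap1 + hap2 equals the genotype at every observed site. When a phased
reference panel covering the same sites is available (it always is in
the pipeline, which reuses the step-5 imputation reference), its
haplotypes are prepended to every conditioning panel; conditioning only
on cohort estimates lets phase errors feed back and plateaus at ~5–7%
switch error, while the reference-conditioned decode reaches ~2%.

**Two-round imputation.** Round 1 imputes the merged panel and computes
ER² for every genotyped variant; variants below the threshold leave the
typed set; round 2 re-phases each platform cohort on the reduced set
(the conservative reading — the dropped variants participated in
phasing; `reimpute_only: true` restores re-imputation without
re-phasing) and re-imputes. When nothing is dropped, round 2 would
reproduce round 1 exactly (same typed set, same seeds), so round-1
results are returned directly.

## Association and meta-analysis

Per-variant logistic regression of phenotype (or platform, in the
technical-comparison mode) on dosage plus an intercept and principal
components, fitted by Newton–Raphson with step-halving; Wald p from
β/SE. Non-convergence, |β| > 15, or SE > 100 flags the record (p set
to 1) rather than correcting it; a Rao score test is available as an
alternative. PCs come from the merged post-QC genotyped matrix:
LD-pruned (greedy 50-marker window, step 5, r² > 0.2), columns centred
at 2p̂ and scaled by √(2p̂(1−p̂)), SVD scores with signs fixed by the
largest-magnitude loading.

Meta-analysis is fixed-effect inverse-variance on the log OR over PASS
records, with one direction character per study ("+", "−", or "?" when
the study lacks the variant — absent by design or removed by its
filters). A sample-size-weighted Z combination is available for
sensitivity.

## The cohort simulator

Haplotypes are founder mosaics: founders are drawn site-wise
Bernoulli(f), f ~ Uniform(0.05, 0.95); every site is forced to
segregate among founders (a fixed site is not a SNP; with 10 founders
~15% of sites would otherwise be fixed and spuriously monomorphic
downstream). Reference-panel haplotypes copy founders with a per-interval
switch probability and per-allele mutation probability; study
haplotypes copy the reference panel with the same process. Chromosomes
(up to 9) segregate independently. Simulated SNPs are never palindromic
(A/T, C/G), since real merging pipelines discard those as
strand-unresolvable. `founder_freq_overrides` pins a site to an *exact*
founder allele count — Bernoulli drift across 10 founders (sd ≈ 0.14)
would otherwise randomise a requested causal MAF.

The array platform observes a seeded random manifest subset of variants;
WGS observes all. Each genotype independently moves to a uniformly
chosen different value with the platform's error rate and is set
missing with its missingness rate. The differential-artifact injector
instead flips each *allele* independently with the extra error rate:
allele-level flips preserve Hardy–Weinberg exactly (so the damaged
variant passes QC and reaches the imputation stage, where the ER²
filter is the intended defence) while shifting the allele frequency
toward 0.5. The phenotype is Bernoulli(logistic(intercept + Σ βᵥgᵥ)).

What the simulator does *not* emulate: coalescent genealogy,
physical/genetic map heterogeneity, read-level sequencing error,
sex-linked inheritance (sex is an independent label; the sex check is
exercised on constructed X-chromosome fixtures), indels and
multiallelics, and realistic MAF spectra (frequencies concentrate away
from rare because founders are few). Passing tests therefore show that
the protocol's logic behaves as designed under its own assumptions, not
that it is robust to everything real platforms do.

## Validation experiments and their scales

The designs live in `gawmerge.scenarios` and are run by
`scripts/acceptance.py` and the test suite:

* **Technical comparison** — the same 500 samples through both platform
  emulators, 5000 markers on 5 chromosomes, platform as the outcome.
  Expected: no genome-wide hits. Note that this design is *paired*:
  each individual contributes an array row and a WGS row whose dosages
  differ only by platform/imputation noise, so the platform test is
  heavily deflated (λ ≪ 1) by construction — the quality filters
  themselves guarantee the within-pair dosage noise is far smaller than
  the between-individual genetic variance. λ near 1 is only meaningful
  in the independent-cohort design below.
* **Filter necessity** — 20 manifest variants with mid-range MAF get a
  0.3 allele-flip artifact on the array side only. With the ER² and
  R²-difference filters disabled, the artifacts reach genome-wide
  significance; with the filters on, they are removed.
* **Type-I error** — 20 replicates of independent null cohorts
  (250 array + 250 WGS, 500 markers); empirical rejection at α = 0.05,
  genome-wide hit count, and λ (≈ 1 here, as the null is exchangeable).
* **Signal recovery** — 50 replicates; each simulates three
  case/control studies (334 cases on array + 334 WGS controls apiece,
  ≈1000 + 1000 in total) sharing one causal variant (per-allele OR 1.5,
  MAF 0.3) placed mid-chromosome on the manifest, runs the full
  protocol per study, and meta-analyses the three. Reported: detection
  (meta p < 10⁻⁴), sign concordance among detections, and how often the
  meta p beats every single-study p. This scenario uses two PCs: the
  cohort is single-ancestry, and with only six independent chromosomes
  additional PCs stop modelling structure and start absorbing
  per-chromosome haplotype axes — including the causal variant's own LD
  block, a desk-scale artifact that genome-wide data does not show.
* **Phasing benchmark** — 500 markers, 200 samples, switch 0.005;
  switch-error rate against the simulated truth (< 5% contract,
  typically ~2%).

Scenario engine parameters: ρ matched to the simulated map
(0.003–0.005 per interval), μ = 0.004 with ε = 0.0005. Problem sizes
are chosen so the full validation battery completes in minutes on one
core; the statistical structure (LD, error rates, effect sizes) is what
carries the conclusions, not the absolute scale.

## Numerical choices and edge cases

* R² (dosage variance over 2p̂(1−p̂)) is capped at 1 and defined as 0
  for monomorphic estimated frequency; it needs ≥ 2 samples.
* HWE uses the stable mid-point recurrence over heterozygote counts;
  monomorphic tables give p = 1.
* Heterozygote ties in phasing resolve to hap1 = ALT; missing genotypes
  take the Viterbi allele on both haplotypes (missingness in practice
  ≤ 1%, the approximation is negligible).
* Fewer than K + 1 samples reduces the conditioning panel with a
  warning; a single sample cannot be phased.
* QC iterates sample/variant exclusions to a fixed point, making the
  stage idempotent (dropping a dense-missing variant can push a
  borderline sample over the 3% threshold, and vice versa).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration gives
  bit-identical output.

## Known limitations

* The engine is a faithful model, not a re-implementation of any
  production phasing/imputation tool; agreement contracts are
  statistical (switch error, dosage accuracy, oracle equivalence on
  enumerable instances), not bit-level.
* TOPMed-style variant flags (SVM, CEN, DISC, EXHET, CHRXHET) are
  consumed from the VCF FILTER column, never recomputed.
* No relatedness filtering, no Firth correction under separation, no
  genome-build liftover, no rare-variant machinery.
* The paired technical-comparison design cannot yield a calibrated λ
  (see above); its readout is the absence of significant hits.
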