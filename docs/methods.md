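# Methods

This note documents the models, conventions, and numerical choices behind
`prsvar`, and what its synthetic benchmarks do and do not demonstrate about
real imputation pipelines.

## Synthetic cohort model

The generator emulates the statistical setting of an ancestry-stratified
imputation study: a large European-like and a smaller African-like group
genotyped on an array, imputed against a European-dominated reference panel,
with a whole-genome-sequencing (WGS) gold standard available for every
individual.

**Allele frequencies.** Ancestral minor allele frequencies are drawn uniform
on a configurable interval (default (0.01, 0.5)), with random allele
orientation. Uniform sampling is a deliberate simplification: it gives every
MAF bin support without committing to a site-frequency spectrum. Population
frequencies follow the Balding–Nichols model — Beta(p(1−F)/F, (1−p)(1−F)/F),
mean p, variance F·p(1−p) — with defaults F_ST = 0 for the European-like
group and F_ST = 0.15 for the African-like group, a typical
continental-divergence magnitude.

**Haplotype panel and LD.** Variants are partitioned into consecutive blocks
(default 20 variants). Each panel haplotype draws one standard-normal latent
factor per block; the latent value at variant j mixes the block factor and
independent noise with weight `block_ld` (default 0.9), and the allele is the
indicator that the latent value falls below the normal quantile of p_j. This
block-factor copula was chosen over founder-copying schemes because it gives
exact Bernoulli(p_j) margins at any block length (so frequency-recovery
checks are clean binomial statements) while making within-block LD a single
tunable knob; founder-copying couples the attainable r² to the founder count
and biases margins once founder patterns are frequency-matched. The cost is
that the panel has no mosaic ancestry of literal shared segments; since
cohort haplotypes are drawn *from* the panel, the copying HMM still has exact
haplotype matches available and the emulator is, if anything, optimistic
about achievable accuracy.

**Cohort.** Each individual is two panel haplotypes of their population,
sampled with replacement; the truth dosage is the ALT-allele sum. Defaults
mirror the study conditions the analysis targets: 1447 + 239 individuals, a
161-SNP score with 38 typed and 123 untyped variants (`fraction_typed` =
38/161), six replicates per process.

**Score model.** Weights are Normal(0, 0.1) log odds ratios; two variants are
boosted tenfold by default, emulating scores dominated by a few large-effect
loci (LPA/ANRIL-like for coronary artery disease, APOE-like for Alzheimer's).

**What the generator does not emulate:** recombination maps and realistic
demography, admixed individuals, phase-switch errors, genotyping error in the
typed SNPs, strand/allele harmonization problems, and HRC-scale variant
counts. Passing benchmarks therefore demonstrate correct *behavior of the
statistics* under controlled imputation noise, not engine-specific accuracy
on real cohorts.

## Imputation emulation

**Parametric route.** For untyped variant j with truth variance V_j, total
added Gaussian noise variance is s²_j = V_j(1−R²_target)/R²_target, so the
expected squared correlation between imputed and truth dosage equals the
target (default 0.925, a realistic aggregate accuracy for common variants).
The noise splits into a component shared across replicates (systematic
difficulty of the variant for this individual) and an independent
per-replicate component with SD `sigma_run`; the split changes run-to-run
variability without changing total error — the mechanism behind
population-level "masking" of individual-level instability. Dosages are
clipped to [0, 2]; achieved post-clip accuracy is recorded in the replicate
metadata and a shortfall beyond 0.02 raises a metadata warning. At desk
scales the calibration is accurate to ~0.001 for 2,000 individuals; per-SNP
R̂² at a few dozen samples is dominated by sampling noise, not
miscalibration.

**Haplotype-copying HMM.** A minimal Li–Stephens model: hidden states are the
N panel haplotypes with a uniform prior; between adjacent sites the chain
stays with probability 1−ρ or switches to a uniformly random haplotype with
probability ρ (default 0.01/site); typed-site emissions match the observed
allele with probability 1−θ (default θ = 0.002). Site-constant ρ, θ keep the
model minimal; no genetic map is used. Forward–backward runs with per-site
scaling (messages renormalized every site), and the posterior allele
probability is the state marginal read out against panel alleles,
Σ_h γ_v(h)·panel[h, v] — so a degenerate single-pattern panel returns that
pattern exactly and uninformative emissions (θ = 0.5) return the panel
frequency profile. Deterministic mode emits posterior-mean dosages (the
behavior of engines without stochastic pre-phasing: replicates are
identical); sampled mode backward-samples one copying path per haplotype per
replicate using the structured-kernel decomposition (stay with probability
∝ (1−ρ)f_v(h'), else redraw from f_v), which is exact and O(N) per site.
Diplotypes are treated as two independent haploid chains conditional on the
known truth phase; phasing error itself is not modelled. Computation is
chunked over haplotypes (default 512 per chunk, forward messages in float32)
to bound memory at large cohort sizes.

## Scoring and ranking conventions

* PRS is the exact weighted dosage sum over the model's variants; a model
  variant missing from the matrix is an error (exclusions are an upstream
  modelling decision, not a silent drop). Scoring-file effect alleles are
  matched against REF/ALT with explicit flip handling (x → 2−x when the
  effect allele is REF); an allele matching neither is an error.
* Percentiles are midrank percentiles within each ancestry group:
  100·(c_less + 0.5·c_equal)/n. The group mean is exactly 50 regardless of
  ties, and percentiles are invariant to shifting or positively rescaling
  scores.
* Replicate scores are ranked within the same cohort and ancestry group of
  that replicate's own score distribution by default. Ranking against the
  WGS-based distribution instead is available (`rank_against="wgs"`); the
  within-replicate convention is the default because the cohort itself is
  re-scored in a re-imputation, but the choice is genuinely open and both are
  kept.
* Tier boundaries are strict: low < 20, high > 80, boundary values
  intermediate. Refined tiers are one-sided strict inequalities ("<5" …
  ">95").

## Variability statistics

* The percentile-change table counts individuals by replicate range
  (max − min over K replicates) against thresholds {1, 5, 10, 20}; "≤ 1" and
  "> 1" partition each stratum exactly at range = 1.0. The range reading of
  "percentile change" is primary; deviation-from-WGS variants are available
  through the deviation summaries.
* Deviation-by-bin uses 10 equal-width WGS-percentile bins by default
  (configurable); per individual, the average and maximum |replicate − WGS|
  percentile deviation, summarized as box-plot statistics; empty bins are
  reported, not raised.
* The 3×3 tier matrix is accumulated over (individual, replicate) pairs with
  rows the single-replicate tier. Two column conventions are both emitted,
  because the underlying table semantics are ambiguous: primary columns are
  the tier of the individual's mean replicate percentile, secondary columns
  the WGS-based tier. The convention is recorded in the output metadata.
* Refined-tier re-classification: among individuals whose WGS percentile is
  in the tier, the rate is the share with ≥ 2 replicates outside it. The 95%
  CI is the untruncated Wald interval rate ± 1.96·√(rate(100−rate)/m) —
  untruncated deliberately, so a 0% rate reports (0–0) and small tiers can
  report negative lower bounds, making the interval arithmetic transparent.

## Accuracy metrics

Dosage R² is the squared Pearson correlation, defined as 0 when either
vector is constant (the conservative reading of an undefined correlation).
Genotype classes are obtained from dosages by rounding to the nearest of
{0, 1, 2} with ties (0.5, 1.5) rounding down. F-score is macro-averaged over
classes present in truth; IQS is the kappa-form chance-adjusted agreement on
the 3×3 table, with the P_exp = 1 degenerate case mapped to 1 for perfect
agreement and 0 otherwise. Per-individual R² uses untyped variants only by
default (typed variants are copied and would inflate accuracy); this is
switchable. MAF bins are half-open (a, b] with default edges
0.005/0.01/0.05/0.1/0.5; a variant exactly on a cut point falls in the lower
bin. The paired process comparison is the two-sided Wilcoxon signed-rank test
with zero differences dropped; an all-zero difference vector is flagged
degenerate rather than tested.

## Per-SNP contribution

The Gini coefficient of a SNP's imputation results is computed per
individual over their K replicate dosages — Σ_{a,b}|x_a − x_b|/(2K²·mean) —
and averaged over individuals. The per-individual-then-average aggregation is
a documented choice (a pooled variant over all individual×replicate dosages
is available but excluded from the invariance guarantees). The 0/0 case
(zero-mean or all-equal replicates) is defined as 0, consistent with
"perfectly consistent" semantics, and the implementation returns exactly 0
there rather than relying on floating-point cancellation. Percent variance
explained is β_j²·Var(x_j) with the empirical truth-dosage variance (no
Hardy–Weinberg assumption; the 2p(1−p) closed form serves only as a test
oracle), normalized to sum to 100. The exact functional form of a score
SNP's "contribution" is an interpretation: weight² × dosage variance is the
natural additive-score variance share and is what the quadrant analysis uses.

## Problem sizes and numerical notes

Benchmark analyses use 2,000 individuals × 200 score SNPs (25% typed, K = 6,
panel of 200 haplotypes) for the stochastic-vs-deterministic contrast and
noise sweeps, and 400 + 400 individuals × 150 SNPs for the two-population
reference-mismatch analysis; these sizes give stable medians and counts while
keeping a full run in the tens of seconds. All randomness flows from a single
master seed through named spawned streams (simulation, one per process, one
per replicate), so identical configurations are bit-reproducible; spawned
seeds are kept below 2³¹ and recorded in the output manifests. VCF
coordinates are 1-based with internal variant keys (chrom, pos, ref, alt);
dosages are written with 3 decimals and read back through htslib's float32
DS field rounded at the 5th decimal so text round trips are exact.

## Known limitations

The emulator's two modes bracket real engines rather than reproduce them:
real stochastic pipelines randomize phasing, not copying paths, and real
panels are vastly larger and unphased cohort genotypes must be pre-phased.
Cohort haplotypes being literal panel members makes matched-population
imputation easier than in practice; accuracy numbers are therefore
upper-end, and cross-population contrasts (where the reference excludes the
target population's haplotypes) are the more faithful qualitative signal.
Re-classification CIs use the Wald approximation, which is inaccurate for
very small tiers — that inaccuracy is intentional, to keep the reported
intervals' arithmetic transparent and reproducible.
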