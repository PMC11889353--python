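# Methods

## Problem and approach

Correlation between a phosphosite's abundance and a protein's abundance in
tumor cohorts does not establish regulation: shared confounders (tumor
purity, global signaling state, technical batch) and reverse causation
produce correlated pairs with no causal link. `phosmr` treats the question
as a one-sample Mendelian randomization (MR) problem: germline SNPs that
perturb a phosphosite's level are used as instrumental variables (IVs),
and the phosphosite→protein causal effect is estimated from per-SNP
summary statistics by inverse-variance-weighted (IVW) meta-analysis of
per-variant Wald ratios.

The difficulty specific to multiomics cancer cohorts is their size (tens
to a few hundred samples). Genome-wide-significant cis-pQTLs essentially
do not exist at n ≈ 80, so conventional IV selection either finds nothing
or, with relaxed thresholds, selects noise and suffers the winner's
curse. The package's flagship selection rule is therefore **dual
evidence**: a SNP becomes an instrument only when (1) the internal,
covariate-adjusted SNP–exposure regression in the small cohort gives
p < 0.05, and (2) external evidence independently supports the
SNP–exposure relationship — Bonferroni-significance in a large external
GWAS (simulation mode), membership in a curated list of
phosphorylation-related SNPs (cohort mode), or both. The conjunction
keeps the internal threshold permissive (retaining weak instruments that
small samples cannot certify alone) while the external channel, being
independent of the analysis sample, damps the selection bias.

## Generative model

Simulations draw, for individual *i* and SNPs *j* = 1…J:

    U_i = Σ_j Φ_j G_ij + ε_iU
    X_i = Σ_j γ_j G_ij + θ_Ux U_i + ε_iX
    Y_i = Σ_j α_j G_ij + θ X_i + θ_Uy U_i + ε_iY

with G_ij ~ Binomial(2, 0.3) iid, ε ~ N(0,1) iid, and defaults J = 50,
30 IVs, θ_Ux = θ_Uy = 0.75. Valid IVs have α_j = Φ_j = 0; invalid IVs
(0 / 30% / 50% of instruments) receive direct outcome effects
α_j ~ N(0, 0.15²), read as standard deviation 0.15 per the R `rnorm`
convention of the reference implementation. Null SNPs have
γ = α = Φ = 0.

Two instrument-strength regimes are used deliberately:

* γ ~ U(0.08, 0.10) — the *weak* regime, where internal selection is the
  bottleneck and the four selection strategies genuinely differ;
* γ ~ U(1.0, 1.5) — the *strong* benchmark regime used for the published
  null-FDR table and the estimate-variability comparison. With weak
  instruments the BH-based competitors (`fdr`, `minp`) select almost no
  IVs at n ≤ 300 and their power collapses (~0.1 vs ~0.6 for `dual` at
  n = 200), so the "comparable power across strategies" benchmark is
  only meaningful in the strong regime.

Each replicate pairs a GWAS cohort (n = 100,000; exposure side only is
used) with a small multiomics cohort (n ∈ {50, 100, 200, 300}) in one of
three heterogeneity modes: **homogeneous** (the small cohort is a row
subsample of the GWAS individuals, with the outcome generated fresh from
the subsampled genotypes, exposure, and retained confounder — the only
self-consistent reading, since Y requires U), **low** (regenerated from
the same realized effect vectors), and **high** (γ redrawn from a
truncated normal before regeneration; mean 0.09, sd 0.01, truncated to
[0.08, 0.10] in the weak regime — the mean/sd are not fixed by the
source description, so these are package defaults, configurable). In the
strong benchmark regime the high-heterogeneity analog redraws from
truncnorm(1.25, 0.1) truncated to [1.0, 1.5], the scale-matched
counterpart.

Genotypes are sampled by inverse-CDF thresholding of a single float32
uniform per entry — distributionally identical to `rng.binomial(2, maf)`
and ~3.5× faster at GWAS scale. Randomness uses one root seed with
per-replicate child streams keyed by `(seed, replicate_index)`, so any
replicate is reproducible in isolation and results are independent of
worker count.

## Summary statistics

Per-SNP effects are ordinary least squares slopes with intercept
(simulation mode) or adjusted for age, sex, and smoking status (cohort
mode), with classical SEs and two-sided t p-values (n − rank df).
Missing data are handled complete-case per SNP, with the per-SNP sample
count recorded; constant genotypes and exact fits yield flagged
degenerate results (p = 1 by convention) rather than errors. The
vectorized batch path is bit-compatible with per-column calls and is
verified against a QR-based reference solver to 1e-10.

## Instrument selection and filters

* `dual` — internal raw p < 0.05 AND every present external channel
  (GWAS raw p < 0.05/J, i.e. Bonferroni over the J SNPs tested for the
  exposure; prior-list membership).
* `fdr` — all SNPs with BH-adjusted internal p < 0.05.
* `minp` — the single smallest-raw-p SNP among the BH-significant ones
  (ties break by input order).
* `gwas` — external Bonferroni significance alone.

Cohort mode additionally applies, in order: feature filtering (missing
fraction ≤ 90%), SNP filtering (variation rate ≥ 10%, MAF > 0.01), a
cis window of gene boundary ± 1 Mb (inclusive at exactly 1 Mb — "up to"
is read as ≤), prior-list intersection, the adjusted internal
regression, and greedy LD pruning: candidates ranked by ascending
p-value are accepted iff their squared Pearson correlation with every
already-accepted SNP is ≤ 0.2, computed on the supplied genotype matrix
(an external reference panel can be substituted by passing its
genotypes). Constant columns are treated as unlinked.

## Causal estimation

For instruments j with exposure effects β_Xj and outcome effects β_Yj
(SE σ_Yj), the fixed-effects IVW estimate is

    θ̂ = Σ β_Xj β_Yj / σ_Yj²  ÷  Σ β_Xj² / σ_Yj²,   se(θ̂) = (Σ β_Xj²/σ_Yj²)^(−1/2)

— weighted least squares of β_Y on β_X through the origin with weights
1/σ_Y², first-order (exposure-side uncertainty ignored), normal
reference for the Wald statistic. A single instrument degenerates to the
Wald ratio β_Y/β_X with SE σ_Y/|β_X|; the minimum instrument count is 1
(configurable). An empty instrument set is a distinguished
"no instruments" result that downstream decision rules count as a
non-discovery. Zero exposure betas are an error rather than silently
dropped — selection should have excluded them.

`ivw` exposes three variance models. `"fixed"` is the formula above.
`"random"` multiplies the SE by max(1, RSE), the residual standard error
of the weighted fit, penalizing between-instrument heterogeneity.
`"default"` applies the random-effects correction only at ≥ 4
instruments, mirroring the default behavior of the widely used R MR
implementation; the point estimate is identical in all three. The
benchmark and screening pipelines use `"default"`: pilot runs showed the
strictly fixed-effects SE leaves the dual strategy's null FDR under 30%
invalid instruments at ~0.02 where the reference results are ~0.002,
while the heterogeneity-penalized SE reproduces them — invalid
instruments inject exactly the kind of between-instrument heterogeneity
the correction is designed to absorb.

Multiple testing uses Benjamini–Hochberg step-up adjustment
(statsmodels) throughout.

## Benchmark engine

Each replicate runs the full pipeline (paired cohorts → summary
statistics → four selection strategies → IVW → Pearson/Spearman on the
small cohort's (X, Y)). Power is the flagged fraction of replicates when
θ ≠ 0; the same fraction under θ = 0 is reported as an FDR. Two decision
modes exist: `raw` (per-replicate p < α) and `bh` (BH across all
replicate p-values of a method as one family, then adjusted p < α). The
`bh` mode is the default and is the reading consistent with the
published null-FDR table's magnitudes; both are available. The
SNP-identity randomization check permutes the identifier↔column
assignment of the small cohort's genotype matrix, preserving every
marginal distribution while severing the SNP–exposure linkage that
selection exploits.

## Synthetic cohort generator

The cohort fixture emulates the screening pipeline's data model: 12
genes on two synthetic chromosomes spaced so cis windows never overlap;
6 cis SNPs per gene in an LD block generated by thresholding correlated
latent Gaussians (the block-factor loading is tetrachorically corrected
so the realized genotype correlation matches the requested `ld_block_r`;
default 0.3); 3 of the 6 are causal for the gene's phosphosite with
effects γ ~ U(0.8, 1.2) — a strong-cis-pQTL regime chosen so that a
200-sample cohort has realistic per-SNP power (~1) — and a configurable
fraction of the causal SNPs enters the prior list (default 1.0). Eight
planted phosphosite→protein links with θ = 0.6 target other genes'
proteins; all features load on one shared confounder (0.75) and on
age/sex/smoking covariates; omics values are masked completely at
random (default 5%). The truth table lists every planted link.

What the fixture does *not* emulate: real LD maps and allele-frequency
spectra, intensity-dependent (non-random) missingness, trans-QTLs,
multi-site phosphopeptides, and normalization artifacts. Passing the
recovery tests therefore demonstrates the pipeline's statistical
machinery under its own assumptions, not robustness to those real-data
features.

## Calibration behavior and known limitations

With the true instruments fed directly to fixed-effects IVW (no
selection), no confounding and θ = 0, the raw type-I error is 0.05 when
the cohort is large relative to the instrument count (0.047–0.051 at
n ≥ 1000, J = 50). At n = 200 with 30 weak instruments it inflates to
~0.08: all outcome-side betas share one Y sample, and their in-sample
cross-correlations interact with the estimated exposure betas — a
finite-sample many-weak-instruments effect of the one-sample design, not
an estimator defect. The calibration suite therefore runs type-I at
n = 1000.

Under θ = 0.6 the one-sample design is asymptotically unbiased (the
exposure measurement error cancels between numerator and denominator),
whereas a two-sample variant attenuates severely with weak instruments
(classic regression dilution; mean θ̂ ≈ 0.23 at n = 200) —
`run_calibration` exposes both via `two_sample=`. At n ≤ 300 the
estimated outcome-side weights carry a small positive finite-sample
bias (~+1% of θ; weights correlate with the outcome-beta errors), at
the Monte-Carlo resolution of a 2000-replicate mean, so unbiasedness is
checked at n = 1000 where it vanishes. One-sample 95% CI coverage is
mildly conservative at large n (~0.973: the outcome-side SE includes
the θ·X variance component, which is conditionally fixed given the
exposure betas) and mildly anticonservative at n = 50 (~0.93); at
n = 100–300 the two effects roughly offset, and the coverage check runs
at n = 100, the grid size closest to the 79-sample cohorts that
motivate the method.

The SNP-identity randomization check on the synthetic cohort uses the
group-wise mode of `randomize_snp_identities` (whole gene blocks
reassigned to other genes, no block mapping to itself): on a 72-SNP
panel a uniform permutation would by chance relink ~10% of phosphosites
to instruments from their own cis block — a finite-panel artifact that
the genome-scale check (hundreds of thousands of cis-SNPs) does not
have.

Other numerical choices: BH inputs must be finite (NaN p-values are the
caller's responsibility — the benchmark maps no-instrument replicates to
non-discoveries before adjustment); LD pruning and `minp` break ties by
input order, making every pipeline stage deterministic given its inputs;
screening requires ≥ 10 complete samples per regression/correlation (an
implementation floor, logged in the stage counts); phosphosite–protein
pairs mapping to the same gene are tested but flagged `same_gene`.

## Problem sizes used in the shipped checks

The acceptance script and statistical tests run 500 replicates per
benchmark scenario (the full study design uses 2000), 5000/2000
replicates for the calibration checks, and 30–50 synthetic-cohort seeds
for the screening checks; Monte-Carlo tolerances are computed at the
replicate counts actually run.
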