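# Methods

## Model and estimands

`medtrans` fits, for each candidate trio (SNP X, cis-mediators M₁…Mₚ,
trans-gene Y, covariates C), the two-stage linear mediation model

```
Y_i   = β₀ + X_i β_X + M_iᵀ β_M + C_iᵀ β_C + ε_Yi,      ε_Yi ~ N(0, σ²)
M_ij  = α₀ⱼ + X_i α_Xj + C_iᵀ α_Cj + ε_Mij,             ε_Mi ~ N_p(0, Σ)
```

by ordinary least squares (outcome stage: Y on [1, X, M, C]; mediator
stage: each Mⱼ on [1, X, C]). ε_Y is assumed independent of ε_M, but Σ's
off-diagonals are free, so mediators may be mutually correlated. Σ is
estimated from the mediator-stage residual cross-products with divisor
n − q − 2. Covariates enter both stages; they are consumed as a
precomputed table (sex, genotype PCs, expression factors) — the package
does not estimate hidden-factor models itself.

Estimands are products of coefficients: the total mediation effect
Δ = α_Xᵀ β_M, its components δⱼ = α_Xj β_Mj, and the single-mediator
version of δⱼ refitted with the other mediators omitted (SME — the
deliberately misspecified analysis whose behaviour the simulation study
quantifies). Δ̂ = Σⱼ δ̂ⱼ holds exactly by construction and is asserted in
tests on every path. Identification rests on the usual mediation
assumptions (no unmeasured confounding of the X→M, X→Y and M→Y relations
given C); no sensitivity analysis for their violation is provided.

## Bootstrap inference

Significance is assessed by nonparametric case resampling: whole rows
(Y, X, M, C) are drawn with replacement, both stages are refitted on each
resample, and a two-sided percentile p-value is computed with the add-one
convention

```
p = min(1, 2·min[(1 + #{T* ≤ 0}), (1 + #{T* ≥ 0})] / (B + 1))
```

which is strictly positive and conservative at the boundary. The CME test
computes one such p per component and combines them by Bonferroni
(p = min(1, p·minⱼ pⱼ)); this controls the composite null and reduces
exactly to the TME test when p = 1. The SME-any rule reports minⱼ pⱼ
uncorrected — rejection of either single-mediator test rejects overall — with
an optional Bonferroni switch. Resamples in which the SNP becomes
monomorphic are redrawn (counted and reported), keeping B fixed. All
randomness flows from explicit integer seeds; trio-level runs derive
independent per-trio streams from one master seed.

The refits are vectorised across resamples (batched normal equations via
stacked matmul + `solve`), which keeps a B = 1000 three-test analysis of
one trio in the low milliseconds and makes replicated operating-
characteristic studies feasible on one CPU.

Choice of B: the add-one percentile rule rejects at level α only on a grid
of tail counts, so at B = 500 the effective level is ≈ 0.046 rather than
0.05. Calibration runs therefore default to B = 999, for which (B+1)·α is
integral and the nominal level is attained; power-curve simulations use
B = 500, where the small conservatism affects all three tests equally and
orderings are unaffected.

## Genotype QC and normalization

The QC cascade mirrors standard array-era practice, in this order: samples
with call rate < 0.97 are removed; then SNPs with missing rate ≥ 0.08, MAF
≤ 0.10 (strict), or exact Hardy–Weinberg p < 10⁻⁵ are removed, with
statistics computed on the retained samples. The HWE test is the exact
conditional test (enumeration of the heterozygote-count distribution given
allele counts, summing probabilities no larger than the observed table's):
at a 10⁻⁵ threshold the chi-square approximation is unreliable in exactly
the tail that matters. Among SNPs in complete LD (pairwise r² = 1 on shared
non-missing samples, including coding flips) or at identical positions, one
representative is kept — deterministically (lowest position, then id) by
default, with a seeded random mode for fidelity to pipelines that choose at
random. Dosages are reoriented to minor-allele counts before analysis;
loaders preserve the file's coding so that round-trips are lossless.

Expression normalization: across-sample quantile normalization (every
sample's distribution mapped onto the mean per-rank reference; ties receive
the mean reference value over their rank range) and, per probe at mediation
time, the rank-based inverse-normal transform with the Blom offset
(rank − 3/8)/(n + 1/4), ties mid-ranked.

## eQTL scan and trio selection

Each SNP–probe pair is classified cis (same chromosome, SNP within 1 Mb of
the probe interval; distance 0 inside it) or trans (everything else,
including all inter-chromosomal pairs). Association is the additive linear
model — OLS of expression on [1, dosage, covariates], two-sided t-test on
the dosage coefficient with n − k − 2 residual degrees of freedom. Missing
dosages are handled complete-case per SNP, keeping the t reference
distribution exact; perfect fits report a machine-epsilon p with a flag
rather than zero. Benjamini–Hochberg q-values are assigned separately
within the cis and the trans class, over the whole scan (a genome-wide
FDR reading, not per-SNP). Candidate trios pair each trans signal with
p < 10⁻⁶ (strict) with its SNP's cis genes at q ≤ 0.05, ordered by
ascending cis p and truncated to at most 5 mediators.

## Simulation study

`simulate` reproduces the three-scenario operating-characteristic study.
Data are drawn as X ~ Binomial(2, 0.3); two mediators with intercepts 0.5,
genotype effects (α_X1, 0.6) with α_X1 on the grid {0.2, 0.4, 0.6, 0.8,
1.0}; exchangeable mediator errors (variance 1, correlation 0.2); outcome
Y = 0.5 + 0.3·X + β_M1 M₁ + β_M2 M₂ + ε_Y with standard-normal ε_Y and no
covariates. Scenario I sets β_M = (0.1, 0): only M₁ mediates, and the SME
analysis of M₁ is the correctly specified model. Scenario II sets
β_M = (0.1, 0.1) (same direction); Scenario III sets β_M = (0.1, −0.1), so
Δ = 0 exactly at α_X1 = 0.6 while δ = (0.06, −0.06) — the cancellation
configuration in which only the component-wise test retains power. Under
the null both components are zero, a configuration shared by all
scenarios. Sample sizes 100 and 300 mirror single-population and combined
panels.

Within a replicate the three tests share one resample-index matrix (they
are tallied marginally, so this is valid and halves cost). In Scenario I
the SME row tests M₁ only (the true model); in Scenarios II/III it tests
both mediators and rejects if either does. Replicate seeds come from a
spawned `SeedSequence` tree, so a fixed master seed gives bit-identical
tables; execution is sequential.

Default problem sizes: calibration runs use 1000 replicates (matching the
binomial 95% band (0.0365, 0.0635) quoted for the empirical levels);
power-curve suites run 300 replicates per grid point, whose ±2 Monte-Carlo-
standard-error tolerance is the yardstick for every ordering assertion.

## Enrichment procedures

Two procedures. (1) MAF-matched permutation: query SNPs are compared with
panel SNPs resampled without replacement within MAF bins (width 0.05,
configurable; matching is on MAF only), using the proportion of SNPs
associated with ≥2 (or ≥1) cis-genes as the statistic and the add-one
empirical p-value (1 + #{resample ≥ observed})/(B + 1). (2) Fisher's exact
test on 2×2 trait-association tables, two-sided by default (one-sided
"greater" available); degenerate margins return p = 1 with an undefined
odds ratio.

## Synthetic data

The fixture generator emulates a small genotyped expression panel: 0/1/2
dosages drawn under Hardy–Weinberg equilibrium with per-SNP MAF uniform in
a configurable range, uniform missingness, SNPs alternating between two
synthetic chromosomes spaced 3 Mb apart (beyond the 1 Mb cis window, so
neighbouring SNPs are trans to each other's probes). Planted trios place
mediator probes inside the cis window of their SNP and the trans probe on
the other chromosome, with values from the two-stage forward model;
"direct" configurations plant a genotype effect on a distant probe with
zero mediator effects (β_M = 0) — a trans-eQTL that must not be called
mediated. Null probes are independent noise. Default planted effects
(α_X = 0.8, β_M = 0.3, n = 300) are deliberately larger than the
simulation-study values: pipeline tests probe recovery, not marginal
power. End-to-end detection fixtures draw planted SNPs with MAF in
(0.2, 0.5): a planted SNP at the 0.10 QC boundary is censored by the MAF
filter about half the time, which would measure threshold discreteness
rather than method behaviour.

What the generator does not emulate: linkage disequilibrium structure,
population admixture, batch effects or other expression confounding, and
multi-allelic or imputed genotypes. Passing pipeline tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data complications (covariates are the
supported mechanism for confounding control, and are exercised with
synthetic null covariates only).

## Numerical choices and edge cases

- Degenerate limits: with zero mediator noise the outcome design
  [1, X, M, C] is exactly singular (mediators collinear with X), so β_M is
  not separately identified; fitting raises a rank-deficiency error naming
  the collinear columns. Tests of the noiseless limit assert the
  identifiable quantities (mediator-stage slopes, total X→Y effect).
- Missing-value tokens NA / . / -9 / empty are accepted on read; NA is
  written. Coordinates are 1-based with inclusive probe intervals
  throughout; the cis distance is anchored to the interval, not its
  midpoint.
- Bootstrap p-values are bounded in [1/(B+1), 1]; empirical permutation
  p-values likewise.
- BH q-values use the standard step-up adjustment; ties share a q.
- `qc_filter` is idempotent; an empty post-QC matrix warns rather than
  errors.

## Known limitations

- Mediation p-values are not adjusted across trios; downstream FDR over
  trio results is the caller's choice.
- The CME combination is Bonferroni min-p; with many highly correlated
  mediators it is conservative (trios here carry at most 5, typically 1-2).
- Case-resampling bootstrap assumes exchangeable rows; family or cohort
  structure beyond the supplied covariates is not handled.
- The exact conditional HWE test is slightly conservative, as all exact
  tests on discrete data are.
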