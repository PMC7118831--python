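# Methods

## Model and score statistics

For n independent subjects with trait Y (binary 0/1 or continuous) and an
n × K matrix G of minor-allele counts/dosages in [0, 2], the association
model is a GLM with logit link (binary) or identity link (continuous):

    h(E[Y_i]) = β₀ + Σ_k β_k G_ik  (+ Σ_j α_j C_ij with covariates)

and the set-level null hypothesis is β = 0.  The tests are built from the
per-variant score statistics

    U_k = Σ_i (Y_i − μ̂_i) g_ik

where, in the marginal model, μ̂_i = Ȳ and g = G; in the covariate-adjusted
model, μ̂ is the fitted mean of a null GLM on (intercept + covariates) and
g is the per-variant OLS residual of genotype on the same design.  The
null covariance factors as V = σ̂² · (gᶜ)ᵀgᶜ with gᶜ the centered (or
covariate-residualized) genotypes and

* σ̂² = Ȳ(1−Ȳ)                      binary, marginal;
* σ̂² = unbiased sample variance of Y  continuous, marginal;
* σ̂² = (1/n) Σ μ̂_i(1−μ̂_i)           binary, adjusted;
* σ̂² = (1/(n−1)) Σ (e_i − ē)²         continuous, adjusted (e = Y − μ̂).

Standardized scores Ũ_k = U_k/√V_kk are asymptotically N(0,1) under the
null, giving marginal p-values p_k = 2[1−Φ(|Ũ_k|)] and the one-sided pair
p_k⁺ = 1−Φ(Ũ_k), p_k⁻ = Φ(Ũ_k).  Numerically, Φ tails are evaluated with
the survival form `ndtr(−u)` (no cancellation), p⁻ is computed as 1 − p⁺
so the pair sums to one exactly, and p_two = 2·min(p⁺, p⁻).

## The adaptive Fisher family

With weights w (default w_k = √(f_k(1−f_k)), f_k the in-sample allele
frequency — allele-flip invariant and ≈ sd(G_k)/√2 under Hardy–Weinberg):

1. R_k = −log p_k (natural log; any fixed base gives the same test),
2. X_k = w_k R_k, sorted descending, partial sums S*_k = Σ_{l≤k} X₍ₗ₎,
3. each S*_k gets a p-value by inclusive counting over the observed
   profile plus B permutation profiles: P(S*_k) = #{b : S*_k⁽ᵇ⁾ ≥ S*_k}/(B+1),
4. T_wAF = min_k P(S*_k); AF is the flat-weight special case; Min-P uses
   the statistic min_k p_k with the same permutation calibration;
5. wAF_d = min(T_wAF, T_wAF⁺, T_wAF⁻), where the one-sided statistics
   apply the identical pipeline to p⁺ and p⁻.

## Permutation calibration

The null distribution permutes residuals e_i = Y_i − μ̂_i (marginal: Ȳ;
adjusted: the covariate-null fit), recomputing U⁽ᵇ⁾ = Σ_i e⁽ᵇ⁾_i g_i while
holding V — and, in the adjusted model, μ̂ and ĝ — fixed at their observed
values.  The final p-value counts permutation statistics at least as
extreme as the observed one, p̂ = #{b ≥ 1 : T⁽ᵇ⁾ ≤ T⁽⁰⁾}/(B+1).

Numerical conventions:

* **p-value floor.**  The counting formula can return 0 when the observed
  statistic is a strict minimum across all replicates; since B
  permutations cannot resolve probabilities below 1/(B+1), the reported
  p-value is floored there.  Partial-sum p-values are automatically
  ≥ 1/(B+1) by inclusive self-counting.
* **Permutation sampling.**  Permutations are uniform draws (with
  replacement) from the symmetric group, generated by argsorting random
  keys from one seeded NumPy generator; execution is single-process and
  vectorized in blocks of bounded size, so identical inputs and seed give
  bit-identical results.  An explicit index array can replace random
  sampling, which the tests use to enumerate all n! orderings exactly on
  tiny datasets.
* **Shared permutations.**  When several methods run on one dataset they
  score the same permutation block, making power comparisons paired; the
  three wAF_d components likewise share each replicate, preserving their
  joint null dependence.
* **Underflow.**  A marginal p-value that underflows to 0 (|Ũ| ≳ 38) is
  clamped to the smallest positive normal double before −log, with a
  logged warning.
* **Ties.**  The descending sort needs no tie-break: S* depends only on
  the multiset of X values.  A stable sort keeps intermediate arrays
  deterministic.
* **Degenerate input.**  Monomorphic variants (V_kk = 0) are dropped with
  a warning at import/construction; a constant trait or residual vector,
  a rank-deficient covariate design, and a non-converged logistic null
  fit raise typed errors rather than falling back silently.
* **σ̂₃² is not recomputed per permutation**; like V it stays at its
  observed value, mirroring the fixed-denominator standardization of the
  marginal case.

## Step-up permutation budget

Genome-wide scans start every gene at B = 100; any gene whose estimated
p-value falls below 5/B is re-tested with B×10 (fresh seeded permutations
per round), iterating until no gene is below threshold or a cap (default
10⁶) is reached, in which case the gene is flagged `censored`.  The cap is
a practical bound on runtime/memory; memory scales as (B+1)×K doubles for
the profile matrix plus a bounded permutation block.

## Simulation framework

The generator emulates a gene's LD structure with a latent-Gaussian
threshold model: per subject, two independent haplotype vectors
Z₁, Z₂ ~ N(0, A) with AR(1) correlation A_{kk'} = c^{|k−k'|} (default
c = 0.9, sampled exactly via the AR recursion), and

    G_ik = 1(Φ(Z₁k) ≤ MAF_k) + 1(Φ(Z₂k) ≤ MAF_k) ∈ {0, 1, 2}.

MAFs are redrawn for every dataset: log-uniform on [0.001, 0.5] by
default, uniform on [0.001, 0.01] for the all-rare regime.  Effects are
sparse: round(πK) positions receive β_k ~ U[−δ, δ] (or U[0, δ] for
same-direction studies), the rest exactly zero.  Binary traits are
Bernoulli(logit⁻¹(Gβ)) with zero intercept — prevalence 0.5 under the
null, drifting only slightly under alternatives, so case/control balance
is approximately maintained without explicit prevalence control;
continuous traits add standard normal noise to Gβ.  Scenario defaults
(n = 1,000, c = 0.9) are the reference study conditions.

What this generator does *not* model: recombination maps, population
structure, Hardy–Weinberg violations, genotyping error, or LD between the
two haplotypes.  Passing calibration and power checks on these synthetic
data therefore demonstrates correctness of the statistics and their
permutation null under exchangeability — not robustness to confounding or
data-quality pathologies in real cohorts.

Power estimation spawns one child random stream per replicate from the
master seed (results independent of execution order), simulates a fresh
dataset, drops monomorphic columns, runs all requested methods on a shared
permutation block, and reports rejection rates with exact Clopper–Pearson
intervals.  For paired method comparisons the Monte-Carlo uncertainty of a
power difference is the paired SE, sd(d)/√reps with d the per-replicate
rejection difference, which is sharper than combining the two marginal
SEs.

### Problem sizes used in the shipped checks

The validation suite runs at desk scale, chosen to keep the statistical
claims testable with tight Monte-Carlo error: type-I error at n = 500,
K = 50, B = 500, 1,000 replicates (99% binomial band [0.032, 0.068]
around α = 0.05); power orderings at n = 500, K = 100, B = 500, 500
replicates; exactness against a full-enumeration oracle at n = 6.  The
reference study design (n = 1,000, 5,000 replicates, K up to 500) is the
generator default and can be run through the same functions at
proportionally higher cost.

## Design choices where the design was open

* **wAF_d permutation sharing** (the directed procedure is only specified
  as "similar"): the three component statistics are computed within each
  replicate and the minimum taken per replicate, preserving their joint
  dependence under the null.  Computing each component's p-value from
  independent permutation sets would be slightly conservative and three
  times the cost.
* **Adjusted-model permutation scheme**: the published procedure covers
  the marginal model; with covariates we permute null-model residuals
  against covariate-residualized genotypes with μ̂, ĝ, V fixed — the
  direct analogue of the marginal steps under the covariate null.
* **Rounding of πK** to the nearest integer (all standard scenarios are
  exactly divisible, so this matters only off-grid; a positive π that
  rounds to zero effects logs a warning).
* **Minor-allele orientation** is enforced at read time (flip when the
  alternate-allele frequency exceeds 0.5, logged); the default weight is
  flip-invariant, so orientation affects only sign conventions of Ũ.
* **Coordinates**: BED is 0-based half-open, VCF 1-based; gene flanks
  (default 5,000 bp) are applied to the BED interval and clipped at zero.
  A variant inside several overlapping flanked regions enters each of
  their sets.

## Known limitations

* Permutation exchangeability assumes independent subjects; related
  samples or strong population structure violate it (covariate adjustment
  helps only with measured confounders such as principal components).
* p-values are Monte-Carlo estimates bounded below by 1/(B+1); genome-wide
  significance claims need the step-up scan with a large cap.
* The asymptotic N(0,1) marginal p-values are used inside the permutation
  loop only as a monotone transform, so their finite-sample inaccuracy
  does not affect validity (the permutation calibration is exact up to
  Monte-Carlo error), but it can affect power for extremely rare variants.
* No family-wise or FDR correction across genes is applied; reported
  p-values are per-gene.
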