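# waftest

Adaptive Fisher association tests for SNV sets: **AF**, the MAF-weighted
**wAF**, the directed **wAF_d**, and the **Min-P** comparator, with
permutation calibration, covariate adjustment, a step-up permutation
budget for genome-wide scans, and a full simulation framework for type-I
error and power studies.

## The problem and the method

Gene-based association tests ask whether *any* of the K single-nucleotide
variants in a gene (plus flanking sequence) is associated with a trait.
Burden and variance-component tests implicitly assume that most variants in
the set carry signal; when only a small fraction do (the *sparse* scenario)
their power suffers, while single-best-variant tests (Min-P) struggle when
signal is spread over many variants (the *dense* scenario).

The adaptive Fisher family adapts to the unknown signal proportion.  For
each variant the marginal score statistic is

&nbsp;&nbsp;U_k = Σᵢ (Yᵢ − μ̂ᵢ) G_ik,&nbsp;&nbsp;Ũ_k = U_k / √V_kk,

with μ̂ᵢ = Ȳ (or the covariate-null fitted mean) and V the estimated null
covariance of U.  Two-sided p-values p_k = 2[1 − Φ(|Ũ_k|)] are transformed
to R_k = −log p_k, weighted as X_k = w_k R_k with w_k = √(MAF_k(1−MAF_k))
by default, sorted in descending order, and accumulated into partial sums
S*_k = X₍₁₎ + … + X₍ₖ₎.  Each S*_k receives a permutation p-value by
inclusive counting over B residual permutations, and the test statistic

&nbsp;&nbsp;T_wAF = min₁≤k≤K P(S*_k)

is itself calibrated by the same permutations:
p̂ = (1/(B+1)) #{b : T⁽ᵇ⁾ ≤ T⁽⁰⁾}.  Because the minimum runs over all
prefix lengths k, the statistic automatically focuses on however many
variants carry signal.  The directed variant wAF_d takes the minimum of
the two-sided and both one-sided wAF statistics, which pays off when all
effects point the same way.

## Worked example

```python
import numpy as np
from waftest import SNVSetTest, SimScenario, simulate_dataset

# simulate one gene: 500 subjects, 50 variants in LD, 20% causal
scn = SimScenario(n=500, k=50, pi=0.2, delta=0.5, trait_type="binary")
y, g, effects = simulate_dataset(scn, np.random.default_rng(9))

model = SNVSetTest(y, g, weights="maf")
res = model.fit(method="all", b=1000, seed=1)
print(res.summary())
```

```
SNV-set association test (adaptive Fisher family)
==========================================================
subjects:           500
trait type:         binary
variants tested:    48  (2 monomorphic dropped)
covariates:         0
weights:            default_maf
permutations (B):   1000
----------------------------------------------------------
method       statistic       p-value   k_hat
af             0.02398     5.195e-02       1
waf           0.006993     1.598e-02       1
wafd          0.002997     1.499e-02       1
minp         0.0009384     2.298e-02      14
----------------------------------------------------------
p-values are permutation estimates, floored at 1/(B+1) = 9.990e-04
```

This draw planted ten causal variants with two-sided effects.  wAF and
wAF_d reject at the 5% level (p ≈ 0.015-0.016); the unweighted AF test is
borderline (p ≈ 0.052) because without MAF weights the many null rare
variants dilute the partial sums.  `statistic` is the observed minimum
partial-sum p-value and `k_hat` the prefix length attaining it.

The command line drives the same machinery from files (VCF or a delimited
dosage matrix, phenotype/covariate tables keyed by subject id, BED gene
regions with ±5,000 bp flanks by default):

```bash
waftest test --vcf cohort.vcf --pheno pheno.tsv --regions genes.bed \
             --method all --scan --b-init 100 --b-max 1000000 \
             --seed 1 --out results.tsv
waftest simulate --n 1000 --k 100 --pi 0.02 --delta 1 --trait-type binary \
                 --method waf --reps 1000 --b 500 --seed 1 --out power.tsv
```

With `--scan`, genes are first tested with B=100 permutations and only
genes whose estimated p-value falls below 5/B are re-tested with tenfold
more, so permutation effort concentrates on the promising genes.

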