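"""Permutation calibration: enumeration oracle, identities, scan policy."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import ndtr

from waftest import (
    GenotypeMatrix,
    ScanPolicy,
    TraitVector,
    adaptive_scan,
    flat_weights,
    run_all_methods,
    run_test,
    run_wafd_test,
)
from conftest import random_dataset


def brute_force_waf(y, g, w, sided="two"):
    """From-scratch wAF over the full permutation group (all n! residual
    orderings as the B permutations), using plain Python loops.

    Returns (statistic, p-value).  Independent of the engine's vectorized
    sort/rank path.
    """
    yv, gm = y.values, g.counts
    n, k = gm.shape
    if y.trait_type == "binary":
        sigma = yv.mean() * (1 - yv.mean())
    else:
        sigma = yv.var(ddof=1)
    gc = gm - gm.mean(0)
    vkk = [sigma * sum(gc[i, j] ** 2 for i in range(n)) for j in range(k)]
    e0 = yv - yv.mean()

    def profile(e):
        xs = []
        for j in range(k):
            u = sum(e[i] * gm[i, j] for i in range(n))
            ut = u / math.sqrt(vkk[j])
            if sided == "two":
                p = 2.0 * ndtr(-abs(ut))
            elif sided == "plus":
                p = ndtr(-ut)
            else:
                p = ndtr(ut)
            xs.append(w[j] * -math.log(p))
        xs = sorted(xs, reverse=True)
        out, acc = [], 0.0
        for x in xs:
            acc += x
            out.append(acc)
        return out

    perms = list(itertools.permutations(range(n)))
    b = len(perms)
    profiles = [profile(e0)] + [profile(e0[list(p)]) for p in perms]
    pvals = []
    for row in profiles:
        pvals.append(
            [
                sum(other[j] >= row[j] for other in profiles) / (b + 1)
                for j in range(k)
            ]
        )
    t = [min(row) for row in pvals]
    count = sum(t[i] <= t[0] for i in range(1, b + 1))
    return t[0], max(count, 1) / (b + 1)


@pytest.mark.parametrize("fixture", ["toy_binary", "toy_continuous"])
def test_full_enumeration_matches_brute_force(fixture, request):
    """With the permutation set equal to all 720 orderings, the engine's
    wAF statistic and p-value equal a loop-based enumeration exactly."""
    y, g = request.getfixturevalue(fixture)
    w = np.array([0.5, 1.0, 0.25])
    perms = np.array(list(itertools.permutations(range(6))))
    from waftest import WeightVector

    res = run_test(
        y, g, weights=WeightVector(w), method="waf", permutations=perms
    )
    t_exp, p_exp = brute_force_waf(y, g, w)
    assert res.statistic == pytest.approx(t_exp, abs=1e-12)
    assert res.pvalue == pytest.approx(p_exp, abs=1e-12)
    assert res.b == 720


def test_flat_weights_waf_equals_af(rng):
    """Constant weights rescale every X identically, preserving all >=
    comparisons: wAF and AF coincide bit-exactly on matched seeds."""
    for trial in range(20):
        trait_type = "binary" if trial % 2 else "continuous"
        y, g = random_dataset(rng, n=30, k=4, trait_type=trait_type)
        res = run_all_methods(
            y, g, weights=flat_weights(4), methods=("af", "waf"), b=99,
            seed=trial,
        )
        assert res["af"].statistic == res["waf"].statistic
        assert res["af"].pvalue == res["waf"].pvalue
        np.testing.assert_array_equal(
            res["af"].partial_pvalues, res["waf"].partial_pvalues
        )


def test_single_variant_collapses_to_abs_score_test(rng):
    """K=1: the wAF p-value is the permutation p-value of the marginal
    two-sided test (monotone transform of |U~|)."""
    # dyadic trait values with n = 8 keep every residual sum exact in
    # floating point, so ties across permutations are exact ties
    y = TraitVector(
        np.array([0.5, 3.0, 1.5, 4.0, 0.0, 2.5, 1.0, 3.5]),
        trait_type="continuous",
    )
    g = GenotypeMatrix(rng.integers(0, 3, size=(8, 1)).astype(float))
    if g.counts.var() == 0:  # pragma: no cover
        g = GenotypeMatrix(np.array([[0, 1, 2, 0, 1, 2, 0, 1.0]]).T)
    perms = np.array(list(itertools.permutations(range(8))))
    res = run_test(y, g, method="waf", permutations=perms)
    e = y.values - y.values.mean()
    v = y.values.var(ddof=1) * np.sum(
        (g.counts[:, 0] - g.counts[:, 0].mean()) ** 2
    )
    u = e[perms] @ g.counts[:, 0]
    u0 = e @ g.counts[:, 0]
    p_perm = 2.0 * ndtr(-np.abs(u) / np.sqrt(v))
    p_obs = 2.0 * ndtr(-np.abs(u0) / np.sqrt(v))
    count = int(np.sum(p_perm <= p_obs))
    assert res.pvalue == pytest.approx(max(count, 1) / (len(perms) + 1))


def test_minp_equals_first_partial_sum_test(rng):
    """Min-P is a monotone transform of S*_1 under flat weights, so its
    permutation p-value equals the first-partial-sum p-value on a shared
    permutation set."""
    y, g = random_dataset(rng, n=25, k=5, trait_type="binary")
    perms = np.array([rng.permutation(25) for _ in range(300)])
    res = run_all_methods(
        y, g, weights=flat_weights(5), methods=("minp",), permutations=perms
    )["minp"]
    # direct S*_1 test: S*_1 = max of -log p = -log(min p)
    from waftest.permutation import _marginal_p_matrix, _permuted_scores
    from waftest.score import compute_score_marginal

    score = compute_score_marginal(y, g)
    u = _permuted_scores(
        score.residuals, score.genotype_residuals, len(perms),
        np.random.default_rng(0), permutations=perms,
    )
    p_two = _marginal_p_matrix(u, np.diag(score.v), "two")
    s1 = (-np.log(p_two)).max(axis=1)
    count = int(np.sum(s1[1:] >= s1[0]))
    assert res.pvalue == pytest.approx(max(count, 1) / (len(perms) + 1))


def test_reproducibility_and_lower_bound(toy_binary):
    y, g = toy_binary
    a = run_test(y, g, method="waf", b=199, seed=42)
    b = run_test(y, g, method="waf", b=199, seed=42)
    assert a.statistic == b.statistic and a.pvalue == b.pvalue
    np.testing.assert_array_equal(a.partial_pvalues, b.partial_pvalues)
    assert a.pvalue >= 1 / 200
    assert np.all(a.partial_pvalues >= 1 / 200)


def test_subject_relabeling_invariance(toy_binary):
    """Relabeling subjects jointly in (Y, G) leaves the exact enumeration
    p-value unchanged: the permutation group is label-invariant."""
    y, g = toy_binary
    perms = np.array(list(itertools.permutations(range(6))))
    sigma = np.array([3, 0, 5, 1, 4, 2])
    y2 = TraitVector(y.values[sigma], trait_type=y.trait_type)
    g2 = GenotypeMatrix(g.counts[sigma])
    r1 = run_test(y, g, method="waf", permutations=perms)
    r2 = run_test(y2, g2, method="waf", permutations=perms)
    assert r1.pvalue == r2.pvalue
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)


def test_wafd_sign_flip_symmetry(rng):
    """Negating a continuous trait swaps the roles of the one-sided
    statistics, leaving wAF_d unchanged on the full enumeration set."""
    y, g = random_dataset(rng, n=6, k=2, trait_type="continuous")
    perms = np.array(list(itertools.permutations(range(6))))
    r1 = run_test(y, g, method="wafd", permutations=perms)
    y_neg = TraitVector(-y.values, trait_type="continuous")
    r2 = run_test(y_neg, g, method="wafd", permutations=perms)
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
    assert r1.pvalue == pytest.approx(r2.pvalue, abs=1e-12)
    c1, c2 = r1.components, r2.components
    assert c1["t_plus"] == pytest.approx(c2["t_minus"], abs=1e-12)
    assert c1["t_minus"] == pytest.approx(c2["t_plus"], abs=1e-12)


def test_adjusted_model_permutes_null_residuals(rng):
    """With covariates the permuted scores use e = Y - mu_hat against
    covariate-residualized genotypes; test runs end to end and keeps the
    p-value floor."""
    from waftest import CovariateMatrix

    n = 60
    c = rng.standard_normal((n, 1))
    y = (rng.random(n) < 0.5).astype(float)
    g = rng.integers(0, 3, size=(n, 3)).astype(float)
    res = run_test(
        TraitVector(y), GenotypeMatrix(g), covariates=CovariateMatrix(c),
        method="waf", b=150, seed=1,
    )
    assert 1 / 151 <= res.pvalue <= 1.0


def test_adaptive_scan_escalates_only_small_pvalues(rng):
    """Null genes stop at the initial budget; a strongly associated gene
    escalates by the 5/B rule until the cap censors it."""
    n = 300
    genes = []
    for j in range(4):
        y, g = random_dataset(rng, n=n, k=4, trait_type="binary")
        genes.append((f"null{j}", y, g, None))
    # planted signal: trait tracks the genotype burden closely
    gsig = rng.integers(0, 3, size=(n, 4)).astype(float)
    score = gsig.sum(1) + 0.2 * rng.standard_normal(n)
    ysig = (score > np.median(score)).astype(float)
    genes.append(("signal", TraitVector(ysig), GenotypeMatrix(gsig), None))

    policy = ScanPolicy(b_initial=50, escalation_factor=10, b_max=5000)
    df = adaptive_scan(genes, policy=policy, method="waf", seed=7)
    df = df.set_index("gene_id")
    sig = df.loc["signal"]
    assert sig["b_final"] == 5000
    assert sig["rounds"] == (50, 500, 5000)
    assert sig["censored"]
    assert sig["pvalue"] < 5 / 5000
    for j in range(4):
        row = df.loc[f"null{j}"]
        if row["pvalue"] >= 5 / 50:
            assert row["b_final"] == 50 and row["rounds"] == (50,)
        assert not row["censored"] or row["b_final"] == 5000


def test_run_wafd_test_wrapper(toy_continuous):
    y, g = toy_continuous
    res = run_wafd_test(y, g, b=99, seed=3)
    assert res.method == "wafd"
    assert res.statistic == pytest.approx(
        min(res.components.values()), abs=1e-15
    )
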