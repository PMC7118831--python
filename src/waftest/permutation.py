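"""Permutation calibration of the AF/wAF/wAF_d/Min-P set tests.

The null distribution is built by permuting trait residuals: with
``e_i = Y_i - Ybar`` (marginal model) or ``e_i = Y_i - mu_hat_i``
(covariate-adjusted model), each of B permutations ``e(b)`` of the residual
vector yields permuted scores ``U(b) = sum_i e(b)_i g_i`` against the fixed
(possibly covariate-residualized) genotypes ``g_i``, standardized by the
*observed* ``V_kk``.  Observed and permuted replicates are then pushed
through the identical marginal-p -> -log -> weight -> sort -> partial-sum
pipeline, partial-sum p-values are obtained by inclusive counting over all
B+1 profiles, and the final p-value counts how many permutation statistics
are at least as extreme (small) as the observed one:

``p_hat = (1/(B+1)) * #{b in 1..B : T(b) <= T(0)}``

floored at ``1/(B+1)`` (an estimate of exactly zero is not attainable from
B permutations).

``adaptive_scan`` implements the step-up budget used for genome-wide scans:
every gene starts at a small B, and only genes whose estimated p-value
falls below ``5/B`` are re-run with B multiplied by 10, until no gene is
below threshold or a cap is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import afstats
from .afstats import TestResult, WeightVector
from .containers import (
    CovariateMatrix,
    GenotypeMatrix,
    TraitVector,
    as_covariates,
    as_genotypes,
    as_trait,
)
from .exceptions import DegenerateTraitError
from .score import compute_score_adjusted, compute_score_marginal

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationPlan",
    "ScanPolicy",
    "run_test",
    "run_wafd_test",
    "run_all_methods",
    "adaptive_scan",
]

METHODS = ("af", "waf", "wafd", "minp")

# rows of permuted residuals scored per block, to bound peak memory
_BLOCK_ELEMENTS = 4_000_000


@dataclass
class PermutationPlan:
    """How many permutations to draw and from which seed."""

    b: int = 1000
    seed: Optional[int] = 0
    residual_mode: str = "auto"  # {"auto", "marginal", "adjusted"}

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("B must be >= 1")


@dataclass
class ScanPolicy:
    """Step-up permutation budget for multi-gene scans.

    Genes are first tested with ``b_initial`` permutations; any gene whose
    estimated p-value is below ``threshold_numerator / B`` is re-tested
    with B multiplied by ``escalation_factor``, until no gene is below
    threshold or ``b_max`` is reached (then flagged censored).
    """

    b_initial: int = 100
    escalation_factor: int = 10
    threshold_numerator: float = 5.0
    b_max: int = 1_000_000

    def __post_init__(self) -> None:
        if self.b_initial < 1:
            raise ValueError("b_initial must be >= 1")
        if self.escalation_factor < 2:
            raise ValueError("escalation_factor must be >= 2")
        if self.b_max < self.b_initial:
            raise ValueError("b_max must be >= b_initial")


def _prepare_null(y: TraitVector, g: GenotypeMatrix, c):
    """Residuals, effective genotypes and fixed V_kk for the null."""
    if c is None:
        score = compute_score_marginal(y, g)
    else:
        score = compute_score_adjusted(y, g, c)
    e = score.residuals
    if np.ptp(e) == 0:
        raise DegenerateTraitError("residual vector is constant")
    vkk = np.diag(score.v).copy()
    return e, score.genotype_residuals, vkk, score


def _permuted_scores(
    e: np.ndarray,
    g_eff: np.ndarray,
    b: int,
    rng: np.random.Generator,
    permutations: Optional[np.ndarray] = None,
) -> np.ndarray:
    """(B+1) x K score matrix; row 0 is the observed score vector.

    Permutations are uniform over the symmetric group (sampled with
    replacement via random-key argsort) unless an explicit index array is
    supplied — used e.g. to enumerate all n! orderings exactly on tiny n.
    """
    n = e.size
    if permutations is not None:
        permutations = np.asarray(permutations, dtype=int)
        if permutations.ndim != 2 or permutations.shape[1] != n:
            raise ValueError("permutations must be a B x n index array")
        b = permutations.shape[0]
    u = np.empty((b + 1, g_eff.shape[1]))
    u[0] = e @ g_eff
    block = max(1, _BLOCK_ELEMENTS // n)
    for start in range(0, b, block):
        stop = min(start + block, b)
        if permutations is None:
            keys = rng.random((stop - start, n))
            idx = np.argsort(keys, axis=1)
        else:
            idx = permutations[start:stop]
        u[1 + start : 1 + stop] = e[idx] @ g_eff
    return u


def _marginal_p_matrix(u: np.ndarray, vkk: np.ndarray, side: str) -> np.ndarray:
    ut = u / np.sqrt(vkk)
    if side == "two":
        p = 2.0 * ndtr(-np.abs(ut))
    elif side == "plus":
        p = ndtr(-ut)
    elif side == "minus":
        p = ndtr(ut)
    else:  # pragma: no cover
        raise ValueError(side)
    return afstats.clamp_pvalues(p)


def _af_t_vector(p: np.ndarray, w: np.ndarray):
    """Partial-sum p-values and per-replicate statistics from marginal p's."""
    x = w * (-np.log(p))
    s_all = afstats.sorted_partial_sum_matrix(x)
    p_all = afstats.partial_sum_pvalues_all(s_all)
    return p_all.min(axis=1), p_all


def _final_pvalue(t: np.ndarray, b: int) -> float:
    count = int(np.sum(t[1:] <= t[0]))
    return max(count, 1) / (b + 1)


def run_all_methods(
    y,
    g,
    covariates=None,
    weights: Optional[WeightVector] = None,
    methods: Sequence[str] = METHODS,
    b: int = 1000,
    seed=0,
    permutations: Optional[np.ndarray] = None,
) -> Dict[str, TestResult]:
    """Run several set tests on one shared block of permuted scores.

    All requested methods see exactly the same permutations, which makes
    power comparisons between them paired.  ``weights`` applies to wAF and
    wAF_d (default: MAF-based); AF and Min-P are unweighted by definition.
    """
    y = as_trait(y)
    g = as_genotypes(g)
    c = as_covariates(covariates)
    methods = [m.lower() for m in methods]
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    if weights is None:
        weights = afstats.default_weights(g)
    if weights.w.size != g.k:
        raise ValueError("weight vector length does not match K")

    e, g_eff, vkk, _ = _prepare_null(y, g, c)
    rng = np.random.default_rng(seed)
    u = _permuted_scores(e, g_eff, b, rng, permutations=permutations)
    b_eff = u.shape[0] - 1

    p_two = _marginal_p_matrix(u, vkk, "two")
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    flat = np.ones(g.k)

    results: Dict[str, TestResult] = {}
    t_waf = p_waf = None
    if {"waf", "wafd"} & set(methods):
        t_waf, p_waf = _af_t_vector(p_two, weights.w)
    if "af" in methods:
        t_af, p_af = _af_t_vector(p_two, flat)
        results["af"] = TestResult(
            statistic=float(t_af[0]),
            pvalue=_final_pvalue(t_af, b_eff),
            partial_pvalues=p_af[0],
            method="af",
            b=b_eff,
            seed=seed_int,
            n_variants=g.k,
        )
    if "waf" in methods:
        results["waf"] = TestResult(
            statistic=float(t_waf[0]),
            pvalue=_final_pvalue(t_waf, b_eff),
            partial_pvalues=p_waf[0],
            method="waf",
            b=b_eff,
            seed=seed_int,
            n_variants=g.k,
        )
    if "wafd" in methods:
        p_plus = _marginal_p_matrix(u, vkk, "plus")
        p_minus = _marginal_p_matrix(u, vkk, "minus")
        t_plus, _ = _af_t_vector(p_plus, weights.w)
        t_minus, _ = _af_t_vector(p_minus, weights.w)
        t_d = np.minimum(t_waf, np.minimum(t_plus, t_minus))
        results["wafd"] = TestResult(
            statistic=float(t_d[0]),
            pvalue=_final_pvalue(t_d, b_eff),
            partial_pvalues=p_waf[0],
            method="wafd",
            b=b_eff,
            seed=seed_int,
            n_variants=g.k,
            components={
                "t_waf": float(t_waf[0]),
                "t_plus": float(t_plus[0]),
                "t_minus": float(t_minus[0]),
            },
        )
    if "minp" in methods:
        t_minp = p_two.min(axis=1)
        results["minp"] = TestResult(
            statistic=float(t_minp[0]),
            pvalue=_final_pvalue(t_minp, b_eff),
            partial_pvalues=p_two[0],
            method="minp",
            b=b_eff,
            seed=seed_int,
            n_variants=g.k,
        )
    return results


def run_test(
    y,
    g,
    covariates=None,
    weights: Optional[WeightVector] = None,
    method: str = "waf",
    b: int = 1000,
    seed=0,
    plan: Optional[PermutationPlan] = None,
    permutations: Optional[np.ndarray] = None,
) -> TestResult:
    """Permutation-calibrated set test (single method).

    See :func:`run_all_methods` for the shared mechanics; ``plan`` may be
    supplied instead of ``b``/``seed``.
    """
    if plan is not None:
        b, seed = plan.b, plan.seed
    return run_all_methods(
        y,
        g,
        covariates=covariates,
        weights=weights,
        methods=[method],
        b=b,
        seed=seed,
        permutations=permutations,
    )[method.lower()]


def run_wafd_test(y, g, covariates=None, weights=None, b=1000, seed=0,
                  plan: Optional[PermutationPlan] = None) -> TestResult:
    """Directed wAF test: minimum of the two-sided and both one-sided wAF
    statistics, all computed on the same permutations."""
    return run_test(
        y, g, covariates=covariates, weights=weights, method="wafd",
        b=b, seed=seed, plan=plan,
    )


def _child_seed(seed: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(seed), *map(int, path)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def adaptive_scan(
    genes: Iterable[tuple],
    policy: Optional[ScanPolicy] = None,
    method: str = "waf",
    weights: str = "maf",
    seed: int = 0,
) -> pd.DataFrame:
    """Step-up permutation scan over a panel of gene SNV sets.

    Parameters
    ----------
    genes
        Iterable of ``(gene_id, trait, genotypes, covariates_or_None)``.
    policy
        Escalation policy; defaults to B=100 start, x10 per round,
        continue while ``p_hat < 5/B``, cap at 1e6.
    weights
        ``"maf"`` (default) or ``"flat"``.

    Returns a DataFrame with one row per gene: final p-value, final B,
    the rounds visited and a ``censored`` flag set when the cap stopped
    an escalation that the 5/B rule would have continued.
    """
    policy = policy or ScanPolicy()
    rows = []
    for gi, (gene_id, y, g, c) in enumerate(genes):
        y = as_trait(y)
        g = as_genotypes(g)
        w = (
            afstats.default_weights(g)
            if weights == "maf"
            else afstats.flat_weights(g.k)
        )
        b = policy.b_initial
        rounds = []
        rnd = 0
        while True:
            res = run_test(
                y, g, covariates=c, weights=w, method=method, b=b,
                seed=_child_seed(seed, gi, rnd),
            )
            rounds.append(b)
            wants_more = res.pvalue < policy.threshold_numerator / b
            if not wants_more or b >= policy.b_max:
                censored = wants_more and b >= policy.b_max
                break
            b = min(b * policy.escalation_factor, policy.b_max)
            rnd += 1
        rows.append(
            {
                "gene_id": gene_id,
                "n_variants": g.k,
                "method": method,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "b_final": res.b,
                "rounds": tuple(rounds),
                "censored": censored,
            }
        )
    return pd.DataFrame(rows)
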