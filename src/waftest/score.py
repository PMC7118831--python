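"""Per-variant score statistics for trait-genotype association.

For a set of K variants the score vector is ``U_k = sum_i (Y_i - mu_i) G_ik``
(with ``mu_i = Ybar`` in the marginal model, or the covariate-null fitted
mean in the adjusted model, where the genotype is additionally replaced by
its residual against the covariates).  The null covariance ``V`` factors
into a trait-variance scalar times the centered genotype cross-product
matrix:

* binary, marginal:      ``V = Ybar (1 - Ybar) * Gc' Gc``
* continuous, marginal:  ``V = s2_Y * Gc' Gc``           (s2_Y unbiased)
* binary, adjusted:      ``V = mean(mu (1 - mu)) * Gr' Gr``
* continuous, adjusted:  ``V = s2_e * Gr' Gr``           (s2_e from residuals)

where ``Gc`` is the column-centered genotype matrix and ``Gr`` the matrix of
per-variant OLS residuals of genotype on (intercept + covariates).

Standardized scores ``U_k / sqrt(V_kk)`` are asymptotically N(0, 1) under
the null, giving two-sided and directional marginal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import ndtr

from .containers import CovariateMatrix, GenotypeMatrix, TraitVector
from .exceptions import DegenerateVariantError, FitFailureError

__all__ = [
    "ScoreResult",
    "MarginalPValues",
    "compute_score_marginal",
    "compute_score_adjusted",
    "standardize_and_pvalues",
]


@dataclass
class ScoreResult:
    """Score vector ``U`` and its estimated null covariance ``V``.

    ``residuals`` (``Y - mu``) and ``genotype_residuals`` (``G`` centered
    or covariate-adjusted) are retained because the permutation engine
    rebuilds permuted scores as ``e(b) @ genotype_residuals`` while holding
    ``V`` fixed at its observed value.
    """

    u: np.ndarray
    v: np.ndarray
    sigma_sq: float
    model: str  # {"marginal", "adjusted"}
    trait_type: str
    residuals: Optional[np.ndarray] = field(default=None, repr=False)
    genotype_residuals: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.u.size

    def standardized(self) -> np.ndarray:
        vkk = np.diag(self.v)
        if np.any(vkk <= 0):
            raise DegenerateVariantError(
                "zero-variance variant: V_kk = 0, standardized score undefined"
            )
        return self.u / np.sqrt(vkk)


@dataclass
class MarginalPValues:
    """Two-sided and directional marginal p-values per variant.

    By construction ``p_plus + p_minus == 1`` entrywise and
    ``p_two == 2 * min(p_plus, p_minus)``.
    """

    p_two: np.ndarray
    p_plus: np.ndarray
    p_minus: np.ndarray


def _check_columns(g: GenotypeMatrix) -> None:
    if np.any(g.column_variances() <= 0):
        bad = [
            v
            for v, s in zip(g.variant_ids, g.column_variances())
            if s <= 0
        ]
        raise DegenerateVariantError(
            f"zero-variance variant column(s): {bad}; filter before scoring"
        )


def compute_score_marginal(
    y: TraitVector, g: GenotypeMatrix
) -> ScoreResult:
    """Score statistics without covariate adjustment."""
    yv, gm = y.values, g.counts
    if gm.shape[0] != yv.size:
        raise ValueError("trait and genotype matrix have different n")
    _check_columns(g)
    e = yv - yv.mean()
    u = e @ gm
    gc = gm - gm.mean(axis=0)
    m = gc.T @ gc
    if y.trait_type == "binary":
        ybar = yv.mean()
        sigma_sq = ybar * (1.0 - ybar)
    else:
        sigma_sq = yv.var(ddof=1)
    return ScoreResult(
        u=u,
        v=sigma_sq * m,
        sigma_sq=float(sigma_sq),
        model="marginal",
        trait_type=y.trait_type,
        residuals=e,
        genotype_residuals=gm,
    )


def compute_score_adjusted(
    y: TraitVector, g: GenotypeMatrix, c: CovariateMatrix
) -> ScoreResult:
    """Score statistics adjusted for covariates.

    The trait null model (intercept + covariates; logistic for binary,
    linear for continuous) gives fitted means ``mu``; each genotype column
    is replaced by its OLS residual against the same design.
    """
    import statsmodels.api as sm

    yv, gm = y.values, g.counts
    if gm.shape[0] != yv.size:
        raise ValueError("trait and genotype matrix have different n")
    _check_columns(g)
    x = c.with_intercept()
    if x.shape[0] != yv.size:
        raise ValueError("covariates and trait have different n")

    if y.trait_type == "binary":
        try:
            fit = sm.GLM(yv, x, family=sm.families.Binomial()).fit(
                tol=1e-8, maxiter=100
            )
        except Exception as exc:  # statsmodels raises PerfectSeparation etc.
            raise FitFailureError(f"logistic null fit failed: {exc}") from exc
        if not fit.converged:
            raise FitFailureError("logistic null fit did not converge")
        mu = fit.fittedvalues
        if np.any(mu <= 0) or np.any(mu >= 1):
            raise FitFailureError(
                "logistic null fit produced degenerate fitted probabilities"
            )
        sigma_sq = float(np.mean(mu * (1.0 - mu)))
    else:
        fit = sm.OLS(yv, x).fit()
        mu = fit.fittedvalues
        e = yv - mu
        sigma_sq = float(np.sum((e - e.mean()) ** 2) / (yv.size - 1))

    # per-variant OLS of genotype on (intercept + covariates), vectorized
    coef, *_ = np.linalg.lstsq(x, gm, rcond=None)
    g_res = gm - x @ coef

    e = yv - mu
    u = e @ g_res
    v = sigma_sq * (g_res.T @ g_res)
    return ScoreResult(
        u=u,
        v=v,
        sigma_sq=sigma_sq,
        model="adjusted",
        trait_type=y.trait_type,
        residuals=e,
        genotype_residuals=g_res,
    )


def standardize_and_pvalues(score: ScoreResult) -> MarginalPValues:
    """Marginal p-values from standardized scores.

    ``p_plus`` is the one-sided p-value for a risk effect
    (``1 - Phi(U~_k)``), ``p_minus`` for a protective effect, and
    ``p_two = 2 [1 - Phi(|U~_k|)]``.  ``p_minus`` is computed as
    ``1 - p_plus`` so the pair sums to one exactly; the survival function
    ``ndtr(-u)`` keeps tail p-values accurate without cancellation.
    """
    ut = score.standardized()
    p_plus = ndtr(-ut)
    p_minus = 1.0 - p_plus
    p_two = 2.0 * np.minimum(p_plus, p_minus)
    return MarginalPValues(p_two=p_two, p_plus=p_plus, p_minus=p_minus)
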