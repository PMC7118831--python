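"""Adaptive Fisher statistics: sorted weighted partial sums of -log p.

The family combines K marginal p-values by transforming them to
``R_k = -log p_k``, weighting (``X_k = w_k R_k``), sorting the X's in
descending order, and taking partial sums ``S*_k = X_(1) + ... + X_(k)``.
Each partial sum gets a permutation p-value by inclusive counting over the
B permutation profiles plus the observed one, and the test statistic is
the minimum of those K partial-sum p-values — small when *some* prefix of
the strongest variants is jointly extreme, which is what makes the test
adaptive to dense and sparse signal alike.

Default weights are ``w_k = sqrt(f_k (1 - f_k))`` with ``f_k`` the
in-sample allele frequency; the formula is symmetric in ``f`` versus
``1 - f`` and therefore invariant to allele flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WeightVector",
    "PartialSumProfile",
    "TestResult",
    "neglog_transform",
    "weighted_partial_sums",
    "partial_sum_pvalues",
    "partial_sum_pvalues_all",
    "af_statistic",
    "wafd_statistic",
    "default_weights",
]

_TINY = np.finfo(float).tiny


@dataclass
class WeightVector:
    """Nonnegative per-variant weights with their provenance."""

    w: np.ndarray
    source: str = "user"  # {"default_maf", "user", "flat"}

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float).ravel()
        if w.size == 0:
            raise ValueError("empty weight vector")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.any(w > 0):
            raise ValueError("at least one weight must be positive")
        self.w = w


@dataclass
class PartialSumProfile:
    """-log p values, their weighted version, and sorted partial sums."""

    r: np.ndarray
    x: np.ndarray
    s_star: np.ndarray


@dataclass
class TestResult:
    """Outcome of one permutation-calibrated set test.

    ``statistic`` is the observed test statistic (the minimum partial-sum
    p-value for AF/wAF, the minimum of the three directional statistics for
    wAF_d, the smallest marginal p-value for Min-P).  ``partial_pvalues``
    are the observed per-k partial-sum p-values (for Min-P, the observed
    marginal p-values).  ``components`` carries the observed directional
    statistics for wAF_d.
    """

    statistic: float
    pvalue: float
    partial_pvalues: np.ndarray
    method: str
    b: int
    seed: Optional[int] = None
    n_variants: int = 0
    censored: bool = False
    components: Optional[dict] = None

    @property
    def k_hat(self) -> int:
        """1-based index of the partial sum attaining the minimum p-value."""
        return int(np.argmin(self.partial_pvalues)) + 1


def neglog_transform(p: np.ndarray) -> np.ndarray:
    """Elementwise natural ``-log p`` for p in (0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return -np.log(p)


def clamp_pvalues(p: np.ndarray) -> np.ndarray:
    """Clamp floating-point underflow to the smallest positive normal.

    A p-value of exactly 0 can only arise by underflow of the normal
    survival function (|U~| > ~38); the clamp keeps -log p finite.
    """
    if np.any(p < _TINY):
        logger.warning("p-value underflow clamped to %.3e", _TINY)
        p = np.maximum(p, _TINY)
    return p


def weighted_partial_sums(r: np.ndarray, w: WeightVector) -> PartialSumProfile:
    """Weight, sort descending, and accumulate: ``S*_k = sum of k largest
    w*R``."""
    r = np.asarray(r, dtype=float).ravel()
    if np.any(r < 0):
        raise ValueError("-log p values must be nonnegative")
    if r.size != w.w.size:
        raise ValueError("weight/R length mismatch")
    x = w.w * r
    s_star = np.cumsum(np.sort(x)[::-1])
    return PartialSumProfile(r=r, x=x, s_star=s_star)


def sorted_partial_sum_matrix(x: np.ndarray) -> np.ndarray:
    """Row-wise descending sort + cumulative sum for a matrix of X values."""
    return np.cumsum(np.sort(x, axis=1)[:, ::-1], axis=1)


def partial_sum_pvalues(s_star_all: np.ndarray, b_star: int = 0) -> np.ndarray:
    """Inclusive-counting p-value of row ``b_star``'s partial sums.

    ``P_{S*_k} = #{b : S*_k(b) >= S*_k(b_star)} / (B + 1)`` over all B+1
    rows (observed profile in row 0).  Counting is inclusive of the row
    itself, so every value is at least ``1/(B+1)``.
    """
    s = np.asarray(s_star_all, dtype=float)
    if s.ndim != 2:
        raise ValueError("expected a (B+1) x K matrix of profiles")
    return (s >= s[b_star]).sum(axis=0) / s.shape[0]


def partial_sum_pvalues_all(s_star_all: np.ndarray) -> np.ndarray:
    """Inclusive-counting p-values for *every* row at once.

    Equivalent to stacking :func:`partial_sum_pvalues` over all b*, but
    computed in O(B log B) per column via min-ranks:
    ``#{x >= s} = B + 1 - #{x < s} = B + 1 - (rank_min(s) - 1)``.
    """
    s = np.asarray(s_star_all, dtype=float)
    m = s.shape[0]
    ranks = rankdata(s, method="min", axis=0)
    return (m - ranks + 1) / m


def af_statistic(partial_pvalues: np.ndarray) -> float:
    """The adaptive Fisher statistic: minimum partial-sum p-value."""
    p = np.asarray(partial_pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty partial p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("partial p-values must lie in (0, 1]")
    return float(p.min())


def wafd_statistic(t_two: float, t_plus: float, t_minus: float) -> float:
    """Directed statistic: minimum of the two-sided and both one-sided
    wAF statistics."""
    return float(min(t_two, t_plus, t_minus))


def default_weights(g: GenotypeMatrix) -> WeightVector:
    """MAF-based weights ``w_k = sqrt(f_k (1 - f_k))``.

    These approximate the per-variant genotype standard deviation (up to a
    factor sqrt(2) under Hardy-Weinberg), mildly up-weighting common
    variants relative to flat weights.
    """
    f = g.allele_frequencies()
    return WeightVector(w=np.sqrt(f * (1.0 - f)), source="default_maf")


def flat_weights(k: int) -> WeightVector:
    return WeightVector(w=np.ones(k), source="flat")
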