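"""Synthetic genotype/trait generator and power estimation.

Genotypes mimic linkage disequilibrium with a latent-Gaussian threshold
model: each haplotype h of subject i draws ``Z_h ~ N(0, A)`` with AR(1)
correlation ``A_{kk'} = c^{|k-k'|}`` (default c = 0.9), and the genotype is
the number of haplotypes whose latent value falls below the MAF quantile,

    G_ik = I(Phi(Z_1k) <= MAF_k) + I(Phi(Z_2k) <= MAF_k)  in {0, 1, 2}.

MAFs are redrawn for every simulated dataset, log-uniform on
[0.001, 0.5] by default or uniform on [0.001, 0.01] for the all-rare
regime.  Effects are sparse: round(pi*K) positions get nonzero beta drawn
uniformly from [-delta, delta] (or [0, delta] for same-direction effects),
the rest are exactly zero.  Binary traits come from a logistic model with
zero intercept (prevalence 0.5 under the null); continuous traits add
standard normal noise to the linear predictor.

``estimate_power`` ties it together: simulate datasets, run one or more
set tests with paired permutations, and report empirical rejection rates
with exact binomial confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence
import logging

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import beta as beta_dist

from . import afstats
from .containers import GenotypeMatrix, TraitVector
from .exceptions import ConfigError
from .permutation import run_all_methods

logger = logging.getLogger(__name__)

__all__ = [
    "SimScenario",
    "EffectVector",
    "PowerEstimate",
    "simulate_genotypes",
    "sample_effects",
    "simulate_trait",
    "simulate_dataset",
    "estimate_power",
]


@dataclass
class SimScenario:
    """All knobs of one simulation condition.

    Defaults follow the reference study design: n = 1,000 subjects,
    AR(1) latent correlation c = 0.9, log-uniform MAFs on [0.001, 0.5],
    two-sided uniform effects.
    """

    n: int = 1000
    k: int = 50
    c: float = 0.9
    maf_mode: str = "loguniform"  # {"loguniform", "rare_uniform"}
    maf_range: Optional[tuple] = None
    pi: float = 0.0
    delta: float = 0.0
    trait_type: str = "binary"
    effect_mode: str = "two_sided"  # {"two_sided", "one_sided"}
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.n >= 2 and self.k >= 1):
            raise ConfigError("need n >= 2 and K >= 1")
        if not (0 <= self.c < 1):
            raise ConfigError("AR(1) parameter c must be in [0, 1)")
        if not (0 <= self.pi <= 1):
            raise ConfigError("effect proportion pi must be in [0, 1]")
        if self.delta < 0:
            raise ConfigError("effect size delta must be >= 0")
        if self.maf_mode not in ("loguniform", "rare_uniform"):
            raise ConfigError(f"unknown maf_mode {self.maf_mode!r}")
        if self.trait_type not in ("binary", "continuous"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")
        if self.effect_mode not in ("two_sided", "one_sided"):
            raise ConfigError(f"unknown effect_mode {self.effect_mode!r}")
        if self.maf_range is None:
            self.maf_range = (
                (0.001, 0.5) if self.maf_mode == "loguniform" else (0.001, 0.01)
            )
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigError("MAF range must satisfy 0 < lo < hi <= 0.5")


@dataclass
class EffectVector:
    """Sparse per-variant effect sizes."""

    beta: np.ndarray
    nonzero_indices: np.ndarray


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _ar1_normal(rng: np.random.Generator, m: int, k: int, c: float) -> np.ndarray:
    """m draws from N(0, A) with A_{kk'} = c^{|k-k'|} via the AR(1)
    recursion Z_k = c Z_{k-1} + sqrt(1-c^2) eps_k (exact, O(mK))."""
    eps = rng.standard_normal((m, k))
    z = np.empty((m, k))
    z[:, 0] = eps[:, 0]
    s = np.sqrt(1.0 - c * c)
    for j in range(1, k):
        z[:, j] = c * z[:, j - 1] + s * eps[:, j]
    return z


def sample_mafs(scenario: SimScenario, rng) -> np.ndarray:
    rng = _rng(rng)
    lo, hi = scenario.maf_range
    if scenario.maf_mode == "loguniform":
        return np.exp(rng.uniform(np.log(lo), np.log(hi), scenario.k))
    return rng.uniform(lo, hi, scenario.k)


def simulate_genotypes(scenario: SimScenario, rng=None) -> GenotypeMatrix:
    """One n x K genotype draw under the latent-Gaussian AR(1) model.

    MAFs are drawn fresh for this dataset; they are recorded on the
    returned matrix as ``true_mafs`` (the tests themselves always use
    in-sample frequencies, never the generating values).
    """
    rng = _rng(rng if rng is not None else scenario.seed)
    mafs = sample_mafs(scenario, rng)
    thr = ndtri(mafs)  # Phi(Z) <= maf  <=>  Z <= Phi^-1(maf)
    z = _ar1_normal(rng, 2 * scenario.n, scenario.k, scenario.c)
    g = (z[: scenario.n] <= thr).astype(float) + (
        z[scenario.n :] <= thr
    ).astype(float)
    gm = GenotypeMatrix(counts=g)
    gm.true_mafs = mafs
    return gm


def sample_effects(scenario: SimScenario, rng=None) -> EffectVector:
    """round(pi*K) nonzero effects, uniform on [-delta, delta] or
    [0, delta]; all other entries exactly zero."""
    rng = _rng(rng if rng is not None else scenario.seed)
    m = int(np.rint(scenario.pi * scenario.k))
    if scenario.pi > 0 and m == 0:
        logger.warning(
            "pi=%g with K=%d rounds to zero nonzero effects; "
            "scenario degenerates to the null",
            scenario.pi,
            scenario.k,
        )
    beta = np.zeros(scenario.k)
    idx = rng.choice(scenario.k, size=m, replace=False) if m else np.array([], int)
    if m:
        if scenario.effect_mode == "two_sided":
            beta[idx] = rng.uniform(-scenario.delta, scenario.delta, m)
        else:
            beta[idx] = rng.uniform(0.0, scenario.delta, m)
    return EffectVector(beta=beta, nonzero_indices=np.sort(idx))


def simulate_trait(
    g: GenotypeMatrix, beta: EffectVector, trait_type: str, rng=None
) -> TraitVector:
    """Trait from the generalized linear model with zero intercept.

    Binary: Y_i ~ Bernoulli(expit(sum_k beta_k G_ik)); continuous:
    Y_i = sum_k beta_k G_ik + eps_i with standard normal errors.
    """
    rng = _rng(rng)
    eta = g.counts @ beta.beta
    if trait_type == "binary":
        y = (rng.random(g.n) < expit(eta)).astype(float)
    else:
        y = eta + rng.standard_normal(g.n)
    return TraitVector(values=y, trait_type=trait_type)


def simulate_dataset(scenario: SimScenario, rng=None):
    """(trait, genotypes, effects) triple for one replicate."""
    rng = _rng(rng if rng is not None else scenario.seed)
    g = simulate_genotypes(scenario, rng)
    eff = sample_effects(scenario, rng)
    y = simulate_trait(g, eff, scenario.trait_type, rng)
    return y, g, eff


@dataclass
class PowerEstimate:
    """Empirical rejection rates with exact (Clopper-Pearson) CIs."""

    scenario: SimScenario
    alpha: float
    reps: int
    b: int
    power: Dict[str, float]
    ci_low: Dict[str, float]
    ci_high: Dict[str, float]
    pvalues: pd.DataFrame = field(repr=False, default=None)

    def mc_se(self, method: str) -> float:
        """Monte-Carlo standard error of the rejection rate."""
        p = self.power[method]
        return float(np.sqrt(p * (1.0 - p) / self.reps))


def _clopper_pearson(x: int, n: int, level: float = 0.95):
    a = 1.0 - level
    lo = beta_dist.ppf(a / 2, x, n - x + 1) if x > 0 else 0.0
    hi = beta_dist.ppf(1 - a / 2, x + 1, n - x) if x < n else 1.0
    return float(lo), float(hi)


def estimate_power(
    scenario: SimScenario,
    methods: Sequence[str] = ("waf",),
    alpha: float = 0.05,
    reps: int = 500,
    b: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
) -> PowerEstimate:
    """Empirical rejection rate of one or more set tests.

    Every replicate simulates a fresh dataset (fresh MAFs, genotypes,
    effects and trait), drops monomorphic variants, and runs all requested
    methods on one shared permutation block so their powers are paired.
    Replicate streams are spawned from ``seed`` so results do not depend
    on execution order.
    """
    if isinstance(methods, str):
        methods = (methods,)
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(reps)
    records = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        y, g, _ = simulate_dataset(scenario, rng)
        g, _ = g.drop_monomorphic(log=False)
        res = run_all_methods(
            y,
            g,
            weights=afstats.default_weights(g),
            methods=methods,
            b=b,
            seed=rng,
        )
        rec = {"rep": r}
        for m in methods:
            rec[m] = res[m].pvalue
        records.append(rec)
    pvals = pd.DataFrame(records).set_index("rep")
    power, lo, hi = {}, {}, {}
    for m in methods:
        x = int((pvals[m] <= alpha).sum())
        power[m] = x / reps
        lo[m], hi[m] = _clopper_pearson(x, reps, ci_level)
    return PowerEstimate(
        scenario=scenario,
        alpha=alpha,
        reps=reps,
        b=b,
        power=power,
        ci_low=lo,
        ci_high=hi,
        pvalues=pvals,
    )
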