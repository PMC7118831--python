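"""Model/results interface for SNV-set association testing.

:class:`SNVSetTest` is built from a trait, a genotype matrix and optional
covariates, in the spirit of a statsmodels model object; :meth:`fit` runs
the permutation-calibrated test(s) and returns :class:`SNVSetTestResults`
with statistics, p-values, per-k partial-sum p-values and a ``summary()``
table.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import afstats
from .afstats import TestResult, WeightVector
from .containers import (
    CovariateMatrix,
    GenotypeMatrix,
    as_covariates,
    as_genotypes,
    as_trait,
)
from .permutation import METHODS, run_all_methods
from .score import compute_score_adjusted, compute_score_marginal, standardize_and_pvalues

__all__ = ["SNVSetTest", "SNVSetTestResults"]


class SNVSetTest:
    """Association test between a trait and a set of variants.

    Parameters
    ----------
    endog
        Trait values (length n); 0/1 vectors are treated as binary unless
        ``trait_type`` says otherwise.
    genotypes
        n x K minor-allele counts/dosages (array or
        :class:`~waftest.containers.GenotypeMatrix`).  Monomorphic columns
        are dropped with a warning at construction.
    exog
        Optional n x J covariates; when present the test permutes
        null-model residuals against covariate-adjusted genotypes.
    weights
        ``"maf"`` (default), ``"flat"``, or an explicit nonnegative vector
        of length K (after monomorphic filtering).
    """

    def __init__(
        self,
        endog,
        genotypes,
        exog=None,
        trait_type: str = "auto",
        weights: Union[str, np.ndarray, WeightVector] = "maf",
    ) -> None:
        self.endog = as_trait(endog, trait_type=trait_type)
        g = as_genotypes(genotypes)
        g, self.dropped_variants = g.drop_monomorphic()
        self.genotypes = g
        self.exog: Optional[CovariateMatrix] = as_covariates(exog)
        if self.genotypes.n != self.endog.n:
            raise ValueError("trait and genotypes have different n")
        if self.exog is not None and self.exog.values.shape[0] != self.endog.n:
            raise ValueError("covariates and trait have different n")
        self.weights = self._resolve_weights(weights)

    def _resolve_weights(self, weights) -> WeightVector:
        if isinstance(weights, WeightVector):
            return weights
        if isinstance(weights, str):
            if weights == "maf":
                return afstats.default_weights(self.genotypes)
            if weights == "flat":
                return afstats.flat_weights(self.genotypes.k)
            raise ValueError(f"unknown weight spec {weights!r}")
        return WeightVector(np.asarray(weights, dtype=float), source="user")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        trait: str,
        variants: Sequence[str],
        covariates: Optional[Sequence[str]] = None,
        **kwargs,
    ) -> "SNVSetTest":
        """Build from one DataFrame holding trait, genotype and covariate
        columns."""
        g = GenotypeMatrix(
            counts=data[list(variants)].to_numpy(float),
            variant_ids=list(variants),
            subject_ids=[str(i) for i in data.index],
        )
        c = None
        if covariates:
            c = CovariateMatrix(
                values=data[list(covariates)].to_numpy(float),
                names=list(covariates),
            )
        return cls(data[trait].to_numpy(float), g, exog=c, **kwargs)

    def score(self):
        """Observed score statistics U and covariance V (no permutation)."""
        if self.exog is None:
            return compute_score_marginal(self.endog, self.genotypes)
        return compute_score_adjusted(self.endog, self.genotypes, self.exog)

    def marginal_pvalues(self):
        """Per-variant two-sided and directional marginal p-values."""
        return standardize_and_pvalues(self.score())

    def fit(
        self,
        method: Union[str, Sequence[str]] = "waf",
        b: int = 1000,
        seed: int = 0,
    ) -> "SNVSetTestResults":
        """Run the permutation test(s).

        ``method`` is one of ``"af"``, ``"waf"``, ``"wafd"``, ``"minp"``,
        ``"all"``, or a sequence of those; all requested methods share one
        block of B permutations.
        """
        if method == "all":
            methods = list(METHODS)
        elif isinstance(method, str):
            methods = [method]
        else:
            methods = list(method)
        results = run_all_methods(
            self.endog,
            self.genotypes,
            covariates=self.exog,
            weights=self.weights,
            methods=methods,
            b=b,
            seed=seed,
        )
        return SNVSetTestResults(self, results, b=b, seed=seed)


class SNVSetTestResults:
    """Results of :meth:`SNVSetTest.fit`.

    Attributes
    ----------
    results
        Mapping method name -> :class:`~waftest.afstats.TestResult`.
    """

    def __init__(
        self, model: SNVSetTest, results: Dict[str, TestResult], b: int, seed
    ) -> None:
        self.model = model
        self.results = results
        self.b = b
        self.seed = seed

    def __getitem__(self, method: str) -> TestResult:
        return self.results[method.lower()]

    @property
    def pvalues(self) -> Dict[str, float]:
        return {m: r.pvalue for m, r in self.results.items()}

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": m,
                "statistic": r.statistic,
                "pvalue": r.pvalue,
                "k_hat": r.k_hat,
                "B": r.b,
            }
            for m, r in self.results.items()
        ]
        return pd.DataFrame(rows).set_index("method")

    def summary(self) -> str:
        m = self.model
        lines = [
            "SNV-set association test (adaptive Fisher family)",
            "=" * 58,
            f"subjects:           {m.endog.n}",
            f"trait type:         {m.endog.trait_type}",
            f"variants tested:    {m.genotypes.k}"
            + (
                f"  ({len(m.dropped_variants)} monomorphic dropped)"
                if m.dropped_variants
                else ""
            ),
            f"covariates:         {m.exog.j if m.exog is not None else 0}",
            f"weights:            {m.weights.source}",
            f"permutations (B):   {self.b}",
            "-" * 58,
            f"{'method':<8}{'statistic':>14}{'p-value':>14}{'k_hat':>8}",
        ]
        for name, r in self.results.items():
            lines.append(
                f"{name:<8}{r.statistic:>14.4g}{r.pvalue:>14.3e}{r.k_hat:>8d}"
            )
        lines.append("-" * 58)
        lines.append(
            "p-values are permutation estimates, floored at 1/(B+1) = "
            f"{1.0 / (self.b + 1):.3e}"
        )
        return "\n".join(lines)
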