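"""In-memory containers for traits, genotypes and covariates.

The central object is :class:`GenotypeMatrix`, an ``n x K`` matrix of
minor-allele counts (or imputed dosages in ``[0, 2]``) with per-variant
metadata.  Traits and covariates are thin validated wrappers around numpy
arrays; all heavy lifting happens in :mod:`waftest.score` and
:mod:`waftest.permutation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    CollinearityError,
    DegenerateTraitError,
    DegenerateVariantError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TraitVector",
    "GenotypeMatrix",
    "CovariateMatrix",
    "as_trait",
    "as_genotypes",
    "as_covariates",
]


@dataclass
class TraitVector:
    """A phenotype for ``n`` independent subjects.

    Parameters
    ----------
    values
        Length-``n`` numeric vector.  Binary traits must be coded 0/1
        (e.g. control/case).
    trait_type
        ``"binary"`` or ``"continuous"``.  When omitted, a vector whose
        values are a subset of ``{0, 1}`` is treated as binary.
    """

    values: np.ndarray
    trait_type: str = "auto"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 2:
            raise DegenerateTraitError("trait needs at least two subjects")
        if not np.all(np.isfinite(v)):
            raise DegenerateTraitError("trait contains non-finite values")
        if self.trait_type == "auto":
            self.trait_type = (
                "binary" if np.isin(v, (0.0, 1.0)).all() else "continuous"
            )
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary" and not np.isin(v, (0.0, 1.0)).all():
            raise DegenerateTraitError("binary trait must be coded 0/1")
        if np.ptp(v) == 0:
            raise DegenerateTraitError("trait is constant")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class GenotypeMatrix:
    """``n x K`` matrix of minor-allele counts/dosages in ``[0, 2]``.

    ``positions`` holds an optional ``(chrom, pos)`` pair per variant with
    1-based coordinates, as read from a VCF.
    """

    counts: np.ndarray
    variant_ids: Optional[Sequence[str]] = None
    positions: Optional[Sequence[tuple]] = None
    subject_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        g = np.asarray(self.counts, dtype=float)
        if g.ndim == 1:
            g = g[:, None]
        if g.ndim != 2 or g.shape[1] < 1:
            raise ValueError("genotype matrix must be 2-D with K >= 1")
        if np.isnan(g).any():
            raise ValueError(
                "genotype matrix contains missing values; impute at read time"
            )
        if g.min() < 0 or g.max() > 2:
            raise ValueError("genotype dosages must lie in [0, 2]")
        self.counts = g
        if self.variant_ids is None:
            self.variant_ids = [f"v{k}" for k in range(g.shape[1])]
        self.variant_ids = list(self.variant_ids)
        if len(self.variant_ids) != g.shape[1]:
            raise ValueError("variant_ids length mismatch")
        if self.positions is not None and len(self.positions) != g.shape[1]:
            raise ValueError("positions length mismatch")
        if self.subject_ids is not None:
            self.subject_ids = list(self.subject_ids)
            if len(self.subject_ids) != g.shape[0]:
                raise ValueError("subject_ids length mismatch")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """In-sample allele frequency per variant, ``mean(G_k) / 2``."""
        return self.counts.mean(axis=0) / 2.0

    def column_variances(self) -> np.ndarray:
        return self.counts.var(axis=0)

    def select(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            counts=self.counts[:, idx],
            variant_ids=[self.variant_ids[i] for i in idx],
            positions=(
                [self.positions[i] for i in idx] if self.positions else None
            ),
            subject_ids=self.subject_ids,
        )

    def drop_monomorphic(self, log: bool = True) -> tuple["GenotypeMatrix", list]:
        """Remove zero-variance (monomorphic) variants.

        Returns the filtered matrix and the list of dropped variant ids.
        Monomorphic columns have ``V_kk = 0`` and no defined standardized
        score, so they cannot enter any test.
        """
        keep = self.column_variances() > 0
        dropped = [v for v, k in zip(self.variant_ids, keep) if not k]
        if dropped and log:
            logger.warning(
                "dropping %d monomorphic variant(s): %s",
                len(dropped),
                ", ".join(map(str, dropped[:10]))
                + ("..." if len(dropped) > 10 else ""),
            )
        if not keep.any():
            raise DegenerateVariantError("all variants are monomorphic")
        if keep.all():
            return self, []
        return self.select(np.flatnonzero(keep)), dropped


@dataclass
class CovariateMatrix:
    """``n x J`` covariates; must be full rank after appending an intercept."""

    values: np.ndarray
    names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.values, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if not np.all(np.isfinite(c)):
            raise ValueError("covariates contain non-finite values")
        self.values = c
        if self.names is None:
            self.names = [f"c{j}" for j in range(c.shape[1])]
        self.names = list(self.names)
        if len(self.names) != c.shape[1]:
            raise ValueError("covariate names length mismatch")
        x = self.with_intercept()
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise CollinearityError(
                "covariate matrix is rank deficient after adding an intercept"
            )

    @property
    def j(self) -> int:
        return self.values.shape[1]

    def with_intercept(self) -> np.ndarray:
        return np.column_stack(
            [np.ones(self.values.shape[0]), self.values]
        )


def as_trait(y, trait_type: str = "auto") -> TraitVector:
    if isinstance(y, TraitVector):
        return y
    return TraitVector(np.asarray(y, dtype=float), trait_type=trait_type)


def as_genotypes(g) -> GenotypeMatrix:
    if isinstance(g, GenotypeMatrix):
        return g
    return GenotypeMatrix(np.asarray(g, dtype=float))


def as_covariates(c) -> Optional[CovariateMatrix]:
    if c is None or isinstance(c, CovariateMatrix):
        return c
    return CovariateMatrix(np.asarray(c, dtype=float))
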