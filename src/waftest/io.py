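"""Readers and writers for genotype, phenotype, covariate and region files.

Conventions
-----------
* VCF positions are 1-based; BED intervals are 0-based half-open.  A
  variant at 1-based position ``p`` falls in a flanked region
  ``[start - flank, end + flank)`` iff ``start - flank <= p - 1 < end + flank``.
* Genotype counts always refer to the in-sample minor allele: any variant
  whose alternate-allele frequency exceeds 0.5 is flipped (2 - count) and
  the flip logged.
* Missing genotypes are mean-imputed per variant; monomorphic variants are
  dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CovariateMatrix, GenotypeMatrix, TraitVector
from .exceptions import AlignmentError, WafError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRegion",
    "read_genotypes",
    "read_genotype_matrix",
    "read_vcf",
    "write_genotype_matrix",
    "read_trait",
    "read_covariates",
    "read_regions",
    "assign_variants",
    "align_subjects",
    "write_results_table",
]

DEFAULT_FLANK = 5000


@dataclass
class GeneRegion:
    """A gene interval (BED convention) with symmetric flanks applied."""

    gene_id: str
    chrom: str
    start: int
    end: int
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise WafError(
                f"region {self.gene_id}: start > end ({self.start} > {self.end})"
            )
        if self.flank < 0:
            raise WafError("flank must be nonnegative")

    @property
    def effective_start(self) -> int:
        return max(0, self.start - self.flank)

    @property
    def effective_end(self) -> int:
        return self.end + self.flank

    def contains(self, chrom: str, pos_1based: int) -> bool:
        return (
            str(chrom) == self.chrom
            and self.effective_start <= pos_1based - 1 < self.effective_end
        )


def _finalize_columns(
    counts: np.ndarray,
    variant_ids: List[str],
    positions: Optional[List[tuple]],
    subject_ids: List[str],
) -> GenotypeMatrix:
    """Impute missing entries, flip to minor allele, drop monomorphic."""
    counts = np.asarray(counts, dtype=float)
    keep, flips = [], []
    for k in range(counts.shape[1]):
        col = counts[:, k]
        miss = np.isnan(col)
        if miss.all():
            logger.warning("variant %s all-missing; dropped", variant_ids[k])
            continue
        freq = np.nanmean(col) / 2.0
        if freq > 0.5:
            col = 2.0 - col
            flips.append(variant_ids[k])
        if miss.any():
            col = np.where(np.isnan(col), np.nanmean(col), col)
        counts[:, k] = col
        keep.append(k)
    if flips:
        logger.warning(
            "flipped %d variant(s) to minor-allele counts: %s",
            len(flips),
            ", ".join(flips[:10]) + ("..." if len(flips) > 10 else ""),
        )
    if not keep:
        raise WafError("no usable variants in input")
    gm = GenotypeMatrix(
        counts=counts[:, keep],
        variant_ids=[variant_ids[k] for k in keep],
        positions=[positions[k] for k in keep] if positions else None,
        subject_ids=subject_ids,
    )
    gm, _ = gm.drop_monomorphic()
    return gm


def read_vcf(path: str, field: str = "GT") -> GenotypeMatrix:
    """Read biallelic variants from a VCF into minor-allele counts.

    ``field="GT"`` counts alternate alleles from the genotype calls;
    ``field="DS"`` reads imputed dosages.  Multi-allelic records are
    skipped with a warning; missing calls become NaN and are mean-imputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    cols, ids, pos = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s:%s", var.CHROM, var.POS
            )
            continue
        if field == "DS":
            ds = var.format("DS")
            if ds is None:
                raise WafError(f"no DS field at {var.CHROM}:{var.POS}")
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            col = np.empty(len(subjects))
            for i, gt in enumerate(var.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                col[i] = sum(a == 1 for a in alleles) if alleles else np.nan
        cols.append(col)
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        ids.append(vid)
        pos.append((str(var.CHROM), int(var.POS)))
    if not cols:
        raise WafError(f"no biallelic variants in {path}")
    return _finalize_columns(np.column_stack(cols), ids, pos, subjects)


def _positions_from_ids(ids: Sequence[str]) -> Optional[List[tuple]]:
    """Recover (chrom, pos) from ``chrom:pos[:ref:alt]``-style ids, if
    every id follows that convention."""
    out = []
    for vid in ids:
        parts = str(vid).split(":")
        if len(parts) < 2 or not parts[1].isdigit():
            return None
        out.append((parts[0], int(parts[1])))
    return out


def read_genotype_matrix(path: str) -> GenotypeMatrix:
    """Read a delimited numeric matrix: header of variant ids, first
    column subject ids.  Ids of the form ``chrom:pos[:ref:alt]`` also
    provide coordinates for region assignment."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    counts = df.to_numpy(dtype=float)
    positions = _positions_from_ids([str(c) for c in df.columns])
    return _finalize_columns(
        counts,
        [str(c) for c in df.columns],
        positions,
        [str(i) for i in df.index],
    )


def read_genotypes(path: str, fmt: str = "matrix", field: str = "GT") -> GenotypeMatrix:
    if fmt == "vcf":
        return read_vcf(path, field=field)
    if fmt == "matrix":
        return read_genotype_matrix(path)
    raise WafError(f"unknown genotype format {fmt!r}")


def write_genotype_matrix(gm: GenotypeMatrix, path: str) -> None:
    subj = gm.subject_ids or [f"s{i}" for i in range(gm.n)]
    df = pd.DataFrame(gm.counts, index=subj, columns=gm.variant_ids)
    df.index.name = "subject"
    df.to_csv(path, sep="\t")


def read_trait(path: str, column: Optional[str] = None,
               trait_type: str = "auto") -> tuple:
    """Read a phenotype table (subject id first column); returns
    ``(TraitVector, subject_ids)``."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    col = column or df.columns[0]
    y = TraitVector(df[col].to_numpy(float), trait_type=trait_type)
    return y, [str(i) for i in df.index]


def read_covariates(path: str) -> tuple:
    """Read a covariate table; returns ``(CovariateMatrix, subject_ids)``."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    c = CovariateMatrix(df.to_numpy(float), names=[str(c) for c in df.columns])
    return c, [str(i) for i in df.index]


def read_regions(path: str, flank: int = DEFAULT_FLANK) -> List[GeneRegion]:
    """Read gene regions from BED (chrom, start, end, name)."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise WafError(
                    f"{path}:{ln}: BED line needs chrom/start/end/name"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise WafError(f"{path}:{ln}: bad coordinates") from exc
            regions.append(
                GeneRegion(
                    gene_id=parts[3], chrom=parts[0], start=start, end=end,
                    flank=flank,
                )
            )
    if not regions:
        raise WafError(f"no regions in {path}")
    return regions


def assign_variants(
    gm: GenotypeMatrix, regions: Sequence[GeneRegion]
) -> Dict[str, List[int]]:
    """Map each region to the genotype-column indices inside its flanked
    interval.  A variant may belong to several overlapping regions."""
    if gm.positions is None:
        raise WafError("genotype matrix has no positions; use a VCF input")
    out: Dict[str, List[int]] = {}
    for reg in regions:
        idx = [
            k
            for k, (chrom, pos) in enumerate(gm.positions)
            if reg.contains(chrom, pos)
        ]
        out[reg.gene_id] = idx
    return out


def align_subjects(
    gm: GenotypeMatrix,
    trait_ids: Sequence[str],
    covar_ids: Optional[Sequence[str]] = None,
):
    """Check subject ids agree across files and return row orders mapping
    trait/covariate rows onto the genotype order.

    Alignment is by identifier, never by row order; a mismatch in the id
    *sets* raises :class:`AlignmentError` listing the offenders.
    """
    if gm.subject_ids is None:
        raise AlignmentError("genotype data carries no subject ids")
    gset = list(gm.subject_ids)
    orders = []
    for name, ids in (("phenotype", trait_ids), ("covariate", covar_ids)):
        if ids is None:
            orders.append(None)
            continue
        missing = sorted(set(gset) - set(ids))
        extra = sorted(set(ids) - set(gset))
        if missing or extra:
            raise AlignmentError(
                f"{name} file subject ids inconsistent with genotypes; "
                f"missing={missing[:5]} extra={extra[:5]}"
            )
        lookup = {s: i for i, s in enumerate(ids)}
        orders.append(np.array([lookup[s] for s in gset]))
    return tuple(orders)


def write_results_table(df: pd.DataFrame, path: str) -> None:
    """Tab-separated results, p-values in scientific notation (3 sig.
    digits), sorted by p-value."""
    out = df.copy()
    if "pvalue" in out.columns:
        out = out.sort_values("pvalue", kind="stable")
        out["pvalue"] = out["pvalue"].map(lambda p: f"{p:.2e}")
    if "statistic" in out.columns:
        out["statistic"] = out["statistic"].map(lambda s: f"{s:.2e}")
    out.to_csv(path, sep="\t", index=False)
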