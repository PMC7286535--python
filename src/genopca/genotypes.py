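"""Genotype containers, QC filtering and row standardization.

The central object is :class:`GenotypeMatrix`: an m-SNP x n-sample matrix of
minor-allele dosages in {0, 1, 2} plus a sparse record of missing calls.
Missing entries are stored as 0 in ``values`` (preserving the base-3 alphabet
that the fast multiplication kernel requires) and tracked separately by index
pairs.

Standardization is *implicit*: :func:`compute_standardization` returns the
per-SNP mean g-bar, scale s and ratio rho = g-bar / s that define

    Y = diag(s)^-1 G - rho 1_n^T        (missing cells set to 0)

so that every row of Y sums to 0 and (in the default unit-norm convention) has
unit sum of squares. Downstream algebra works with (G, params) and never needs
the dense Y, except in oracles and small-problem references where
:func:`standardized_matrix` materializes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSnpError, EmptyPanelError, ParameterError

__all__ = [
    "GenotypeMatrix",
    "StandardizationParams",
    "compute_standardization",
    "standardized_matrix",
    "snp_metadata",
    "qc_filter",
    "drop_monomorphic",
]

META_COLUMNS = ["chrom", "id", "pos", "allele1", "allele2"]


@dataclass
class GenotypeMatrix:
    """m x n matrix of genotypes in {0,1,2} with a sparse missing-call record.

    Parameters
    ----------
    values : ndarray of int8, shape (m, n)
        Minor-allele dosage; missing cells hold 0.
    missing_rows, missing_cols : ndarray of intp
        Parallel index arrays of the missing (SNP, sample) cells.
    """

    values: np.ndarray
    missing_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    missing_cols: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ParameterError("genotype values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ParameterError(f"need m >= 1 SNPs and n >= 2 samples, got {m} x {n}")
        self.missing_rows = np.asarray(self.missing_rows, dtype=np.intp)
        self.missing_cols = np.asarray(self.missing_cols, dtype=np.intp)
        if self.missing_rows.shape != self.missing_cols.shape:
            raise ParameterError("missing_rows and missing_cols must be parallel arrays")
        bad = (self.values < 0) | (self.values > 2)
        if bad.any():
            j, i = np.argwhere(bad)[0]
            raise ParameterError(
                f"genotype outside {{0,1,2}} at SNP {j}, sample {i}: {self.values[j, i]}"
            )
        if self.missing_rows.size:
            per_row = np.bincount(self.missing_rows, minlength=m)
            if (per_row >= n).any():
                j = int(np.argmax(per_row >= n))
                raise ParameterError(f"SNP row {j} is entirely missing")
            # missing cells must be stored as 0 so the base-3 alphabet holds
            if self.values[self.missing_rows, self.missing_cols].any():
                raise ParameterError("missing cells must hold value 0")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.missing_rows.size)

    def missing_per_snp(self) -> np.ndarray:
        """Count of missing calls for each SNP row."""
        return np.bincount(self.missing_rows, minlength=self.m)

    def called_per_snp(self) -> np.ndarray:
        return self.n - self.missing_per_snp()

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row-subset the matrix, remapping the missing record."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        remap = -np.ones(self.m, dtype=np.intp)
        remap[index] = np.arange(index.size)
        keep = remap[self.missing_rows] >= 0
        return GenotypeMatrix(
            self.values[index],
            remap[self.missing_rows[keep]],
            self.missing_cols[keep],
        )


@dataclass(frozen=True)
class StandardizationParams:
    """Per-SNP centering/scaling defining the implicit standardized matrix."""

    mean: np.ndarray  # g-bar, per-SNP mean of non-missing dosages
    scale: np.ndarray  # s, per-SNP scale (unit-norm or sd*sqrt(n) convention)
    rho: np.ndarray  # g-bar / s

    def __post_init__(self) -> None:
        if not (self.scale > 0).all():
            raise DegenerateSnpError("all scales must be positive")
        if not np.allclose(self.rho, self.mean / self.scale, rtol=0, atol=1e-12):
            raise ParameterError("rho must equal mean / scale elementwise")


def _row_moments(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP non-missing count, mean and centered sum of squares."""
    g = geno.values
    called = geno.called_per_snp().astype(np.float64)
    row_sum = g.sum(axis=1, dtype=np.float64)
    row_sumsq = (g.astype(np.float64) ** 2).sum(axis=1)
    mean = row_sum / called
    # missing cells contribute 0 to row_sum/row_sumsq; centered SS over the
    # called cells is sum(g^2) - called * mean^2
    css = row_sumsq - called * mean**2
    return called, mean, np.maximum(css, 0.0)


def compute_standardization(
    geno: GenotypeMatrix, scale_mode: str = "norm"
) -> StandardizationParams:
    """Compute per-SNP mean, scale and their ratio.

    scale_mode="norm" (default) uses s_j = sqrt(sum_i (g_ji - gbar_j)^2) over
    called cells, so each standardized row has unit norm. scale_mode="sd" uses
    the per-SNP standard deviation times sqrt(n); the two differ by one global
    scalar per SNP and leave the principal directions unchanged.
    """
    if scale_mode not in ("norm", "sd"):
        raise ParameterError(f"unknown scale_mode {scale_mode!r}")
    called, mean, css = _row_moments(geno)
    if (css <= 0).any():
        j = int(np.argmax(css <= 0))
        raise DegenerateSnpError(f"SNP row {j} has zero variance; remove it before PCA")
    if scale_mode == "norm":
        scale = np.sqrt(css)
    else:
        scale = np.sqrt(css / called) * np.sqrt(geno.n)
    return StandardizationParams(mean=mean, scale=scale, rho=mean / scale)


def standardized_matrix(
    geno: GenotypeMatrix, params: StandardizationParams, dtype=np.float64
) -> np.ndarray:
    """Materialize Y = diag(s)^-1 G - rho 1^T with missing cells set to 0.

    Only for oracles/small-problem references; the EM never builds this.
    """
    y = geno.values.astype(dtype)
    y -= params.mean[:, None].astype(dtype)
    y /= params.scale[:, None].astype(dtype)
    if geno.n_missing:
        y[geno.missing_rows, geno.missing_cols] = 0
    return y


def _hwe_pvalues(n_hom1: np.ndarray, n_het: np.ndarray, n_hom2: np.ndarray) -> np.ndarray:
    """Pearson chi-square (1 df) test of Hardy-Weinberg proportions.

    No continuity correction. SNPs where an expected genotype count is zero
    (monomorphic) get p = 1: there is no testable deviation.
    """
    n = n_hom1 + n_het + n_hom2
    p = (2 * n_hom1 + n_het) / (2 * n)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack([n * p**2, 2 * n * p * q, n * q**2])
        obs = np.stack([n_hom1, n_het, n_hom2])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(
            axis=0
        )
    pval = stats.chi2.sf(chi2, df=1)
    return np.where((p == 0) | (q == 0), 1.0, pval)


def snp_metadata(
    geno: GenotypeMatrix,
    chrom=None,
    ids=None,
    pos=None,
    allele1=None,
    allele2=None,
) -> pd.DataFrame:
    """Build the per-SNP metadata table, computing missing rate, MAF and HWE p.

    MAF is computed from non-missing alleles only; the dosage counts copies of
    allele1 (the PLINK A1/minor allele by convention).
    """
    m, n = geno.m, geno.n
    g = geno.values
    called = geno.called_per_snp().astype(np.float64)
    n_hom1 = (g == 2).sum(axis=1).astype(np.float64)
    n_het = (g == 1).sum(axis=1).astype(np.float64)
    if geno.n_missing:
        # missing cells are stored as 0 and must not count as hom-allele2
        n_hom2 = called - n_hom1 - n_het
    else:
        n_hom2 = (g == 0).sum(axis=1).astype(np.float64)
    freq1 = (2 * n_hom1 + n_het) / (2 * called)
    df = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "id": ids if ids is not None else [f"snp{j}" for j in range(m)],
            "pos": pos if pos is not None else np.arange(1, m + 1),
            "allele1": allele1 if allele1 is not None else ["A"] * m,
            "allele2": allele2 if allele2 is not None else ["C"] * m,
            "missing_rate": geno.missing_per_snp() / n,
            "maf": np.minimum(freq1, 1.0 - freq1),
            "hwe_p": _hwe_pvalues(n_hom1, n_het, n_hom2),
        }
    )
    return df


def _zero_variance_mask(geno: GenotypeMatrix) -> np.ndarray:
    _, _, css = _row_moments(geno)
    return css <= 0


def drop_monomorphic(
    geno: GenotypeMatrix, meta: pd.DataFrame | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame | None]:
    """Remove SNPs with no variation across samples (required before PCA)."""
    keep = ~_zero_variance_mask(geno)
    if not keep.any():
        raise EmptyPanelError("every SNP is monomorphic")
    if keep.all():
        return geno, meta
    out_meta = meta.loc[keep].reset_index(drop=True) if meta is not None else None
    return geno.take_snps(keep), out_meta


def qc_filter(
    geno: GenotypeMatrix,
    meta: pd.DataFrame,
    max_missing_rate: float = 0.01,
    min_maf: float = 0.01,
    min_hwe_p: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter SNPs on missingness, minor allele frequency and HWE.

    Retains SNPs with missing_rate <= max_missing_rate, maf >= min_maf and
    hwe_p >= min_hwe_p; zero-variance SNPs are always removed. Sample order is
    never changed. Applying the filter twice with the same thresholds is a
    no-op the second time.
    """
    for name, v in (
        ("max_missing_rate", max_missing_rate),
        ("min_maf", min_maf),
        ("min_hwe_p", min_hwe_p),
    ):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {v}")
    keep = (
        (meta["missing_rate"].to_numpy() <= max_missing_rate)
        & (meta["maf"].to_numpy() >= min_maf)
        & (meta["hwe_p"].to_numpy() >= min_hwe_p)
        & ~_zero_variance_mask(geno)
    )
    if not keep.any():
        raise EmptyPanelError("QC filtering removed every SNP")
    n_removed = int((~keep).sum())
    if n_removed:
        warnings.warn(f"QC removed {n_removed} of {geno.m} SNPs", stacklevel=2)
    return geno.take_snps(keep), meta.loc[keep].reset_index(drop=True)
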