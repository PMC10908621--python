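"""Core in-memory containers shared across the package.

Conventions
-----------
* Dosage and relatedness matrices are dense ``numpy`` float arrays with
  ``NaN`` marking missing entries.
* Read counts are integer arrays; a total depth of 0 encodes a missing
  genotype call.
* Per-individual ploidy ``psi_i`` (an integer >= 2) drives every estimator:
  dosages live in ``0..psi_i`` and the relatedness parameterisation is
  ``r_hi = sqrt(psi_h * psi_i) * theta_hi`` off the diagonal and
  ``r_ii = 1 + (psi_i - 1) * F_i`` on it, with ``theta`` the coancestry and
  ``F`` the inbreeding coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "ReadCounts",
    "GRM",
    "AlleleFreqs",
    "as_ploidy",
    "as_error_rates",
]


def as_ploidy(ploidy, n: int) -> np.ndarray:
    """Normalise a ploidy specification to an integer vector of length ``n``.

    Accepts a scalar (shared ploidy) or a length-``n`` sequence. Every value
    must be an integer >= 2.
    """
    arr = np.asarray(ploidy)
    if arr.ndim == 0:
        arr = np.full(n, int(arr))
    arr = arr.astype(np.int64)
    if arr.shape != (n,):
        raise ValueError(f"ploidy has length {arr.shape}, expected ({n},)")
    if np.any(arr < 2):
        raise ValueError("every ploidy must be an integer >= 2")
    return arr


def as_error_rates(eps, m: int) -> np.ndarray:
    """Normalise a sequencing-error spec (scalar or per-SNP) to length ``m``.

    Rates must satisfy 0 <= eps_j < 0.5; at 0.5 and beyond a read carries no
    information about the underlying allele and the moment corrections blow up.
    """
    arr = np.asarray(eps, dtype=float)
    if arr.ndim == 0:
        arr = np.full(m, float(arr))
    if arr.shape != (m,):
        raise ValueError(f"error rates have shape {arr.shape}, expected ({m},)")
    if np.any((arr < 0) | (arr >= 0.5)):
        raise ValueError("sequencing error rates must lie in [0, 0.5)")
    return arr


def _check_labels(labels: Sequence[str], n: int, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"{what}: {len(labels)} labels for {n} entries")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what}: labels are not unique")
    return labels


@dataclass
class GenotypeMatrix:
    """Reference-allele dosages X_ij (individuals x SNPs), NaN = missing."""

    values: np.ndarray
    individual_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("genotype matrix must be 2-D and non-empty")
        n, m = self.values.shape
        self.individual_ids = _check_labels(self.individual_ids, n, "individuals")
        self.snp_ids = _check_labels(self.snp_ids, m, "SNPs")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
            raise ValueError("dosages must be non-negative integers (or NaN)")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def validate_ploidy(self, ploidy) -> np.ndarray:
        """Check every dosage against its individual's ploidy; return ploidy."""
        psi = as_ploidy(ploidy, self.n_individuals)
        with np.errstate(invalid="ignore"):
            bad = np.nan_to_num(self.values, nan=0.0) > psi[:, None]
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage {self.values[i, j]:g} exceeds ploidy {psi[i]} for "
                f"individual '{self.individual_ids[i]}' at SNP '{self.snp_ids[j]}'"
            )
        return psi

    def proportions(self, ploidy) -> np.ndarray:
        """Dosage proportions R_ij = X_ij / psi_i (NaN where missing)."""
        psi = self.validate_ploidy(ploidy)
        return self.values / psi[:, None]


@dataclass
class ReadCounts:
    """Reference reads Y_ij and total depths d_ij per individual per SNP.

    ``depth == 0`` encodes a missing genotype call; 0 <= Y <= d always.
    """

    ref_reads: np.ndarray
    depth: np.ndarray
    individual_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self):
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.ref_reads.shape != self.depth.shape:
            raise ValueError("ref_reads and depth shapes differ")
        if self.ref_reads.ndim != 2 or min(self.ref_reads.shape) < 1:
            raise ValueError("read-count matrices must be 2-D and non-empty")
        n, m = self.depth.shape
        self.individual_ids = _check_labels(self.individual_ids, n, "individuals")
        self.snp_ids = _check_labels(self.snp_ids, m, "SNPs")
        if np.any(self.ref_reads < 0) or np.any(self.depth < 0):
            raise ValueError("read counts must be non-negative")
        if np.any(self.ref_reads > self.depth):
            raise ValueError("reference reads exceed total depth")

    @property
    def n_individuals(self) -> int:
        return self.depth.shape[0]

    @property
    def n_snps(self) -> int:
        return self.depth.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.depth == 0

    def ratios(self) -> np.ndarray:
        """S_ij = Y_ij / d_ij, NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(self.depth > 0, self.ref_reads / np.maximum(self.depth, 1), np.nan)
        return s

    def subset_snps(self, index) -> "ReadCounts":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ReadCounts(
            self.ref_reads[:, index],
            self.depth[:, index],
            list(self.individual_ids),
            [self.snp_ids[j] for j in index],
        )


@dataclass
class AlleleFreqs:
    """Per-SNP reference-allele frequencies p_j with provenance."""

    p: np.ndarray
    source: str = "supplied"

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        obs = self.p[~np.isnan(self.p)]
        if np.any((obs < 0) | (obs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def informative(self) -> np.ndarray:
        """SNPs usable by the estimators: frequency strictly inside (0, 1)."""
        with np.errstate(invalid="ignore"):
            return (~np.isnan(self.p)) & (self.p > 0.0) & (self.p < 1.0)


@dataclass
class GRM:
    """Symmetric relatedness matrix with per-entry usable-SNP counts.

    Diagonal entries estimate self-relatedness 1 + (psi_i - 1) F_i; off-
    diagonals estimate sqrt(psi_h psi_i) theta_hi. Entries with no usable
    SNPs are NaN and have ``n_snps_used == 0``.
    """

    values: np.ndarray
    n_snps_used: np.ndarray
    individual_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.n_snps_used = np.asarray(self.n_snps_used, dtype=np.int64)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.n_snps_used.shape != (n, n):
            raise ValueError("GRM matrices must be square and congruent")
        self.individual_ids = _check_labels(self.individual_ids, n, "individuals")
        if not _symmetric_with_nan(self.values):
            raise ValueError("GRM values are not symmetric")
        if np.any(self.n_snps_used != self.n_snps_used.T):
            raise ValueError("n_snps_used is not symmetric")
        if np.any(np.isnan(self.values) & (self.n_snps_used > 0)):
            raise ValueError("NaN entry with a positive SNP count")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    def diagonal(self) -> np.ndarray:
        return np.diag(self.values).copy()

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries as a flat vector."""
        iu = np.triu_indices(self.n_individuals, k=1)
        return self.values[iu]


def _symmetric_with_nan(a: np.ndarray, rtol: float = 1e-10) -> bool:
    nan = np.isnan(a)
    if np.any(nan != nan.T):
        return False
    b = np.where(nan, 0.0, a)
    scale = np.max(np.abs(b)) or 1.0
    return bool(np.all(np.abs(b - b.T) <= rtol * scale))
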