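"""SNP filtering for sequencing data: MAF, missingness, depth, and HWE.

The basic cascade mirrors standard GBS practice: discard SNPs with minor
allele frequency below a floor, with too many zero-depth (missing) calls,
or with implausibly high mean depth (repetitive or paralogous regions).

The Hardy-Weinberg filter is a likelihood-ratio test on the raw read
counts, extending the classical read-based HWE test for diploids to an
arbitrary shared ploidy psi. Genotypes are never called: for each
individual the psi+1 genotype likelihoods

    L_i(x) = Bin(Y_i; d_i, pi(x)),   pi(x) = (x/psi)(1-eps) + (1-x/psi) eps

are combined under two models for the genotype frequencies —

* null (HWE): genotype frequencies Bin(psi, p), one free parameter p,
  maximised by bounded 1-D optimisation;
* alternative: free frequencies on the psi-simplex, maximised by EM —

and 2 * (logL1 - logL0) is referred to a chi-square with psi - 1 degrees of
freedom (psi free parameters versus 1). Individuals with zero depth
contribute nothing. SNPs with excess homozygosity *or* heterozygosity
relative to HWE are both flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import AlleleFreqs, ReadCounts, as_error_rates
from .grm import estimate_freq_reads

__all__ = [
    "FilterReport",
    "HWEResult",
    "filter_basic",
    "hwe_test",
    "add_hwe_flags",
    "apply_filters",
    "split_by_depth",
]


@dataclass
class FilterReport:
    """Per-SNP failure flags and the thresholds that produced them."""

    snp_ids: list[str]
    maf_fail: np.ndarray
    missing_fail: np.ndarray
    depth_fail: np.ndarray
    hwe_fail: np.ndarray
    thresholds: dict

    @property
    def retained(self) -> np.ndarray:
        return ~(self.maf_fail | self.missing_fail | self.depth_fail | self.hwe_fail)

    def counts(self) -> dict:
        return {
            "n_snps": len(self.snp_ids),
            "maf_fail": int(self.maf_fail.sum()),
            "missing_fail": int(self.missing_fail.sum()),
            "depth_fail": int(self.depth_fail.sum()),
            "hwe_fail": int(self.hwe_fail.sum()),
            "retained": int(self.retained.sum()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids,
            "maf_fail": self.maf_fail,
            "missing_fail": self.missing_fail,
            "depth_fail": self.depth_fail,
            "hwe_fail": self.hwe_fail,
            "retained": self.retained,
        })


@dataclass
class HWEResult:
    """Per-SNP HWE likelihood-ratio test results."""

    snp_ids: list[str]
    loglik_null: np.ndarray
    loglik_alt: np.ndarray
    lrt: np.ndarray
    df: int
    p_value: np.ndarray


def filter_basic(rc: ReadCounts, maf_min: float = 0.01, max_missing: float = 0.5,
                 max_mean_depth: float = 500.0,
                 p: AlleleFreqs | None = None) -> FilterReport:
    """Flag SNPs on MAF, missingness and mean depth.

    Missingness counts individuals with zero depth and fails at
    ``max_missing`` *or more* (boundary inclusive); mean depth is over all
    individuals, zeros included, and fails strictly above the ceiling.
    """
    if p is None:
        p = estimate_freq_reads(rc)
    if p.p.shape != (rc.n_snps,):
        raise ValueError("allele-frequency length does not match SNP count")
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p.p, 1.0 - p.p)
        maf_fail = ~np.isnan(maf) & (maf < maf_min) | np.isnan(maf)
    missing = (rc.depth == 0).mean(axis=0)
    mean_depth = rc.depth.mean(axis=0)
    return FilterReport(
        list(rc.snp_ids),
        maf_fail=maf_fail,
        missing_fail=missing >= max_missing,
        depth_fail=mean_depth > max_mean_depth,
        hwe_fail=np.zeros(rc.n_snps, dtype=bool),
        thresholds={"maf_min": maf_min, "max_missing": max_missing,
                    "max_mean_depth": max_mean_depth},
    )


def _hwe_single(y: np.ndarray, d: np.ndarray, psi: int, eps: float,
                tol: float = 1e-8, max_iter: int = 500):
    """Null/alt log-likelihoods for one SNP; returns (ll0, ll1) or None."""
    use = d > 0
    y, d = y[use], d[use]
    if y.size == 0:
        return None
    x = np.arange(psi + 1)
    pi = (x / psi) * (1.0 - eps) + (1.0 - x / psi) * eps
    # Genotype likelihood matrix, individuals x (psi + 1).
    lik = stats.binom.pmf(y[:, None], d[:, None], pi[None, :])
    # Guard against total underflow at extreme depths.
    row_max = lik.max(axis=1, keepdims=True)
    if np.any(row_max == 0):
        return None
    lik = lik / row_max
    log_scale = np.log(row_max).sum()

    def negll_null(p: float) -> float:
        w = stats.binom.pmf(x, psi, p)
        return -np.log(lik @ w).sum()

    res = optimize.minimize_scalar(negll_null, bounds=(1e-6, 1.0 - 1e-6),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    ll0 = -res.fun + log_scale

    phi = np.full(psi + 1, 1.0 / (psi + 1))
    ll1 = -np.inf
    for _ in range(max_iter):
        joint = lik * phi[None, :]
        marg = joint.sum(axis=1)
        new_ll = np.log(marg).sum()
        phi = (joint / marg[:, None]).mean(axis=0)
        if new_ll - ll1 < tol * (abs(new_ll) + 1.0) and np.isfinite(ll1):
            ll1 = new_ll
            break
        ll1 = new_ll
    return ll0, ll1 + log_scale


def hwe_test(rc: ReadCounts, ploidy: int, eps=0.0) -> HWEResult:
    """Autopolyploid HWE LRT on read counts; shared ploidy across individuals.

    SNPs where the likelihood degenerates (no reads, or underflow) get NaN
    p-values and are treated as retained by the HWE filter.
    """
    psi = int(ploidy)
    if psi < 2:
        raise ValueError("ploidy must be >= 2")
    eps_vec = as_error_rates(eps, rc.n_snps)
    m = rc.n_snps
    ll0 = np.full(m, np.nan)
    ll1 = np.full(m, np.nan)
    for j in range(m):
        out = _hwe_single(rc.ref_reads[:, j], rc.depth[:, j], psi, eps_vec[j])
        if out is not None:
            ll0[j], ll1[j] = out
    # EM converges from below and the null is nested, but allow tiny negatives.
    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    df = psi - 1
    pval = stats.chi2.sf(lrt, df)
    return HWEResult(list(rc.snp_ids), ll0, ll1, lrt, df, pval)


def add_hwe_flags(report: FilterReport, hwe: HWEResult,
                  alpha: float = 0.1) -> FilterReport:
    """Set hwe_fail where the HWE p-value is below ``alpha`` (NaN retained)."""
    if hwe.snp_ids != report.snp_ids:
        raise ValueError("HWE results and filter report cover different SNPs")
    with np.errstate(invalid="ignore"):
        fail = ~np.isnan(hwe.p_value) & (hwe.p_value < alpha)
    report.hwe_fail = fail
    report.thresholds = {**report.thresholds, "hwe_alpha": alpha}
    return report


def apply_filters(rc: ReadCounts, report: FilterReport) -> ReadCounts:
    """Subset to retained SNPs, preserving order."""
    if report.snp_ids != rc.snp_ids:
        raise ValueError("filter report covers different SNPs")
    keep = report.retained
    if not keep.any():
        raise ValueError("all SNPs were filtered out")
    return rc.subset_snps(keep)


def split_by_depth(rc: ReadCounts, threshold: float = 50.0):
    """Partition SNPs on mean depth; SNPs at the threshold go to the high set."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mean_depth = rc.depth.mean(axis=0)
    low = mean_depth < threshold
    low_rc = rc.subset_snps(low) if low.any() else None
    high_rc = rc.subset_snps(~low) if (~low).any() else None
    return low_rc, high_rc
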