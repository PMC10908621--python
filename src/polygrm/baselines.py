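"""Ratio-based comparator GRMs built on naive depth-ratio genotype proxies.

The common practice for sequencing data is to plug the dosage proxy
Z_ij = psi_i * Y_ij / d_ij straight into the genotype GRM. Two denominator
conventions circulate:

* ``expected``: sqrt(psi_h psi_i) * sum_j p_j (1 - p_j), the model-based
  denominator of the VanRaden-style estimator;
* ``sample-variance``: the empirical per-SNP variance of the centred Z
  columns, summed (the AGHmatrix-style default). Binomial read sampling
  inflates var(Z) as depth falls, so this mode shrinks estimates toward zero
  at low depth — the bias the corrected estimator avoids.

Neither mode corrects the diagonal for read-sampling noise, so self-
relatedness from these baselines is biased upward at low depth.
"""

from __future__ import annotations

import numpy as np

from .types import GRM, AlleleFreqs, ReadCounts, as_ploidy

__all__ = ["ratio_genotypes", "grm_ratio"]


def ratio_genotypes(rc: ReadCounts, ploidy) -> np.ndarray:
    """Dosage proxies Z_ij = psi_i * Y_ij / d_ij (NaN where depth is 0)."""
    psi = as_ploidy(ploidy, rc.n_individuals)
    return psi[:, None] * rc.ratios()


def grm_ratio(rc: ReadCounts, ploidy, p: AlleleFreqs, denominator: str = "expected") -> GRM:
    """VanRaden GRM on depth-ratio proxies, pairwise-complete.

    ``denominator='expected'`` uses sum_j p_j(1-p_j); with full-depth,
    error-free data (Z = X) it reproduces the genotype GRM exactly.
    ``denominator='sample-variance'`` replaces psi * sum p(1-p) with the sum
    of per-SNP sample variances of Z (computed over non-missing cells), the
    convention that drives the shrinkage bias at low depth.
    """
    if denominator not in ("expected", "sample-variance"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    psi = as_ploidy(ploidy, rc.n_individuals)
    if p.p.shape != (rc.n_snps,):
        raise ValueError("allele-frequency length does not match SNP count")
    keep = p.informative

    z = ratio_genotypes(rc, psi)[:, keep]
    pj = p.p[keep]
    obs = ~np.isnan(z)
    b = obs.astype(float)
    w = np.where(obs, z - psi[:, None] * pj[None, :], 0.0)

    num = w @ w.T
    n_used = np.rint(b @ b.T).astype(np.int64)
    scale = np.sqrt(np.outer(psi, psi))

    if denominator == "expected":
        v = pj * (1.0 - pj)
        den = scale * ((b * v[None, :]) @ b.T)
    else:
        # Per-SNP sample variance of observed Z, pairwise-complete sum.
        n_obs = b.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_z = np.where(n_obs > 0, np.where(obs, z, 0.0).sum(axis=0) / n_obs, np.nan)
            centred = np.where(obs, z - mean_z[None, :], 0.0)
            var_z = np.where(
                n_obs > 1, (centred**2).sum(axis=0) / (n_obs - 1), np.nan
            )
        var_z = np.where(np.isnan(var_z), 0.0, var_z)
        den = (b * var_z[None, :]) @ b.T

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / den, np.nan)
    values = np.where(n_used > 0, values, np.nan)
    values = 0.5 * (values + values.T)
    return GRM(
        values,
        n_used,
        list(rc.individual_ids),
        metadata={"estimator": f"ratio-{denominator}", "freq_source": p.source},
    )
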