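"""Method-of-moments genomic relationship matrices for autopolyploids.

Two estimators are provided, both VanRaden (method 1) style and both valid
for mixed-ploidy populations:

``grm_genotype``
    For called dosages X_ij in 0..psi_i,

        G_hi = sum_j (X_hj - psi_h p_j)(X_ij - psi_i p_j)
               / ( sqrt(psi_h psi_i) * sum_j p_j (1 - p_j) ),

    which for psi_h = psi_i = 2 is exactly the classical diploid VanRaden
    estimator. Equivalently, with R_ij = X_ij / psi_i,
    G_hi = sqrt(psi_h psi_i) sum_j (R_hj - p_j)(R_ij - p_j) / sum_j p_j(1-p_j).

``grm_hts``
    For raw sequencing read counts, where only Y_ij reference reads out of
    d_ij total are observed and each read is miscalled with probability
    eps_j. Writing S_ij = Y_ij / d_ij, the read-level moments imply the
    corrected off-diagonal estimator

        G_hi = sqrt(psi_h psi_i)
               * sum_j [ (S_hj - p_j)(S_ij - p_j) - eps_j^2 eta_j ] / gamma_j
               / sum_j p_j (1 - p_j),                      (h != i)

    with gamma_j = 1 - 4 eps_j (1 - eps_j) and eta_j = 1 - 4 p_j (1 - p_j),
    and the self-relatedness estimator (only depths >= 2 carry information
    about inbreeding)

        G_ii = psi_i * sum_j [ (S_ij - p_j)^2 - A_ij ] / (gamma_j delta_ij)
               / sum_j p_j (1 - p_j),                      (d_ij >= 2)

    where delta_ij = 1 - 1/d_ij and
    A_ij = p_j(1-p_j)(1 - gamma_j delta_ij) + eps_j (eta_j - (1-eps_j) delta_ij).

    Because the off-diagonal depends on the counts only through S, relatedness
    between distinct individuals is unbiased at any depth; the diagonal
    adjustment removes the upward bias that the naive ratio estimator suffers
    at low depth.

Missing data are handled pairwise-complete: each entry (h, i) sums only over
SNPs observed in both individuals, with matching per-entry denominators.
This is implemented with indicator-matrix products, so the cost is a fixed
number of (N x M)(M x N) multiplications regardless of the missingness
pattern.
"""

from __future__ import annotations

import numpy as np

from .types import GRM, AlleleFreqs, GenotypeMatrix, ReadCounts, as_error_rates, as_ploidy

__all__ = [
    "estimate_freq_genotype",
    "estimate_freq_reads",
    "grm_genotype",
    "grm_hts",
    "grm_pipeline",
    "hts_adjustment_terms",
]


def estimate_freq_genotype(g: GenotypeMatrix, ploidy) -> AlleleFreqs:
    """Estimate reference-allele frequencies from dosages.

    p_hat_j is the mean of X_ij / psi_i over individuals with a non-missing
    call at SNP j (for complete data, (1/N) sum_i X_ij / psi_i). SNPs with no
    calls at all get NaN.
    """
    r = g.proportions(ploidy)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(r, axis=0)
    return AlleleFreqs(p, source="genotype-estimated")


def estimate_freq_reads(rc: ReadCounts, eps=0.0, adjust: bool = True) -> AlleleFreqs:
    """Estimate reference-allele frequencies from read counts.

    The depth-weighted raw ratio q_hat_j = sum_i Y_ij / sum_i d_ij estimates
    the per-read reference probability eps_j + (1 - 2 eps_j) p_j, so the
    error-adjusted moment estimator is

        p_hat_j = clamp( (q_hat_j - eps_j) / (1 - 2 eps_j), 0, 1 ).

    With ``adjust=False`` the raw ratio is returned. SNPs with zero total
    depth get NaN.
    """
    eps = as_error_rates(eps, rc.n_snps)
    tot = rc.depth.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(tot > 0, rc.ref_reads.sum(axis=0) / np.maximum(tot, 1), np.nan)
    if not adjust:
        return AlleleFreqs(q, source="read-estimated")
    p = np.clip((q - eps) / (1.0 - 2.0 * eps), 0.0, 1.0)
    return AlleleFreqs(p, source="read-estimated")


def _resolve_freqs(p: AlleleFreqs, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (p, informative mask) for the M retained SNPs."""
    if p.p.shape != (m,):
        raise ValueError(f"allele frequencies have shape {p.p.shape}, expected ({m},)")
    return p.p, p.informative


def grm_genotype(g: GenotypeMatrix, ploidy, p: AlleleFreqs) -> GRM:
    """Mixed-ploidy VanRaden GRM from dosage genotypes, pairwise-complete.

    SNPs with p_j in {0, 1} (zero-variance denominator terms) or missing
    frequency are excluded from every sum. Entries with no jointly observed
    SNP are NaN with ``n_snps_used == 0``.
    """
    psi = g.validate_ploidy(ploidy)
    pj, keep = _resolve_freqs(p, g.n_snps)
    x = g.values[:, keep]
    pj = pj[keep]

    obs = ~np.isnan(x)
    b = obs.astype(float)
    w = np.where(obs, x - psi[:, None] * pj[None, :], 0.0)

    num = w @ w.T
    v = pj * (1.0 - pj)
    den = (b * v[None, :]) @ b.T
    n_used = np.rint(b @ b.T).astype(np.int64)

    scale = np.sqrt(np.outer(psi, psi))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / (scale * den), np.nan)
    values = np.where(n_used > 0, values, np.nan)
    values = 0.5 * (values + values.T)  # exact symmetry against fp drift
    return GRM(
        values,
        n_used,
        list(g.individual_ids),
        metadata={"estimator": "genotype", "freq_source": p.source},
    )


def hts_adjustment_terms(depth: np.ndarray, pj: np.ndarray, eps: np.ndarray):
    """Moment-correction terms for the sequencing-data estimator.

    Returns (gamma_j, eta_j, delta_ij, A_ij); delta and A are NaN where the
    depth is below 2 (no inbreeding information).
    """
    gamma = 1.0 - 4.0 * eps * (1.0 - eps)
    eta = 1.0 - 4.0 * pj * (1.0 - pj)
    with np.errstate(divide="ignore"):
        delta = np.where(depth >= 2, 1.0 - 1.0 / np.maximum(depth, 1), np.nan)
    v = pj * (1.0 - pj)
    a = v[None, :] * (1.0 - gamma[None, :] * delta) + eps[None, :] * (
        eta[None, :] - (1.0 - eps[None, :]) * delta
    )
    return gamma, eta, delta, a


def grm_hts(rc: ReadCounts, ploidy, eps, p: AlleleFreqs) -> GRM:
    """Sequencing-error- and depth-corrected GRM from raw read counts.

    Off-diagonal entries use SNPs with d > 0 in both individuals; diagonal
    entries use SNPs with d >= 2 in that individual. The two sums use their
    own matched denominators (pairwise-complete missing-data scheme).
    """
    psi = as_ploidy(ploidy, rc.n_individuals)
    eps = as_error_rates(eps, rc.n_snps)
    pj, keep = _resolve_freqs(p, rc.n_snps)

    y = rc.ref_reads[:, keep].astype(float)
    d = rc.depth[:, keep].astype(float)
    pj = pj[keep]
    eps = eps[keep]

    obs = d > 0
    b = obs.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(obs, y / np.maximum(d, 1.0), 0.0)

    gamma, eta, delta, a = hts_adjustment_terms(d, pj, eps)
    v = pj * (1.0 - pj)

    # Off-diagonals: sum_j [(S_h - p)(S_i - p) - eps^2 eta]/gamma over joint d>0.
    t = np.where(obs, (s - pj[None, :]) / np.sqrt(gamma)[None, :], 0.0)
    c = eps**2 * eta / gamma
    num = t @ t.T - (b * c[None, :]) @ b.T
    den = (b * v[None, :]) @ b.T
    n_used = np.rint(b @ b.T).astype(np.int64)

    scale = np.sqrt(np.outer(psi, psi))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, scale * num / den, np.nan)

    # Diagonals: sum over d >= 2 of [(S - p)^2 - A]/(gamma delta).
    inbred_obs = d >= 2
    with np.errstate(invalid="ignore"):
        diag_terms = ((s - pj[None, :]) ** 2 - a) / (gamma[None, :] * delta)
    diag_num = np.where(inbred_obs, diag_terms, 0.0).sum(axis=1)
    diag_den = (inbred_obs * v[None, :]).sum(axis=1)
    diag_n = inbred_obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag_vals = np.where(diag_den > 0, psi * diag_num / diag_den, np.nan)

    np.fill_diagonal(values, diag_vals)
    np.fill_diagonal(n_used, diag_n)
    values = np.where(n_used > 0, values, np.nan)
    values = 0.5 * (values + values.T)
    return GRM(
        values,
        n_used,
        list(rc.individual_ids),
        metadata={
            "estimator": "hts",
            "freq_source": p.source,
            "eps_min": float(eps.min()) if eps.size else 0.0,
            "eps_max": float(eps.max()) if eps.size else 0.0,
        },
    )


def grm_pipeline(data, ploidy, eps=0.0, p: AlleleFreqs | None = None) -> GRM:
    """Estimate allele frequencies if needed, then dispatch to the matching GRM.

    ``GenotypeMatrix`` input uses the dosage frequency estimator and the
    genotype GRM; ``ReadCounts`` input uses the error-adjusted read-ratio
    frequency estimator and the sequencing-data GRM.
    """
    if isinstance(data, GenotypeMatrix):
        if p is None:
            p = estimate_freq_genotype(data, ploidy)
        return grm_genotype(data, ploidy, p)
    if isinstance(data, ReadCounts):
        if p is None:
            p = estimate_freq_reads(data, eps)
        return grm_hts(data, ploidy, eps, p)
    raise TypeError(f"unsupported input type {type(data).__name__}")
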