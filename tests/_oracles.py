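"""Independent brute-force reference implementations used only by tests.

These deliberately use naive per-pair / per-SNP loops so they share no code
with the vectorised implementations they check.
"""

import numpy as np


def grm_genotype_brute(x, psi, p):
    """Naive pairwise-complete mixed-ploidy VanRaden GRM (loops over pairs)."""
    n, m = x.shape
    g = np.full((n, n), np.nan)
    keep = [j for j in range(m) if 0.0 < p[j] < 1.0 and not np.isnan(p[j])]
    for h in range(n):
        for i in range(h, n):
            num = den = 0.0
            used = 0
            for j in keep:
                if np.isnan(x[h, j]) or np.isnan(x[i, j]):
                    continue
                num += (x[h, j] - psi[h] * p[j]) * (x[i, j] - psi[i] * p[j])
                den += p[j] * (1.0 - p[j])
                used += 1
            if used:
                g[h, i] = g[i, h] = num / (np.sqrt(psi[h] * psi[i]) * den)
    return g


def grm_hts_brute(y, d, psi, eps, p):
    """Naive sequencing-data GRM with per-entry SNP sets (loops over pairs)."""
    n, m = y.shape
    g = np.full((n, n), np.nan)
    keep = [j for j in range(m) if 0.0 < p[j] < 1.0 and not np.isnan(p[j])]
    gamma = 1.0 - 4.0 * eps * (1.0 - eps)
    eta = 1.0 - 4.0 * p * (1.0 - p)
    for h in range(n):
        for i in range(n):
            if h == i:
                num = den = 0.0
                used = 0
                for j in keep:
                    if d[i, j] < 2:
                        continue
                    s = y[i, j] / d[i, j]
                    delta = 1.0 - 1.0 / d[i, j]
                    v = p[j] * (1.0 - p[j])
                    a = v * (1.0 - gamma[j] * delta) + eps[j] * (
                        eta[j] - (1.0 - eps[j]) * delta)
                    num += ((s - p[j]) ** 2 - a) / (gamma[j] * delta)
                    den += v
                    used += 1
                if used:
                    g[i, i] = psi[i] * num / den
            elif h < i:
                num = den = 0.0
                used = 0
                for j in keep:
                    if d[h, j] < 1 or d[i, j] < 1:
                        continue
                    sh = y[h, j] / d[h, j]
                    si = y[i, j] / d[i, j]
                    num += ((sh - p[j]) * (si - p[j]) - eps[j] ** 2 * eta[j]) / gamma[j]
                    den += p[j] * (1.0 - p[j])
                    used += 1
                if used:
                    g[h, i] = g[i, h] = np.sqrt(psi[h] * psi[i]) * num / den
    return g


def vanraden_diploid(x, p):
    """Classical diploid VanRaden estimator, complete data, direct formula."""
    num = (x - 2 * p[None, :]) @ (x - 2 * p[None, :]).T
    return num / (2.0 * np.sum(p * (1.0 - p)))
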