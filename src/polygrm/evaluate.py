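"""Scoring of estimated GRMs against truth and against each other.

Per-relationship-class error summaries are the headline metric: for each
class (half sibs, parent-offspring, ...) the bias, variance and RMSE of the
estimates are computed over all pairs in the class, pooled across simulation
replicates, so that RMSE^2 = bias^2 + variance holds exactly. The flat
"sum over all off-diagonals, divide by N" RMSE convention is also available
(``normalization='per-individual'``) for comparability with that reporting
style.

Two experiment drivers are included: ``run_method_comparison`` (fixed
design, several estimators, per-class errors) and ``run_depth_sweep``
(fixed total sequencing effort N * M * depth, trading SNPs against depth).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import baselines, grm as grm_mod
from .simulate import SimConfig, class_index_map, simulate_dataset
from .types import GRM

__all__ = [
    "rmse",
    "concordance",
    "class_summary",
    "run_method_comparison",
    "run_depth_sweep",
    "METHODS",
]


def _scope_entries(est: GRM, truth: GRM, scope) -> tuple[np.ndarray, np.ndarray]:
    if est.individual_ids != truth.individual_ids:
        raise ValueError("GRMs cover different individuals")
    n = est.n_individuals
    if scope == "diagonal":
        idx = (np.arange(n), np.arange(n))
    elif scope == "off-diagonal":
        idx = np.triu_indices(n, k=1)
    else:  # explicit (rows, cols) pair-index arrays
        idx = scope
    a, b = est.values[idx], truth.values[idx]
    ok = ~(np.isnan(a) | np.isnan(b))
    return a[ok], b[ok]


def rmse(est: GRM, truth: GRM, scope="diagonal",
         normalization: str = "per-entry") -> float:
    """Root-mean-square error of ``est`` vs ``truth`` over a scope.

    ``scope`` is "diagonal", "off-diagonal", or explicit pair-index arrays
    (rows, cols). Missing entries are excluded pairwise.
    ``normalization='per-entry'`` divides the squared-error sum by the number
    of entries compared; ``'per-individual'`` divides by N (the flat
    convention sqrt((1/N) sum_h sum_{i != h} (...)^2) sometimes used for the
    off-diagonal summary, counting each unordered pair twice).
    """
    a, b = _scope_entries(est, truth, scope)
    if a.size == 0:
        raise ValueError("no comparable entries in the requested scope")
    sq = (a - b) ** 2
    if normalization == "per-entry":
        return float(np.sqrt(sq.mean()))
    if normalization == "per-individual":
        total = sq.sum() if scope == "diagonal" else 2.0 * sq.sum()
        return float(np.sqrt(total / est.n_individuals))
    raise ValueError(f"unknown normalization {normalization!r}")


def concordance(a: GRM, b: GRM, part: str = "off-diagonal") -> dict:
    """Agreement statistics between two GRMs over a part.

    Returns Spearman's rank correlation, Lin's concordance correlation
    coefficient ccc = 2 cov(a,b) / (var(a) + var(b) + (mean(a) - mean(b))^2),
    and Bland-Altman statistics (mean difference and mean +/- 2 SD limits).
    """
    x, y = _scope_entries(a, b, part)
    if x.size < 3:
        raise ValueError("need at least 3 paired entries")
    out = {}
    out["spearman_r"] = float(stats.spearmanr(x, y).statistic)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        out["lin_ccc"] = np.nan
        out["ccc_defined"] = False
    else:
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        out["lin_ccc"] = float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))
        out["ccc_defined"] = True
    diff = x - y
    md, sd = diff.mean(), diff.std()
    out["ba_mean_diff"] = float(md)
    out["ba_lower"] = float(md - 2 * sd)
    out["ba_upper"] = float(md + 2 * sd)
    return out


def class_summary(errors_by_class: dict[str, np.ndarray]) -> pd.DataFrame:
    """Bias / variance / RMSE per relationship class from pooled errors."""
    rows = []
    for cls, err in errors_by_class.items():
        err = np.concatenate(err) if isinstance(err, list) else np.asarray(err)
        err = err[~np.isnan(err)]
        if err.size == 0:
            continue
        bias = err.mean()
        var = err.var()  # ddof=0 so that rmse^2 = bias^2 + var exactly
        rows.append({
            "cls": cls,
            "n_pairs": int(err.size),
            "bias": float(bias),
            "variance": float(var),
            "rmse": float(np.sqrt((err**2).mean())),
        })
    return pd.DataFrame(rows)


#: Estimators available to the comparison driver.
METHODS = ["genotype-truth", "hts", "hts-err", "ratio-expected", "ratio-sample-variance"]


def _estimate(method: str, sim, freqs) -> GRM:
    cfg = sim.config
    if method == "genotype-truth":
        return grm_mod.grm_genotype(sim.genotypes, cfg.ploidy, freqs)
    if method == "hts":
        return grm_mod.grm_hts(sim.reads, cfg.ploidy, 0.0, freqs)
    if method == "hts-err":
        return grm_mod.grm_hts(sim.reads, cfg.ploidy, cfg.eps, freqs)
    if method == "ratio-expected":
        return baselines.grm_ratio(sim.reads, cfg.ploidy, freqs, "expected")
    if method == "ratio-sample-variance":
        return baselines.grm_ratio(sim.reads, cfg.ploidy, freqs, "sample-variance")
    raise ValueError(f"unknown method {method!r}")


def run_method_comparison(config: SimConfig, methods=None, n_replicates: int = 100,
                          use_true_freqs: bool = False) -> pd.DataFrame:
    """Replicate the design, score each estimator per relationship class.

    Returns a tidy table (method, cls, n_pairs, bias, variance, rmse) with
    errors pooled over replicates. ``use_true_freqs`` supplies the founder
    allele frequencies to the estimators instead of re-estimating them from
    each dataset.
    """
    methods = list(methods or METHODS)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates) % (2**31)
    classes = None
    errors = {m: {} for m in methods}
    for rep in range(n_replicates):
        cfg = SimConfig(**{**config.__dict__, "seed": int(seeds[rep])})
        sim = simulate_dataset(cfg)
        if classes is None:
            classes = class_index_map(sim.pedigree)
        if use_true_freqs:
            freqs = sim.freqs
        else:
            freqs = grm_mod.estimate_freq_reads(sim.reads, cfg.eps)
        for m in methods:
            est = _estimate(m, sim, freqs)
            err = est.values - sim.truth.values
            for cls, idx in classes.items():
                errors[m].setdefault(cls, []).append(err[idx])
    frames = []
    for m in methods:
        df = class_summary(errors[m])
        df.insert(0, "method", m)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["ploidy"] = config.ploidy
    out["mean_depth"] = config.mean_depth
    out["eps"] = config.eps
    return out


def run_depth_sweep(total_reads: int, ploidy: int, depths, n_replicates: int = 100,
                    n_families: int = 20, eps: float = 0.001,
                    seed: int = 0) -> pd.DataFrame:
    """RMSE versus mean depth at fixed sequencing effort N * M * depth.

    For each mean depth mu the SNP count is M = round(total_reads / (N mu)).
    Returns one row per depth with diagonal and off-diagonal RMSE (pooled
    over replicates) and M; the RMSE-minimising depth per scope is in the
    ``attrs`` of the returned frame.
    """
    depths = list(depths)
    n_ind = 21 * n_families
    rows = []
    ss = np.random.SeedSequence(seed).generate_state(len(depths) * n_replicates)
    ss = (ss % (2**31)).reshape(len(depths), n_replicates)
    for k, mu in enumerate(depths):
        m_snps = int(round(total_reads / (n_ind * mu)))
        if m_snps < 1:
            raise ValueError(f"sequencing effort too small at depth {mu}")
        sq_diag, sq_off, n_diag, n_off = 0.0, 0.0, 0, 0
        for rep in range(n_replicates):
            cfg = SimConfig(n_families=n_families, ploidy=ploidy, n_snps=m_snps,
                            mean_depth=float(mu), eps=eps, seed=int(ss[k, rep]))
            sim = simulate_dataset(cfg)
            freqs = grm_mod.estimate_freq_reads(sim.reads, cfg.eps)
            est = grm_mod.grm_hts(sim.reads, cfg.ploidy, cfg.eps, freqs)
            for scope, acc in (("diagonal", "d"), ("off-diagonal", "o")):
                a, b = _scope_entries(est, sim.truth, scope)
                if acc == "d":
                    sq_diag += ((a - b) ** 2).sum()
                    n_diag += a.size
                else:
                    sq_off += ((a - b) ** 2).sum()
                    n_off += a.size
        rows.append({
            "mean_depth": float(mu),
            "n_snps": m_snps,
            "rmse_diagonal": float(np.sqrt(sq_diag / n_diag)) if n_diag else np.nan,
            "rmse_offdiagonal": float(np.sqrt(sq_off / n_off)) if n_off else np.nan,
        })
    df = pd.DataFrame(rows)
    df.attrs["optimal_depth_diagonal"] = float(
        df.loc[df["rmse_diagonal"].idxmin(), "mean_depth"])
    df.attrs["optimal_depth_offdiagonal"] = float(
        df.loc[df["rmse_offdiagonal"].idxmin(), "mean_depth"])
    return df
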