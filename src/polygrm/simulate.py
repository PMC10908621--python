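"""Pedigree gene-drop simulator with identity-by-descent tracking.

The simulator produces, for a structured multi-family pedigree:

1. founder haplotypes — every founder carries ``psi`` uniquely labelled
   haplotype copies; at each SNP each copy is the reference allele
   independently with probability p_j, with p_j ~ U(0, 1) across SNPs
   (equivalently founder dosages are Bin(psi, p_j));
2. a gene drop — each offspring inherits psi/2 of each parent's psi
   haplotype labels. In ``unlinked`` mode the gamete is an independent
   uniform draw without replacement at every locus (bivalent meiosis, no
   double reduction). In ``linked`` mode homologues are paired randomly
   into bivalents per chromosome and one recombinant chromatid per bivalent
   is transmitted, with crossovers from a Poisson process on the genetic
   map (Haldane model);
3. the true realized relationship matrix — from label identity:
   theta_hi = mean over loci of the IBD fraction among the psi_h x psi_i
   cross pairs, F_i = mean IBD fraction among the psi(psi-1) ordered
   distinct within-individual pairs, reported as r_hi = sqrt(psi_h psi_i)
   theta_hi and r_ii = 1 + (psi_i - 1) F_i;
4. sequencing data — depths d_ij drawn i.i.d. from a negative binomial with
   mean mu and dispersion equal to the ploidy,
   P(d) = C(d + psi - 1, d) (psi/(mu+psi))^psi (mu/(mu+psi))^d,
   then reference reads Y_ij ~ Bin(d_ij, pi_ij) with
   pi_ij = (x_ij/psi)(1 - eps_j) + (1 - x_ij/psi) eps_j.

Everything is driven by one seeded ``numpy.random.Generator``, so a dataset
is fully reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import build_pedigree, classify_pairs
from .types import GRM, AlleleFreqs, GenotypeMatrix, ReadCounts, as_error_rates, as_ploidy

__all__ = [
    "SimConfig",
    "SimResult",
    "IBDGenome",
    "simulate_founders",
    "gene_drop",
    "true_grm",
    "simulate_depths",
    "simulate_reads",
    "read_success_prob",
    "simulate_dataset",
    "default_chromosome_map",
]


def default_chromosome_map(n_snps: int) -> list[tuple[float, int]]:
    """A 12-chromosome potato-like genetic map for linked mode.

    Equal 90-cM chromosomes with SNPs split as evenly as possible; users with
    a real map can pass their own list of (length_cM, n_snps) pairs.
    """
    base, extra = divmod(n_snps, 12)
    return [(90.0, base + (1 if c < extra else 0)) for c in range(12)]


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset.

    Defaults are the reference simulation conditions: 20 families (420
    individuals), shared tetraploidy, 10,000 unlinked SNPs, founder allele
    frequencies uniform on [0, 1], mean depth 5 and no sequencing error.
    """

    n_families: int = 20
    ploidy: int = 4
    n_snps: int = 10_000
    mean_depth: float = 5.0
    eps: float = 0.0
    seed: int | None = None
    mode: str = "unlinked"
    chromosomes: list[tuple[float, int]] | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError("ploidy must be an even integer >= 2 (gametes carry psi/2)")
        if self.mode not in ("unlinked", "linked"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.mode == "linked" and self.chromosomes is None:
            self.chromosomes = default_chromosome_map(self.n_snps)
        if self.chromosomes is not None:
            if sum(m for _, m in self.chromosomes) != self.n_snps:
                raise ValueError("chromosome SNP counts must sum to n_snps")


@dataclass
class IBDGenome:
    """Founder-haplotype labels per individual per locus: (N, M, psi) ints."""

    labels: np.ndarray
    individual_ids: list[str]
    family: np.ndarray  # per-individual family index, exploited by true_grm

    @property
    def n_individuals(self) -> int:
        return self.labels.shape[0]

    @property
    def n_loci(self) -> int:
        return self.labels.shape[1]

    @property
    def ploidy(self) -> int:
        return self.labels.shape[2]


@dataclass
class SimResult:
    """Bundle of observed data plus every truth object needed for scoring."""

    reads: ReadCounts
    genotypes: GenotypeMatrix
    truth: GRM
    pedigree: pd.DataFrame
    freqs: AlleleFreqs
    ibd: IBDGenome
    config: SimConfig

    @property
    def metadata(self) -> dict:
        return asdict(self.config)


def simulate_founders(ped: pd.DataFrame, config: SimConfig, rng: np.random.Generator):
    """Founder haplotypes: unique IBD labels plus per-label allele vectors.

    Returns ``(ibd_founders, hap_alleles, freqs)`` where ``hap_alleles`` maps
    (label, locus) -> 1 if the haplotype carries the reference allele.
    Founder dosages are then Bin(psi, p_j) by construction.
    """
    psi, m = config.ploidy, config.n_snps
    founders = ped.loc[ped["generation"] == "Gen1"]
    nf = len(founders)
    p = rng.uniform(0.0, 1.0, size=m)
    labels = np.arange(nf * psi, dtype=np.int32).reshape(nf, 1, psi)
    labels = np.broadcast_to(labels, (nf, m, psi)).copy()
    hap_alleles = (rng.random((nf * psi, m)) < p[None, :]).astype(np.int8)
    ibd = IBDGenome(labels, list(founders["id"]), founders["family"].to_numpy())
    return ibd, hap_alleles, AlleleFreqs(p, source="supplied")


def _gamete_unlinked(parent_labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent uniform choice of psi/2 of psi labels at every locus."""
    m, psi = parent_labels.shape
    idx = rng.permuted(np.broadcast_to(np.arange(psi), (m, psi)).copy(), axis=1)
    idx = idx[:, : psi // 2]
    return np.take_along_axis(parent_labels, idx, axis=1)


def _gamete_linked(
    parent_labels: np.ndarray,
    chrom_bounds: list[tuple[int, int]],
    positions_cm: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant chromatid per random bivalent, Poisson crossovers."""
    m, psi = parent_labels.shape
    gamete = np.empty((m, psi // 2), dtype=parent_labels.dtype)
    for lo, hi in chrom_bounds:
        pos = positions_cm[lo:hi]
        length = pos[-1] - pos[0] if hi > lo else 0.0
        pairing = rng.permutation(psi).reshape(psi // 2, 2)
        for b, (h1, h2) in enumerate(pairing):
            n_x = rng.poisson(length / 100.0)
            strand = np.full(hi - lo, rng.integers(2), dtype=np.int64)
            if n_x:
                cuts = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
                strand = (strand + np.searchsorted(cuts, pos, side="right")) % 2
            src = np.where(strand == 0, h1, h2)
            gamete[lo:hi, b] = parent_labels[np.arange(lo, hi), src]
    return gamete


def gene_drop(ped: pd.DataFrame, founders: IBDGenome, config: SimConfig,
              rng: np.random.Generator) -> IBDGenome:
    """Drop founder haplotype labels down the pedigree, one meiosis at a time."""
    psi, m = config.ploidy, config.n_snps
    ids = list(ped["id"])
    index = {i: k for k, i in enumerate(ids)}
    labels = np.zeros((len(ids), m, psi), dtype=np.int32)
    founder_index = {i: k for k, i in enumerate(founders.individual_ids)}
    for i, k in founder_index.items():
        labels[index[i]] = founders.labels[k]

    if config.mode == "linked":
        bounds, positions = [], []
        start = 0
        for length, count in config.chromosomes:
            bounds.append((start, start + count))
            positions.append(np.linspace(0.0, length, count))
            start += count
        positions_cm = np.concatenate(positions)

    for row in ped.itertuples():
        if row.sire is None:
            continue
        gametes = []
        for parent in (row.sire, row.dam):
            pl = labels[index[parent]]
            if config.mode == "unlinked":
                gametes.append(_gamete_unlinked(pl, rng))
            else:
                gametes.append(_gamete_linked(pl, bounds, positions_cm, rng))
        labels[index[row.id]] = np.concatenate(gametes, axis=1)
    return IBDGenome(labels, ids, ped["family"].to_numpy())


def dosages_from_ibd(ibd: IBDGenome, hap_alleles: np.ndarray) -> GenotypeMatrix:
    """Realized dosages: count reference alleles among inherited haplotypes."""
    m = ibd.n_loci
    x = hap_alleles[ibd.labels, np.arange(m)[None, :, None]].sum(axis=2)
    return GenotypeMatrix(x.astype(float), ibd.individual_ids, _snp_ids(m))


def _snp_ids(m: int) -> list[str]:
    return [f"snp{j + 1}" for j in range(m)]


def true_grm(ibd: IBDGenome, ploidy=None) -> GRM:
    """Realized relationship matrix from IBD label identity.

    Families carry disjoint label sets, so cross-family entries are exactly
    zero and the quadratic label-match counts are computed family by family
    (a one-hot matrix product per family) rather than over all N^2 pairs.
    """
    n, m, psi = ibd.labels.shape
    values = np.zeros((n, n))
    for f in np.unique(ibd.family):
        rows = np.flatnonzero(ibd.family == f)
        sub = ibd.labels[rows]  # (k, M, psi)
        uniq, inv = np.unique(sub, return_inverse=True)
        sub = inv.reshape(sub.shape)
        k, n_lab = len(rows), len(uniq)
        onehot = np.zeros((k, m, n_lab), dtype=np.float32)
        np.add.at(onehot, (np.arange(k)[:, None, None],
                           np.arange(m)[None, :, None], sub), 1.0)
        flat = onehot.reshape(k, m * n_lab)
        matches = flat @ flat.T  # total label-pair matches summed over loci
        theta = matches / (psi * psi * m)
        block = psi * theta
        # Diagonal: exclude the psi guaranteed self-matches per locus.
        f_inbreed = (np.diag(matches) - psi * m) / (psi * (psi - 1) * m)
        np.fill_diagonal(block, 1.0 + (psi - 1) * f_inbreed)
        values[np.ix_(rows, rows)] = block
    n_used = np.full((n, n), m, dtype=np.int64)
    return GRM(values, n_used, ibd.individual_ids, metadata={"estimator": "true-ibd"})


def simulate_depths(config: SimConfig, n_individuals: int,
                    rng: np.random.Generator) -> np.ndarray:
    """I.i.d. negative-binomial depths, mean mu and dispersion = ploidy."""
    mu, psi = config.mean_depth, config.ploidy
    if mu == 0:
        return np.zeros((n_individuals, config.n_snps), dtype=np.int64)
    prob = psi / (mu + psi)
    return rng.negative_binomial(psi, prob, size=(n_individuals, config.n_snps))


def read_success_prob(x: np.ndarray, ploidy, eps) -> np.ndarray:
    """pi_ij = (x/psi)(1 - eps) + (1 - x/psi) eps, the per-read reference prob."""
    psi = as_ploidy(ploidy, x.shape[0])
    eps = as_error_rates(eps, x.shape[1])
    r = x / psi[:, None]
    return r * (1.0 - eps[None, :]) + (1.0 - r) * eps[None, :]


def simulate_reads(x: GenotypeMatrix, depths: np.ndarray, eps, ploidy,
                   rng: np.random.Generator) -> ReadCounts:
    """Binomial read sampling of each genotype with per-read error eps."""
    pi = read_success_prob(x.values, ploidy, eps)
    y = rng.binomial(depths, pi)
    return ReadCounts(y, depths, list(x.individual_ids), list(x.snp_ids))


def simulate_dataset(config: SimConfig) -> SimResult:
    """End-to-end dataset: pedigree, gene drop, truth GRM, depths and reads."""
    rng = np.random.default_rng(config.seed)
    ped = build_pedigree(config.n_families)
    founders, hap_alleles, freqs = simulate_founders(ped, config, rng)
    ibd = gene_drop(ped, founders, config, rng)
    genotypes = dosages_from_ibd(ibd, hap_alleles)
    truth = true_grm(ibd)
    depths = simulate_depths(config, len(ped), rng)
    reads = simulate_reads(genotypes, depths, config.eps, config.ploidy, rng)
    return SimResult(reads, genotypes, truth, ped, freqs, ibd, config)


def class_index_map(ped: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Map each relationship class to (row, col) index arrays into the GRM."""
    pairs = classify_pairs(ped)
    index = {i: k for k, i in enumerate(ped["id"])}
    out = {}
    for cls, grp in pairs.groupby("cls"):
        rows = grp["id1"].map(index).to_numpy()
        cols = grp["id2"].map(index).to_numpy()
        out[cls] = (rows, cols)
    return out
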