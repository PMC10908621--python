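# Methods

## Relatedness parameterisation

`polygrm` estimates genomic relationship matrices (GRMs) for autopolyploid
populations with polysomic inheritance. Relatedness is parameterised by the
coancestry coefficient θ_hi (probability that a random allele from
individual *h* and one from *i* are identical-by-descent) and the inbreeding
coefficient F_i (probability that two distinct alleles within *i* are IBD).
The reported coefficients are

    r_hi = sqrt(ψ_h ψ_i) θ_hi          (off-diagonal)
    r_ii = 1 + (ψ_i − 1) F_i           (diagonal, self-relatedness)

where ψ_i ≥ 2 is the (possibly individual-specific) ploidy. Under this
scaling a non-inbred individual has self-relatedness 1 at any ploidy, and a
tetraploid full-sib-mated offspring has expectation 1.25.

## Genotype estimator

For called dosages X_ij ∈ {0, …, ψ_i} and reference-allele frequencies p_j,
the method-of-moments (VanRaden method 1 style) estimator is

    G_hi = Σ_j (X_hj − ψ_h p_j)(X_ij − ψ_i p_j)
           / ( sqrt(ψ_h ψ_i) Σ_j p_j (1 − p_j) ).

With ψ ≡ 2 this is exactly the classical diploid VanRaden estimator. In the
dosage-proportion representation R_ij = X_ij/ψ_i the estimator is
sqrt(ψ_h ψ_i) Σ (R_hj − p_j)(R_ij − p_j) / Σ p_j(1−p_j); datasets that share
R (e.g. a tetraploid dataset whose dosages are exactly twice a diploid one)
therefore yield GRMs that are *proportional* with the exact factor
sqrt(ψ_h ψ_i)/2, not equal — "diploidising" polyploid calls rescales, but
does not otherwise change, the estimates.

Allele frequencies default to the missing-aware sample estimate
p̂_j = mean over called individuals of X_ij/ψ_i. Frequencies estimated from
the study sample introduce a small O(1/N) downward bias in the GRM
(pronounced in small, strongly structured samples); supplying external
frequencies avoids it.

## Sequencing-data estimator

With genotyping-by-sequencing or other HTS data, the genotype is latent;
the observations are Y_ij reference reads out of depth d_ij. Reads are
modelled as binomial samples of the genotype's alleles with a per-read
miscall probability ε_j:

    Y_ij | X_ij = x ~ Bin(d_ij, π_ij),
    π_ij = (x/ψ_i)(1 − ε_j) + (1 − x/ψ_i) ε_j.

Writing S_ij = Y_ij/d_ij, moment calculations under this model give the
corrected estimators (γ_j = 1 − 4ε_j(1−ε_j), η_j = 1 − 4p_j(1−p_j),
δ_ij = 1 − 1/d_ij):

    off-diagonal: G_hi = sqrt(ψ_h ψ_i)
        Σ_j [ (S_hj − p_j)(S_ij − p_j) − ε_j² η_j ] / γ_j
        / Σ_j p_j (1 − p_j),                         over d_hj, d_ij ≥ 1

    diagonal: G_ii = ψ_i
        Σ_j [ (S_ij − p_j)² − A_ij ] / (γ_j δ_ij)
        / Σ_j p_j (1 − p_j),                         over d_ij ≥ 2
    A_ij = p_j(1−p_j)(1 − γ_j δ_ij) + ε_j(η_j − (1−ε_j) δ_ij).

Two properties, both verified in the test suite by exact enumeration over
(X, Y):

* E[((S−p)² − A)/(γδ)] = p(1−p)/ψ under Hardy–Weinberg proportions, so the
  diagonal is unbiased — the term removes the read-sampling variance that
  inflates naive self-relatedness at low depth;
* E[(S_h−p)(S_i−p)] = ε²η for unrelated individuals, so the off-diagonal is
  centred; it depends on the data only through S, making relatedness (but
  not self-relatedness) invariant to rescaling all depths.

Depths of 0 and 1 carry no information about inbreeding (a single read
cannot show two alleles), hence the d ≥ 2 restriction on the diagonal; the
diagonal and off-diagonal sums for the same individual deliberately use
different SNP sets.

Missing data (d = 0, or missing dosage calls) are handled
pairwise-complete: each entry sums only over SNPs observed in both members
of the pair, with a matching per-entry denominator, implemented as
indicator-matrix products so the cost is a constant number of N×M by M×N
multiplications. Frequencies are estimated once, globally, from all
individuals with data (not per entry); the per-entry alternative is noted
but not implemented.

For read data the frequency estimator is the depth-weighted ratio
q̂_j = Σ_i Y_ij / Σ_i d_ij, error-adjusted as
p̂_j = clamp((q̂_j − ε_j)/(1 − 2ε_j), 0, 1), since E[q̂] = ε + (1−2ε)p under
the read model. An unadjusted mode returns q̂ directly. SNPs with p̂ ∈ {0, 1}
are excluded from every sum (their denominator terms vanish).

ε defaults to 0; a scalar is broadcast, per-SNP vectors are accepted, and
ε ≥ 0.5 is rejected (a read then carries no allele information). Typical
HTS error rates are 0.1–0.3%; ε is treated as known, shared across
individuals at a SNP.

## Ratio baselines

The common uncorrected practice plugs Z_ij = ψ_i Y_ij/d_ij into the
genotype estimator. Two denominator conventions are implemented:

* `expected` — sqrt(ψ_h ψ_i) Σ p̂(1−p̂): with error-free data at high depth
  this equals the genotype GRM, and its off-diagonals coincide exactly with
  the corrected estimator at ε = 0; its diagonal is inflated by roughly
  ψ E[1/d] at low depth.
* `sample-variance` — the summed per-SNP sample variance of the observed Z
  columns (an AGHmatrix-style default). Read sampling inflates var(Z) as
  depth falls, shrinking all estimates toward zero. Because the summed
  sample variance approximately equals the mean diagonal of the numerator,
  this convention forces the GRM's mean diagonal to ≈ 1; a consequence
  worth knowing is that its *errors* are not uniformly worse — for entries
  whose true value is exactly 1 (non-inbred self-relatedness) or exactly 0
  (unrelated pairs) the shrinkage cancels or costs nothing, while every
  entry whose truth is away from {0, 1} (inbred diagonals, related pairs)
  is systematically attenuated. Missing Z cells are excluded from the
  variance; exact replication of any particular external package is not
  attempted.

## Simulator

The simulator reproduces a structured multi-family pedigree study design:
each family has one sire mated to 5 unrelated dams (Gen1, 6 founders), each
pair producing 2 full sibs (Gen2, 10), each full-sib pair mating to produce
1 inbred offspring (Gen3, 5). Defaults are the reference conditions: 20
families (420 individuals), shared tetraploidy, 10,000 unlinked SNPs,
founder allele frequencies uniform on [0, 1], negative-binomial depths and
binomial reads. The closed-form relationship census per family is
6/10/5 self (G1/G2/G3), 10 parent–offspring (G2–G3), 20 parent–offspring
(G1–G2), 5 full-sib, 10 grandparent–offspring, 40 half-sib, 10 half-cousin,
40 pibling–half-nibling pairs, and 75 within-family unrelated pairs; all
cross-family pairs are unrelated.

* **Founders** carry ψ uniquely labelled haplotypes; each label is the
  reference allele at SNP j independently with probability p_j (dosages are
  therefore Bin(ψ, p_j)).
* **Gene drop**: each gamete takes ψ/2 of a parent's ψ haplotype labels.
  Unlinked mode (default) draws uniformly without replacement at every
  locus independently — bivalent meiosis with free recombination. Linked
  mode pairs homologues randomly into bivalents per chromosome and
  transmits one recombinant chromatid per bivalent with Poisson (Haldane)
  crossovers on the genetic map; a 12-chromosome, 90 cM-each potato-like
  default map is supplied. Linkage changes only the variance of realized
  relatedness, not class means, and the estimators are locus-order-free,
  so unlinked mode suffices for estimator validation. Kosambi interference
  and quadrivalent pairing (hence double reduction) are not modelled; with
  double reduction, Gen3 self-relatedness would exceed its bivalent
  expectation of 1.25. Odd ploidies cannot produce balanced gametes and are
  rejected by the simulator (the estimators themselves accept them).
* **Truth**: realized relatedness from label identity — θ̂_hi is the mean
  over loci of the IBD fraction among the ψ_h × ψ_i label cross-pairs, and
  F̂_i the mean IBD fraction among the ψ(ψ−1) ordered distinct
  within-individual pairs. Families have disjoint label sets, so
  cross-family truth is exactly 0 and the quadratic match counts are
  computed family-by-family via one-hot matrix products.
* **Sequencing**: depths are i.i.d. negative binomial with mean μ and
  dispersion equal to the ploidy, P(d) = C(d+ψ−1, d) (ψ/(μ+ψ))^ψ
  (μ/(μ+ψ))^d — e.g. P(d=0) = (4/9)⁴ ≈ 0.039 at ψ=4, μ=5 — constant μ
  across SNPs by default (per-SNP means can be supplied by passing a
  vector); reads then follow the binomial error model above. One seeded
  `numpy.random.Generator` drives all stages; the seed is mandatory and
  echoed in outputs.

What the generator does *not* emulate: locus-specific depth profiles,
overdispersed (beta-binomial) read counts, allelic bias, preferential
pairing, selection or non-random mating. Passing tests therefore
demonstrate correctness under the stated model, not robustness to these
real-data features; the estimator's known behaviour under overdispersion
(unchanged relatedness, inflated self-relatedness) is discussed in the
literature but out of scope here.

## SNP filtering and the HWE test

The GBS filter cascade flags SNPs with minor allele frequency below 0.01,
with ≥ 50% zero-depth calls (boundary inclusive), or with mean depth
(zeros included) strictly above 500; retained SNPs can be split into
low/high sets at mean depth 50, ties going high. Thresholds are the
defaults used for potato GBS panels and are all configurable.

The Hardy–Weinberg filter is a genotype-call-free likelihood-ratio test on
read counts for a shared ploidy ψ. Per SNP, individual genotype likelihoods
L_i(x) = Bin(Y_i; d_i, π(x)) are combined under (a) the null — genotype
frequencies Bin(ψ, p), the single parameter p maximised by bounded Brent
search on [1e−6, 1−1e−6] (xatol 1e−10) — and (b) the alternative — free
frequencies on the ψ-simplex, maximised by EM to relative log-likelihood
change < 1e−8 or 500 iterations. The statistic 2(logL₁ − logL₀) is referred
to χ² with ψ − 1 degrees of freedom (ψ free parameters vs 1); this df is an
assumption of the implementation. Zero-depth individuals contribute
nothing; likelihood rows are max-normalised to avoid underflow at extreme
depths, and degenerate SNPs get NaN p-values and are retained. Monomorphic
SNPs sit at the boundary where null and alternative coincide, giving
LRT ≈ 0 and p ≈ 1. Calibration is checked at N=200 tetraploids, depth 30,
with null frequencies drawn U(0.1, 0.9) — chosen so every genotype class
has non-negligible expected frequency, as the χ² approximation requires an
interior truth; with frequencies near 0 or 1 the test is conservative. The
test is exactly invariant to swapping reference and alternate labels.

## Evaluation

Errors are summarised per relationship class with errors pooled across
replicates: bias = mean error, variance = population variance of errors,
RMSE = sqrt(mean squared error), so RMSE² = bias² + variance holds to
numerical precision. The flat convention that sums all off-diagonal squared
errors and divides by N (rather than by the number of pairs) is available
as `normalization="per-individual"` for comparability with that reporting
style. GRM-vs-GRM agreement uses Spearman rank correlation, Lin's
concordance correlation coefficient
ccc = 2 cov(a,b)/(var a + var b + (mean a − mean b)²), and Bland–Altman
statistics (mean difference, mean ± 2 SD limits); ccc is flagged undefined
for zero-variance inputs.

Two experiment drivers are provided. `run_method_comparison` scores any
subset of {genotype-truth, hts, hts-err, ratio-expected,
ratio-sample-variance} per class over replicated datasets.
`run_depth_sweep` fixes the total sequencing effort N·M·μ and trades SNPs
against depth (M = round(total/(N·μ))), reporting diagonal and off-diagonal
RMSE per depth and the RMSE-minimising depth. Package defaults are
desk-scale (2 families, 100 replicates); the reference design (20 families,
10,000 SNPs, 500–1000 replicates) is reachable through the same flags. The
test suite uses 2–5 families, 2,000 SNPs and 10–600 replicates per
scenario, sizes chosen so each Monte-Carlo comparison has enough power to
resolve the systematic effect it checks; scaled-down sweeps verify shape
and ordering, not exact optimal depths.

## Numerical and design choices

* Symmetry is enforced by averaging G with its transpose (pure
  floating-point drift, relative 1e−10 tolerance in tests); a naive
  per-pair loop oracle agrees with the matrix implementation to that
  tolerance on random instances with missingness.
* GRM CSVs are written at %.17g and parsed with round-trip float precision,
  so write→read is bit-exact, NaN entries round-trip via "NA".
* Missing dosage tokens accepted on read: "NA", empty cell, "-9"; "NA" is
  written.
* VCF ingestion uses FORMAT/AD exclusively (the estimators consume raw
  counts, never GT calls); multiallelic records are skipped, not split —
  the read model is biallelic. SNP identity is the (CHROM, POS, REF, ALT)
  string; positions are not otherwise interpreted.
* The csv-pair reader accepts either orientation (individuals-by-SNPs or
  SNPs-by-individuals) via a flag, since external count matrices ship both
  ways.

## Known limitations

* ε and ploidy are assumed known; no in-package estimation of either.
* The HWE test requires a shared ploidy across the tested individuals.
* No beta-binomial overdispersion, allelic bias, double reduction, or
  pooled-sample support; no imputation (missingness is handled
  pairwise-complete under a missing-at-random assumption).
* Frequencies estimated from small, highly related samples bias the GRM
  downward; the package does not correct for this beyond allowing external
  frequencies.
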