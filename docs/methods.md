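# Methods

## The model

`genopca` infers population structure from an m-SNP x n-sample genotype
matrix G with entries in {0, 1, 2} (minor-allele dosage). Each SNP row is
centered and rescaled, giving the standardized matrix

    Y = diag(s)^-1 G - rho 1_n^T,      rho_j = gbar_j / s_j,

and the top-K principal components of Y are the maximum-likelihood solution
of probabilistic PCA, y_i = C x_i + eps_i with x_i ~ N(0, I) and isotropic
Gaussian noise, in the zero-noise limit. The EM algorithm for that model
collapses to alternating least squares:

    E-step:  X = (C^T C)^-1 C^T Y
    M-step:  C = Y X^T (X X^T)^-1

Each iteration touches Y only through thin matrix products, and Y itself is
never formed: products with the raw integer matrix G are computed by the
Mailman kernel (below), followed by a rank-one correction for the centering
term and a sparse correction for missing cells. The fixed point of the
iteration spans the top-l principal subspace; `finalize_pcs` orthonormalizes
the converged basis, projects the data onto it, and extracts ordered,
sign-fixed, orthonormal PCs from the small l x n SVD.

### Assumptions

- SNPs are unlinked (LD pruning happens upstream) and biallelic.
- Missing genotypes are mean-imputed: a missing cell standardizes to exactly
  0. Inside the kernel the cell holds raw 0 and the centering term is
  corrected per missing cell, so the result is identical to dense mean
  imputation (verified against the dense oracle to 1e-10).
- Zero-variance SNPs must be removed before standardization
  (`drop_monomorphic` / `qc_filter`); the scale would be undefined.

### Row-scaling convention

Two common conventions differ by one scalar per SNP and leave all principal
directions unchanged. The default (`scale_mode="norm"`) sets
s_j = sqrt(sum (g - gbar)^2) over called cells, so each standardized row has
unit norm; `scale_mode="sd"` uses the per-SNP standard deviation times
sqrt(n). The unit-norm convention makes ||Y||_F^2 = m exactly, which the
reconstruction-error tracker uses.

## The Mailman kernel

A height-h block of G over {0,1,2} is a selection of columns of the matrix
of all 3^h base-3 vectors, so the block is stored as one integer code per
column. With h chosen as the smallest integer with 3^h > n, a block-vector
product costs O(n + 3^h) = O(n) instead of O(h n): a full m x n product runs
in O(mn / log3 n). Taller matrices are cut into contiguous segments (the
last may be shorter) that share one decomposition.

Both directions reuse the same decomposition — this is the point of the
left-multiplication variant. The right product scatters b into a code-indexed
accumulator and collapses it digit by digit (least significant first); the
left product expands f over the code tree (most significant first) and
gathers per column. The digit order (first row of a segment = most
significant) is fixed identically in the decomposition and both recursions.
Accumulation is always double precision; the per-segment work buffer never
exceeds 3^h < 3n entries, and the code table U is never materialized.

Both paths are verified bit-tight (<= 1e-9) against naive integer products
on hundreds of random instances, and `operation_counts` exposes the exact
per-segment work for the cost property test.

## Defaults and tunable parameters

| parameter | default | why |
|---|---|---|
| `l` (latent dim) | 2K | extra directions absorb early-iteration noise in the top K; standard practice for this estimator |
| `max_iterations` | K | accurate across realistic divergence levels; convergence below is usually reached earlier only for strong structure |
| `convergence_tol` | 1e-6 | change in MEV between successive iterate subspaces; stop early when below |
| `seed` | required | C is initialized with standard-normal entries; runs are bitwise reproducible |
| `kernel` | "mailman" | "dense" is the reference path; both agree to <= 1e-8 per iteration from identical seeds |
| QC thresholds | missing <= 1%, MAF >= 1%, HWE p >= 1e-6 | conventional array-data panel filters |

A rank collapse of the iterate (numerically singular Gram) re-randomizes the
basis and continues; Gram singularity is detected by an eigenvalue check
(ratio below 1e-12), not by trusting Cholesky to fail.

## The simulator

`simulate_genotypes` draws, per SNP, an ancestral frequency
f0 ~ Uniform(0.05, 0.95); each of q subpopulations drifts independently,
f_l ~ Normal(f0, f0 (1 - f0) Fst), clipped to {0, 1} outside [0, 1]; each
diploid individual in population l draws Binomial(2, f_l). One seeded
generator drives ancestral frequencies, then the m x q drifted frequency
matrix, then genotype blocks population by population — fixtures are stable
across releases. Clipping happens per draw; the marginal law is unaffected
by the order.

What it does *not* emulate: linkage disequilibrium, mutation/recombination
processes, admixture gradients, genotyping batch effects, or call-rate
structure. Passing accuracy and calibration tests on these panels therefore
shows the estimator and scan behave correctly under the idealized divergence
model, not that real-data confounders (LD leakage into PCs, array artifacts)
are handled.

### Identifiability and the choice q = K + 1

Row-centering removes one sample-side dimension, so q subpopulations produce
exactly q - 1 eigenvalues above the Marchenko-Pastur bulk. If one asks for
K = q components, the K-th direction lies inside the noise bulk, where
eigenvalue spacings are O(n^-2/3): no iterative method can align it, the
exact solver's K-th vector is effectively arbitrary, and the subspace
overlap is capped near (K-1)/K. The accuracy study therefore simulates
q = K + 1 subpopulations (6 for K=5, 11 for K=10), making every reported
direction identifiable; this is the only configuration under which accuracy
near 1 is achievable at all, for this or any other solver.

### Accuracy metric

MEV = ||U^T V||_F^2 / K, the mean squared projection of one orthonormal PC
set onto the span of the other (the squared form is the one that equals the
explained-variance fraction and gives exactly 1 for identical subspaces).
It is symmetric and invariant to rotations within either subspace.

## The selection scan

Under the model, the part of a standardized SNP not explained by the score
directions, projected onto a score, is Gaussian with a SNP-independent
variance, giving d_jk^2 / sigma_k^2 ~ chi^2_1 under neutrality, with
sigma_k^2 the genome-wide unbiased sample variance of column k of d. The
combined statistic sums the K per-PC statistics (chi^2_K).

A least-squares residual against all K score directions is orthogonal to
every score, making the projection identically zero — the literal formula is
degenerate. The operational statistic residualizes PC k against the other
K-1 score directions only and projects onto the unit-normalized k-th score;
for mutually orthogonal scores (always true from an SVD) this equals the
plain projection y_j . x_hat_k, the classic PC differentiation statistic.
The literal form is kept behind `projection="full"` for inspection. Scores
are unit-normalized so sigma_k^2 is comparable across PCs; p-values are also
reported as log10(p) computed in log space, so they survive below 1e-308.

The scan panel may differ from the PCA panel (it is typically larger and not
LD-pruned); sigma^2 is estimated on the scan panel. Sample alignment between
the score file and the scan panel is by sample-id intersection in .fam
order. Significance uses a Bonferroni threshold alpha / ((K + 1) x m_scan)
— K per-PC tests plus the combined one. Significant SNPs are clustered
greedily into 1 Mb windows centered on the most significant unassigned SNP
(ties broken by lower position); the regional allele-frequency follow-up is
a pooled two-proportion Z-test of each region against all others, with a
caller-supplied Bonferroni factor (loci x regions).

## Numerical choices

- Gram solves: l x l eigenvalue check then Cholesky; `RankError` when the
  smallest eigenvalue is below 1e-12 of the largest.
- Per-iteration QR of the iterate for the convergence metric only; the
  iteration itself applies the normal-equations updates unchanged.
- PC signs: the entry of largest magnitude in each loading is made positive
  (deterministic output files); ties resolved by the first such entry.
- HWE: Pearson chi-square with 1 df on observed vs expected genotype counts,
  no continuity correction; monomorphic SNPs get p = 1 (they are removed by
  the zero-variance rule anyway). MAF uses called alleles only.
- .bim positions are 1-based; all windows are 1-based inclusive.
- The exact reference in accuracy comparisons is ARPACK (`svds`, tol=0) on
  the materialized standardized matrix in double precision — at the study
  sizes this is the full-SVD top-K to machine precision.

## Problem sizes used in the checks

The accuracy study in `scripts/acceptance.py` runs the full 50,000 x 10,000
design. The test suite exercises the same claims at desk scale, with sizes
chosen so each property genuinely holds there:

- accuracy trend: 10,000 x 2,000 panels across Fst in {0.001, 0.002, 0.005}
  show the same monotone improvement as the full-size table;
- the K=10 configuration is scaled 2.5x down with Fst scaled 2.5x up
  (20,000 x 4,000 at Fst = 0.0025): the spike strength grows like m x Fst at
  fixed m/n, so this preserves the spike-to-bulk geometry of the full-size
  Fst = 0.001 run and the near-1 overlap;
- scan calibration: 50,000 SNPs x 2,000 samples (q = 5), large enough that
  the +/-0.005 type-I band is several Monte-Carlo standard errors wide.

## Known limitations

- The Mailman kernel requires discrete genotypes; imputed dosages are out of
  scope (use the dense path on hard calls, or a different tool).
- sigma^2 of the noise model is not estimated (zero-noise limit); the
  probabilistic missing-data E-step is likewise out of scope — missing calls
  are mean-imputed only.
- With K at or above the number of identifiable directions (q - 1 under the
  divergence model), trailing components are noise directions: their scores
  are reproducible but not meaningful, and subspace overlap with any exact
  solver will be poor (see Identifiability above).
- Single-threaded by design; memory is O(mn / log3 n) extra for the stored
  decomposition (~220 MB for 50,000 x 10,000).
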