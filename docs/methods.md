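# Methods

## Data model and preprocessing

A gene's splicing observations are intron-excision ratios in [0, 1], one
table per tissue, rows = events (`chrom:start:end:cluster` IDs, 1-based
inclusive coordinates), columns = subjects. Missing tokens `NA`, `NaN` and
the empty string all map to the missing marker. Stacking tables over the
union of events yields the raw n × p × t array with NaN holes.

Cohort filters drop tissues with fewer than 200 available samples and
subjects with data in fewer than 13 tissues (5 in brain-cluster mode, via a
tissue whitelist and `min_tissues_per_subject=5`). Because dropping a
tissue changes subject counts and vice versa, the filter iterates to a
fixpoint; applying it to its own output is the identity.

Missingness is classified per (event, tissue): **structural** when no
subject with any data in that tissue observes the event, **technical**
otherwise. Events structurally absent from more than 20 tissues are
removed; genes left with fewer than two events are untestable. Structural
cells are filled with the minimum observed ratio *within the gene's
splicing matrix* — per gene, not transcriptome-wide, which keeps genes
independent and errs toward biological zero. Technical cells are filled by
EM for a multivariate normal on the subject × (event, tissue) unfolding.
The EM uses exact sufficient statistics (conditional means plus the
conditional covariance of each missingness pattern), a 1e-4 ridge on the
covariance for stability at small n, and is fitted on a seeded bootstrap
resample of subjects; the single imputation used downstream is the
conditional mean, clipped to [0, 1]. Imputation is a pure function of
(data, seed). `impute_benchmark` reproduces the masking diagnostic: hide
10% of a complete matrix at random, impute, report RMSE on the hidden
cells; on correlated Gaussian data the EM beats column-mean imputation.

## CP decomposition

Rank is tied to the event count, `r = p` (multipliers 0.5 / 1.5 available
for sensitivity analysis; fractional ranks round half-up). The Kruskal
screen `min(2p + t, 3p) ≥ 2r + 2` (valid because n > p gives the subject
factor full column rank) is reported as a margin, not enforced — a
non-unique factorization still yields a usable subject-loading basis for
the downstream sparse CCA.

ALS updates each factor by a least-squares solve through the pseudo-inverse
of the Hadamard product of the other factors' Gram matrices; rank-deficient
solves therefore never crash. Initialization is i.i.d. standard normal from
the given seed (one restart by default, `n_restarts` keeps the best fit).
Convergence is a change in fit `1 − ‖𝒢 − 𝒢̂‖_F/‖𝒢‖_F` below 1e-6, capped at
500 iterations; the fit trace is monotone non-decreasing up to 1e-10 slack.
On exit, factor columns are scaled to unit L2 norm with scales absorbed
into component weights, and each component's sign is fixed by making the
first nonzero tissue-loading entry nonnegative (compensated in the subject
column), so identical seeds give bitwise-identical models.

## Sparse CCA

The rank-1 penalized matrix decomposition alternates
`w ← S(Zu, λ_w)/‖·‖₂` and `u ← S(Zᵀw, λ_u)/‖·‖₂` on `Z = XᵀY`
(column-standardized X and Y), with each λ found by binary search as the
smallest value putting the L1 norm of the unit-L2 vector at its bound
(λ = 0 when already feasible; ties resolve toward smaller λ, the denser
solution). Initialization is the leading right singular vector of Z, so the
procedure is deterministic; with inactive penalties it reduces to the
rank-1 SVD. The canonical covariance `d = wᵀZu` is kept nonnegative by
joint sign flips.

Penalties are tied across a 10-point grid `c_i = f·√(dim_i)`,
`f ∈ linspace(0.1, 0.7)`, and selected once on the undeflated Z by the
permutation z-score of the Fisher-transformed canonical correlation against
25 row-permutations of Y (permutations shared across grid points). The
selected pair is reused for all p deflation steps
`Z_{k+1} = Z_k − d_k w_k u_kᵀ`. Y is standardized before fitting
(`standardize=true`), matching the usual treatment of both sides in PMD.
Zero-variance genotype columns are excluded and reinserted as zero rows of
W; requesting more factors than `min(q, r)` zero-fills the excess with a
warning.

## Association test

Harmonization matches SNPs by ID, flips the z sign when the GWAS effect
allele is the model's reference allele, and drops palindromic (A/T, C/G)
variants outright — no allele-frequency input is consumed, so strand cannot
be resolved for them. `T = zᵀW(WᵀΣW)⁻Wᵀz` uses an eigendecomposition-based
pseudo-inverse keeping eigenvalues ≥ λ_max/30; this single code path covers
both the well-conditioned case (where it equals the dense inverse) and the
near-singular case. The χ² reference has df = retained eigenvalue count —
the mathematically consistent choice for a truncated quadratic form, and
the one under which the null simulations calibrate. Statistics within −1e-8
of zero are clamped to 0. Optional LD shrinkage `Σ ← (1−λ)Σ + λI` exists
for ill-conditioned panels but defaults to off. Bonferroni divides α by the
number of testable genes only.

## Null simulation and the synthetic generator

Each null replicate draws genotype rows i.i.d. MVN(0, Σ) for n = 5000
individuals, an independent N(0, 1) trait, and computes per-SNP marginal
OLS slope/se z-scores (the standard GWAS estimator; the protocol fixes the
simulation but not the estimator). The fast path draws `z ~ MVN(0, Σ)`
directly — the asymptotic null law of those z-scores — and is statistically
indistinguishable from the individual-level path in the tests; it makes
10⁵-replicate tail checks run in milliseconds. Replicates use counter-based
seed streams (seed, replicate index), so batched and serial runs agree.
When no reference Σ is supplied, AR(1) with ρ = 0.5 stands in for a local
LD block.

The synthetic gene generator emulates the structure the model assumes:
AR(1)-correlated Gaussians thresholded at Hardy–Weinberg quantiles give
dosages in {0, 1, 2} that inherit the LD; two latent components are each
driven by the same small causal SNP set with `h2_component` of their
variance genetic; events load on components with normal weights, tissues
with uniform positive weights; observations are the component mixture plus
N(0, 0.05²) noise, affinely mapped into [0.05, 0.95]; structural holes
blank whole (event, tissue) slabs (keeping each event in ≥ 2 tissues) and
technical holes are MCAR cells, both at 5% by default. It does **not**
emulate read-depth-dependent noise, cluster-level sum constraints among
LeafCutter events, covariate structure (age, batch, ancestry), or realistic
minor-allele-frequency spectra — passing tests show the statistics behave
as designed under the assumed generative model, not that the model captures
every property of real cohort data.

## Problem sizes and numerical choices

The shipped validation uses one gene fixture (n = 300 training subjects,
p = 4 events, t = 5 tissues, q = 50 cis-SNPs) with 10,000 individual-level
null replicates at n = 5000 for the 0.05/0.01 calibration, 100,000 fast
replicates for the 10⁻³ tail, and 50 seeds for recovery — sizes at which
every binomial confidence band is decisive while a full run stays within a
few minutes on one CPU. Calibration is judged against binomial 99%
confidence intervals of the nominal level; recovery requires a true causal
SNP among the two top-weight SNPs in ≥ 80% of seeds.

Known limitations: the 1-Mb cis window is anchored at the TSS only (closed
interval); no covariate correction or quantile normalization of ratios; no
genotype imputation, liftover or BGEN input; palindromic SNPs are always
dropped; deep-tail type-I rates (below 10⁻⁵) need more replicates than the
desk-scale protocol runs.
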