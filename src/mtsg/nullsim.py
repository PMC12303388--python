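"""Null simulation of GWAS summary statistics and a synthetic-gene generator.

Type-I-error protocol: for each replicate draw an individual-level genotype
matrix X1 (n = 5000 rows, i.i.d. MVN with covariance equal to the LD matrix),
an independent standard-normal trait Y1, compute per-SNP marginal OLS
z-scores, and feed them through the gene test.  A fast path draws
z ~ MVN(0, Sigma) directly — the asymptotic null distribution of those
z-scores — so deep-tail calibration runs at scale.

The synthetic-gene generator plants the generative structure the model
assumes: a handful of latent splicing components driven by a few causal
cis-SNPs, shared across tissues with tissue-specific loadings, observed as
noisy ratios in [0, 1] with both structural (tissue-wide) and technical
(subject-level) holes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .assoc import gene_test
from .formats_io import GenotypeBlock, LdMatrix
from .preprocess import MissingKind


def ar1_ld(q: int, rho: float = 0.5) -> LdMatrix:
    """AR(1) correlation: sigma_ij = rho^|i-j| — a standard stand-in for a
    local LD block when no reference panel is supplied."""
    idx = np.arange(q)
    sigma = rho ** np.abs(idx[:, None] - idx[None, :])
    return LdMatrix(sigma, [f"snp{i}" for i in range(q)])


@dataclass
class SimConfig:
    n_gwas: int = 5000
    n_reps: int = 10_000
    alpha_levels: tuple[float, ...] = (0.05, 0.01)
    seed: int = 0
    fast_path: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not all(0 < a < 1 for a in self.alpha_levels):
            raise ValueError("alpha levels must lie in (0, 1)")


def _chol_psd(sigma: np.ndarray) -> np.ndarray:
    """Cholesky factor, projecting to the nearest PSD matrix if needed."""
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("LD matrix not PSD; projecting to nearest PSD")
        lam, Q = np.linalg.eigh((sigma + sigma.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
        fixed = Q @ np.diag(lam) @ Q.T
        return np.linalg.cholesky(fixed + 1e-10 * np.eye(len(lam)))


def marginal_ols_z(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-SNP slope/se z-scores from simple linear regression, vectorized."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (Xc * Xc).sum(axis=0)
    sxy = Xc.T @ yc
    syy = float(yc @ yc)
    safe = np.where(sxx == 0, 1.0, sxx)
    beta = sxy / safe
    rss = syy - beta * sxy
    se = np.sqrt(np.clip(rss, 0, None) / (n - 2) / safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where((sxx == 0) | (se == 0), 0.0, beta / se)
    return z


def simulate_null_sumstats(
    config: SimConfig, sigma: LdMatrix, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One replicate of null GWAS z-scores over the LD block."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = _chol_psd(sigma.sigma)
    q = sigma.sigma.shape[0]
    if config.fast_path:
        return L @ rng.standard_normal(q)
    X1 = rng.standard_normal((config.n_gwas, q)) @ L.T
    Y1 = rng.standard_normal(config.n_gwas)
    return marginal_ols_z(X1, Y1)


@dataclass
class Type1Result:
    rates: dict[float, float]
    ci_low: dict[float, float]
    ci_high: dict[float, float]
    n_reps: int
    pvalues: np.ndarray | None = None


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    lo, hi = stats.binom.interval(level, n, max(k, 0) / n) if n else (0, 0)
    return lo / n, hi / n


def type1_experiment(
    W: np.ndarray,
    sigma: LdMatrix,
    config: SimConfig,
    return_pvalues: bool = False,
) -> Type1Result:
    """Empirical rejection rates of the gene test under the null.

    Replicates use counter-based seed streams (seed, rep index) so serial
    and batched runs agree.  The fast path vectorizes the quadratic form
    across replicates; the individual-level path loops the paper-faithful
    simulation.
    """
    W = np.asarray(W, dtype=float)
    if not np.any(W):
        raise ValueError("untestable (all-zero) model; nothing to simulate")
    probe = gene_test(W, np.zeros(W.shape[0]), sigma.sigma)
    if not probe.testable:
        raise ValueError("model is untestable against this LD matrix")
    from .assoc import regularized_pinv

    A = W.T @ sigma.sigma @ W
    A_pinv, df = regularized_pinv(A)
    L = _chol_psd(sigma.sigma)
    q = W.shape[0]
    if config.fast_path:
        pvals = np.empty(config.n_reps)
        batch = 20_000
        for start in range(0, config.n_reps, batch):
            stop = min(start + batch, config.n_reps)
            rng = np.random.default_rng((config.seed, start))
            Zb = rng.standard_normal((stop - start, q)) @ L.T
            V = Zb @ W
            statb = np.einsum("ij,jk,ik->i", V, A_pinv, V)
            pvals[start:stop] = stats.chi2.sf(np.clip(statb, 0, None), df)
    else:
        pvals = np.empty(config.n_reps)
        for rep in range(config.n_reps):
            rng = np.random.default_rng((config.seed, rep))
            z = simulate_null_sumstats(config, sigma, rng=rng)
            v = W.T @ z
            stat = max(float(v @ A_pinv @ v), 0.0)
            pvals[rep] = stats.chi2.sf(stat, df)
    rates, lo, hi = {}, {}, {}
    for a in config.alpha_levels:
        k = int((pvals < a).sum())
        rates[a] = k / config.n_reps
        lo[a], hi[a] = _binom_ci(k, config.n_reps)
    return Type1Result(rates, lo, hi, config.n_reps,
                       pvalues=pvals if return_pvalues else None)


# ---------------------------------------------------------------------------
# synthetic gene


@dataclass
class SyntheticGene:
    genotypes: GenotypeBlock
    g_raw: np.ndarray            # n x p x t with NaN holes (pre-imputation)
    subject_ids: list[str]
    event_ids: list[str]
    tissue_ids: list[str]
    truth: dict = field(default_factory=dict)
    ld: LdMatrix | None = None


def _gaussian_to_dosage(latent: np.ndarray, mafs: np.ndarray) -> np.ndarray:
    """Threshold a correlated Gaussian at Hardy-Weinberg quantiles to get
    dosages in {0, 1, 2} that inherit the Gaussian's LD structure."""
    p0 = (1 - mafs) ** 2
    p1 = 2 * mafs * (1 - mafs)
    t1 = stats.norm.ppf(p0)
    t2 = stats.norm.ppf(p0 + p1)
    return (latent > t1).astype(float) + (latent > t2).astype(float)


def generate_synthetic_gene(
    n_train: int = 300,
    p: int = 4,
    t: int = 5,
    q: int = 30,
    n_causal: int = 2,
    h2_component: float = 0.5,
    ld_rho: float = 0.5,
    missing_rates: tuple[float, float] = (0.05, 0.05),
    n_components: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
    gene_id: str = "geneSYN",
) -> SyntheticGene:
    """Simulate one gene: LD-structured genotypes, genotype-driven latent
    splicing components shared across tissues, ratio-scale observations with
    structural and technical holes.

    ``h2_component`` is the variance fraction of each latent component
    explained by its causal SNPs; ``missing_rates`` gives (structural rate
    per event-tissue pair, technical rate per cell).
    """
    rng = np.random.default_rng(seed)
    sigma = ar1_ld(q, ld_rho)
    L = np.linalg.cholesky(sigma.sigma)
    latent = rng.standard_normal((n_train, q)) @ L.T
    mafs = rng.uniform(0.1, 0.5, size=q)
    X = _gaussian_to_dosage(latent, mafs)

    causal = rng.choice(q, size=n_causal, replace=False)
    gammas = np.zeros((q, n_components))
    s = np.zeros((n_train, n_components))
    for k in range(n_components):
        gammas[causal, k] = rng.normal(0, 1, size=n_causal)
        genetic = X @ gammas[:, k]
        gvar = genetic.var()
        if h2_component > 0 and gvar > 0:
            genetic = genetic / np.sqrt(gvar) * np.sqrt(h2_component)
            eps = rng.standard_normal(n_train) * np.sqrt(1 - h2_component)
        else:
            genetic = np.zeros(n_train)
            gammas[:, k] = 0.0
            eps = rng.standard_normal(n_train)
        s[:, k] = genetic - genetic.mean() + eps

    C = rng.normal(0, 1, size=(p, n_components))
    Tl = rng.uniform(0.2, 1.0, size=(t, n_components))
    g = np.einsum("ik,jk,mk->ijm", s, C, Tl) + rng.normal(0, noise_sd, (n_train, p, t))
    # affine map to the ratio scale, preserving structure
    gmin, gmax = g.min(), g.max()
    g = 0.05 + 0.9 * (g - gmin) / (gmax - gmin if gmax > gmin else 1.0)

    struct_rate, tech_rate = missing_rates
    structural = rng.random((p, t)) < struct_rate
    # never blank an event everywhere: keep each event in >= 2 tissues
    for j in range(p):
        while structural[j].sum() > t - 2:
            structural[j, rng.integers(0, t)] = False
    g_raw = g.copy()
    for j in range(p):
        for m in range(t):
            if structural[j, m]:
                g_raw[:, j, m] = np.nan
    tech = rng.random((n_train, p, t)) < tech_rate
    g_raw[tech] = np.nan

    subject_ids = [f"S{i:04d}" for i in range(n_train)]
    event_ids = [f"chr1:{1000 + 100 * j}:{1050 + 100 * j}:clu_1" for j in range(p)]
    tissue_ids = [f"tissue{m}" for m in range(t)]
    positions = np.linspace(4_500_000, 5_500_000, q).astype(np.int64)
    block = GenotypeBlock(
        gene_id=gene_id,
        tss=5_000_000,
        X=X,
        snp_ids=list(sigma.snp_ids),
        positions=positions,
        ref_allele=["A"] * q,
        alt_allele=["G"] * q,
        subject_ids=subject_ids,
    )
    truth = {
        "causal_snps": causal.tolist(),
        "gamma": gammas,
        "components": s,
        "event_loadings": C,
        "tissue_loadings": Tl,
        "noise_sd": noise_sd,
        "h2_component": h2_component,
        "structural_mask": structural,
        "seed": seed,
    }
    return SyntheticGene(block, g_raw, subject_ids, event_ids, tissue_ids, truth, ld=sigma)


def power_experiment(
    W: np.ndarray,
    sigma: LdMatrix,
    causal_snps: list[int],
    effect_on_trait: float,
    config: SimConfig,
) -> Type1Result:
    """Rejection rates when the trait loads on the gene's causal SNPs:
    Y1 = X1 gamma * b + N(0, 1).  effect_on_trait = 0 reduces to the null."""
    W = np.asarray(W, dtype=float)
    from .assoc import regularized_pinv

    A = W.T @ sigma.sigma @ W
    A_pinv, df = regularized_pinv(A)
    if df == 0:
        raise ValueError("untestable model")
    L = _chol_psd(sigma.sigma)
    q = W.shape[0]
    gamma = np.zeros(q)
    gamma[causal_snps] = 1.0
    pvals = np.empty(config.n_reps)
    for rep in range(config.n_reps):
        rng = np.random.default_rng((config.seed, rep))
        X1 = rng.standard_normal((config.n_gwas, q)) @ L.T
        Y1 = X1 @ gamma * effect_on_trait + rng.standard_normal(config.n_gwas)
        z = marginal_ols_z(X1, Y1)
        v = W.T @ z
        stat = max(float(v @ A_pinv @ v), 0.0)
        pvals[rep] = stats.chi2.sf(stat, df)
    rates, lo, hi = {}, {}, {}
    for a in config.alpha_levels:
        k = int((pvals < a).sum())
        rates[a] = k / config.n_reps
        lo[a], hi[a] = _binom_ci(k, config.n_reps)
    return Type1Result(rates, lo, hi, config.n_reps)
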