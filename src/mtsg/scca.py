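"""Sparse CCA between cis-genotypes and subject loadings via penalized
matrix decomposition (PMD).

Given column-standardized X (n x q genotypes) and Y (n x r subject
loadings), the first canonical pair solves

    maximize  w' X'Y u   s.t.  ||w||2 <= 1, ||u||2 <= 1,
                               ||w||1 <= c1, ||u||1 <= c2.

The L1 bounds c1 in [1, sqrt(q)] and c2 in [1, sqrt(r)] interpolate between
a single-coordinate solution and the dense leading singular pair of Z = X'Y.
Further pairs come from deflating Z by the rank-1 term d_k w_k u_k' and
refitting; after p pairs the genotype-side vectors form the q x p SNP
weight matrix W that is the gene's trained model.

Penalties are selected once on the undeflated Z by a permutation scheme:
the grid point whose real-data canonical correlation stands out most
(Fisher-z score) against row-permuted nulls wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SccaModel:
    W: np.ndarray            # q x p SNP weights
    U: np.ndarray            # r x p component weights
    d: np.ndarray            # canonical covariances, d_k = w_k' Z_k u_k >= 0
    c1: float
    c2: float
    snp_ids: list[str] = field(default_factory=list)
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    y_sd: np.ndarray | None = None
    degenerate: bool = False


def soft_threshold(a: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def _l1_project(a: np.ndarray, c: float, tol: float = 1e-8) -> np.ndarray:
    """Soft-threshold ``a`` with the smallest lambda making the unit-L2
    rescaled vector satisfy ||.||1 <= c (lambda = 0 when already feasible).

    Binary search on lambda; ties resolved toward smaller lambda (denser
    solution at the constraint boundary).
    """
    norm = np.linalg.norm(a)
    if norm == 0:
        return np.zeros_like(a)
    v = a / norm
    if np.abs(v).sum() <= c + tol:
        return v
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(200):
        lam = (lo + hi) / 2.0
        s = soft_threshold(a, lam)
        ns = np.linalg.norm(s)
        l1 = np.abs(s).sum() / ns if ns > 0 else 0.0
        if l1 > c:
            lo = lam
        else:
            hi = lam
        if hi - lo < tol * (1.0 + hi):
            break
    s = soft_threshold(a, hi)
    ns = np.linalg.norm(s)
    return s / ns if ns > 0 else np.zeros_like(a)


def pmd_rank1(
    Z: np.ndarray,
    c1: float,
    c2: float,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Rank-1 PMD of Z (q x r): returns (w, u, d, degenerate).

    Alternating soft-thresholded power iterations started from the leading
    right singular vector of Z; d = w'Zu with the pair's joint sign flipped
    so d >= 0.  An all-zero Z returns the degenerate zero solution.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z contains non-finite values")
    if np.all(Z == 0):
        return np.zeros(Z.shape[0]), np.zeros(Z.shape[1]), 0.0, True
    # deterministic init: leading right singular vector
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    u = vt[0]
    w = np.zeros(Z.shape[0])
    for _ in range(max_iter):
        w_new = _l1_project(Z @ u, c1)
        u_new = _l1_project(Z.T @ w_new, c2)
        delta = max(np.max(np.abs(w_new - w)), np.max(np.abs(u_new - u)))
        w, u = w_new, u_new
        if delta < tol:
            break
    d = float(w @ Z @ u)
    if d < 0:
        w, d = -w, -d
    if np.linalg.norm(w) == 0 or np.linalg.norm(u) == 0:
        return np.zeros(Z.shape[0]), np.zeros(Z.shape[1]), 0.0, True
    return w, u, d, False


def standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale columns; zero-variance columns are left centered at 0."""
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    return (M - mean) / safe, mean, sd


def default_penalty_grid(q: int, r: int, n_grid: int = 10) -> list[tuple[float, float]]:
    """c_i = f * sqrt(dim_i) for f in linspace(0.1, 0.7), floored at 1."""
    fs = np.linspace(0.1, 0.7, n_grid)
    return [(max(1.0, f * np.sqrt(q)), max(1.0, f * np.sqrt(r))) for f in fs]


def permute_select(
    X: np.ndarray,
    Y: np.ndarray,
    grid: list[tuple[float, float]] | None = None,
    n_perm: int = 25,
    seed: int = 0,
) -> tuple[float, float]:
    """Choose (c1, c2) by the permutation z-score of the canonical correlation.

    For each grid point, the first canonical pair is fitted on the real
    cross-product and on ``n_perm`` row-permutations of Y (shared across grid
    points); the winner maximizes (atanh(cor) - mean atanh(cor_perm)) / sd.
    Falls back to the largest grid value when every point is degenerate.
    """
    rng = np.random.default_rng(seed)
    Xs, _, _ = standardize(X)
    Ys, _, _ = standardize(Y)
    if grid is None:
        grid = default_penalty_grid(X.shape[1], Y.shape[1])
    perms = [rng.permutation(X.shape[0]) for _ in range(n_perm)]
    Z_real = Xs.T @ Ys
    Z_perms = [Xs.T @ Ys[p] for p in perms]

    def cancor(Z, Yside, c1, c2):
        w, u, d, degen = pmd_rank1(Z, c1, c2)
        if degen:
            return np.nan
        a, b = Xs @ w, Yside @ u
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    best, best_z = None, -np.inf
    for c1, c2 in grid:
        cor = cancor(Z_real, Ys, c1, c2)
        if not np.isfinite(cor):
            continue
        cors_b = np.array([cancor(Zb, Ys[p], c1, c2) for Zb, p in zip(Z_perms, perms)])
        cors_b = cors_b[np.isfinite(cors_b)]
        if len(cors_b) < 2:
            continue
        atanh = lambda x: np.arctanh(np.clip(x, -1 + 1e-12, 1 - 1e-12))
        sd = atanh(cors_b).std(ddof=1)
        if sd == 0:
            continue
        zscore = (atanh(cor) - atanh(cors_b).mean()) / sd
        if zscore > best_z:
            best_z, best = zscore, (c1, c2)
    if best is None:
        warnings.warn("all penalty grid points degenerate; using largest grid value")
        best = grid[-1]
    return best


def scca_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_factors: int,
    seed: int = 0,
    c1: float | None = None,
    c2: float | None = None,
    grid: list[tuple[float, float]] | None = None,
    n_perm: int = 25,
    snp_ids: list[str] | None = None,
    standardize_inputs: bool = True,
) -> SccaModel:
    """Fit p sparse canonical pairs by successive rank-1 PMD with deflation.

    Penalties are selected once on the undeflated cross-product and reused
    for every deflation step: Z_{k+1} = Z_k - d_k w_k u_k'.  Zero-variance
    genotype columns are excluded from the fit and reinserted as zero rows
    of W, so a monomorphic SNP never carries weight.
    """
    n, q = X.shape
    r = Y.shape[1]
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(q)]
    var_ok = X.std(axis=0) > 0
    Xf = X[:, var_ok]
    if standardize_inputs:
        Xs, x_mean, x_sd = standardize(Xf)
        Ys, y_mean, y_sd = standardize(Y)
    else:
        Xs, x_mean, x_sd = Xf, np.zeros(Xf.shape[1]), np.ones(Xf.shape[1])
        Ys, y_mean, y_sd = Y, np.zeros(r), np.ones(r)
    if c1 is None or c2 is None:
        c1, c2 = permute_select(Xf, Y, grid=grid, n_perm=n_perm, seed=seed)
    qf = Xs.shape[1]
    attainable = min(qf, r)
    if n_factors > attainable:
        warnings.warn(
            f"requested {n_factors} factors but rank is at most {attainable}; "
            "extra factors zero-filled"
        )
    Z = Xs.T @ Ys
    W_fit = np.zeros((qf, n_factors))
    U = np.zeros((r, n_factors))
    d = np.zeros(n_factors)
    degenerate = True
    for k in range(min(n_factors, attainable)):
        w_k, u_k, d_k, degen = pmd_rank1(Z, c1, c2, seed=seed)
        if degen:
            break
        W_fit[:, k], U[:, k], d[k] = w_k, u_k, d_k
        degenerate = False
        Z = Z - d_k * np.outer(w_k, u_k)
    W = np.zeros((q, n_factors))
    W[var_ok, :] = W_fit
    full_mean = np.zeros(q)
    full_sd = np.ones(q)
    full_mean[var_ok], full_sd[var_ok] = x_mean, x_sd
    return SccaModel(
        W=W, U=U, d=d, c1=float(c1), c2=float(c2), snp_ids=list(snp_ids),
        x_mean=full_mean, x_sd=full_sd, y_mean=y_mean, y_sd=y_sd,
        degenerate=degenerate,
    )
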