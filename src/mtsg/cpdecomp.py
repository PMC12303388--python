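"""Canonical polyadic (CP) decomposition of the per-gene splicing tensor.

The n x p x t tensor is approximated by a sum of r rank-1 outer products

    G  ~  sum_k  weights[k] * Y[:, k] o C[:, k] o Tmat[:, k]

fit by alternating least squares (ALS).  The rank is tied to the number of
splicing events, r = p (optionally 0.5x or 1.5x for sensitivity analysis),
and identifiability is screened with the Kruskal sufficient condition
min(2p + t, 3p) >= 2r + 2 before trusting component interpretation.

Factor columns carry unit L2 norm with scales absorbed into ``weights``;
the sign of each component is fixed by making the first nonzero entry of
its tissue-loading column nonnegative (compensated in the subject column),
so repeated runs from the same seed are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FactorModel:
    Y: np.ndarray      # n x r subject loadings
    C: np.ndarray      # p x r splicing-event loadings
    Tmat: np.ndarray   # t x r tissue loadings
    weights: np.ndarray
    rank: int
    fit: float         # 1 - ||G - Ghat||_F / ||G||_F
    n_iter: int
    converged: bool
    seed: int
    fit_trace: np.ndarray | None = None


def choose_rank(p: int, multiplier: float = 1.0) -> int:
    """r = max(1, round(multiplier * p)), round-half-up."""
    if p < 2:
        raise ValueError("gene with fewer than 2 events should be untestable upstream")
    return max(1, int(np.floor(multiplier * p + 0.5)))


def kruskal_check(p: int, t: int, r: int) -> tuple[bool, int]:
    """Sufficient uniqueness screen for the CP model at the given sizes.

    With n > p subjects the subject factor has full column rank, so the
    Kruskal-rank sum is bounded below by min(2p + t, 3p); uniqueness is
    guaranteed when that bound reaches 2r + 2.
    """
    bound = min(2 * p + t, 3 * p)
    margin = bound - (2 * r + 2)
    return margin >= 0, margin


def _unfold(g: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(g, mode, 0).reshape(g.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product: (I*J) x r from I x r and J x r."""
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def reconstruct(model: FactorModel) -> np.ndarray:
    """Ghat = sum_k weights[k] * Y[:,k] o C[:,k] o Tmat[:,k]."""
    return np.einsum(
        "k,ik,jk,mk->ijm", model.weights, model.Y, model.C, model.Tmat, optimize=True
    )


def _normalize_and_sign(Y, C, Tmat, weights):
    """Unit-norm columns, scales into weights, tissue-column sign convention."""
    for mat in (Y, C, Tmat):
        norms = np.linalg.norm(mat, axis=0)
        norms = np.where(norms == 0, 1.0, norms)
        weights = weights * norms
        mat /= norms
    for k in range(Tmat.shape[1]):
        col = Tmat[:, k]
        nz = np.nonzero(col)[0]
        if nz.size and col[nz[0]] < 0:
            Tmat[:, k] = -col
            Y[:, k] = -Y[:, k]
    return Y, C, Tmat, weights


def cp_als(
    tensor: np.ndarray,
    r: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 1,
) -> FactorModel:
    """Rank-r CP decomposition by ALS with random normal initialization.

    Each mode update solves a linear least-squares problem through the
    pseudo-inverse of the Hadamard product of the other factors' Gram
    matrices, so rank-deficient iterations never crash.  The fit
    1 - ||G - Ghat||_F/||G||_F is non-decreasing across iterations (up to
    floating-point slack); convergence is declared when it changes by less
    than ``tol``.  Multiple restarts keep the best-fit solution.
    """
    if np.any(~np.isfinite(tensor)):
        raise ValueError("tensor contains NaN or infinite values")
    if r < 1:
        raise ValueError("rank must be >= 1")
    best: FactorModel | None = None
    for restart in range(n_restarts):
        model = _cp_als_single(tensor, r, seed + restart, tol, max_iter)
        if best is None or model.fit > best.fit:
            best = model
    best.seed = seed
    return best


def _cp_als_single(g, r, seed, tol, max_iter):
    rng = np.random.default_rng(seed)
    shape = g.shape
    norm_g = np.linalg.norm(g)
    factors = [rng.standard_normal((s, r)) for s in shape]
    unfolds = [_unfold(g, m) for m in range(3)]
    weights = np.ones(r)
    fit_prev = -np.inf
    trace = []
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            # khatri-rao ordering must match the unfold's reshape order
            kr = _khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            factors[mode] = unfolds[mode] @ kr @ np.linalg.pinv(gram)
        # fit from the last-updated mode
        Y, C, Tmat = factors
        ghat = np.einsum("ik,jk,mk->ijm", Y, C, Tmat, optimize=True)
        err = np.linalg.norm(g - ghat)
        fit = 1.0 - err / norm_g if norm_g > 0 else 1.0
        trace.append(fit)
        if abs(fit - fit_prev) < tol:
            converged = True
            break
        fit_prev = fit
    Y, C, Tmat = (f.copy() for f in factors)
    Y, C, Tmat, weights = _normalize_and_sign(Y, C, Tmat, np.ones(r))
    return FactorModel(
        Y=Y, C=C, Tmat=Tmat, weights=weights, rank=r,
        fit=float(trace[-1]), n_iter=n_iter, converged=converged, seed=seed,
        fit_trace=np.asarray(trace),
    )


def export_factors_tsv(model: FactorModel, prefix, subject_ids, event_ids, tissue_ids):
    """Write Y, C, Tmat as labeled TSVs (one file per factor matrix)."""
    import pandas as pd

    cols = [f"component_{k+1}" for k in range(model.rank)]
    pd.DataFrame(model.Y, index=subject_ids, columns=cols).to_csv(
        f"{prefix}.subjects.tsv", sep="\t")
    pd.DataFrame(model.C, index=event_ids, columns=cols).to_csv(
        f"{prefix}.events.tsv", sep="\t")
    pd.DataFrame(model.Tmat, index=tissue_ids, columns=cols).to_csv(
        f"{prefix}.tissues.tsv", sep="\t")
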