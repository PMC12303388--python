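"""Gene-trait association from GWAS summary statistics.

With a trained q x p SNP weight matrix W, GWAS z-scores z and an LD matrix
Sigma, the gene-level statistic is

    T = z' W (W' Sigma W)^- W' z

where the pseudo-inverse discards eigenvalues below 1/30 of the largest —
canonical pairs within a gene are correlated, so W' Sigma W routinely
approaches singularity.  Under the null, W'z ~ MVN(0, W' Sigma W) and T is
chi-square with degrees of freedom equal to the retained eigenvalue count.

Harmonization matches model and GWAS SNPs by id, flips z where the GWAS
effect allele is the model's reference allele, and drops strand-ambiguous
palindromic (A/T, C/G) variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .formats_io import GeneModelRecord, GwasStats, LdMatrix

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class HarmonizeReport:
    n_matched: int = 0
    n_flipped: int = 0
    n_palindromic_dropped: int = 0
    n_absent_from_gwas: int = 0
    n_allele_mismatch_dropped: int = 0


@dataclass
class AssocResult:
    gene_id: str
    stat: float
    df: int
    pvalue: float  # NaN when untestable
    n_snps_used: int
    n_snps_dropped: int
    testable: bool
    significant_bonferroni: bool = False
    chrom: str = "NA"
    tss: int = 0
    n_events: int = 0


def harmonize(
    model: GeneModelRecord, gwas: GwasStats, ld: LdMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray, HarmonizeReport]:
    """Align W rows, z entries and Sigma to the shared, strand-safe SNP set.

    Returns (W_aligned, z_aligned, sigma_aligned, report); zero overlap
    yields empty arrays (the caller marks the gene untestable).
    """
    report = HarmonizeReport()
    gidx = {s: i for i, s in enumerate(gwas.snp_id)}
    keep_rows: list[int] = []
    z_vals: list[float] = []
    for row, snp in enumerate(model.snp_ids):
        ref = model.ref_allele[row].upper()
        alt = model.alt_allele[row].upper()
        if (ref, alt) in PALINDROMIC:
            report.n_palindromic_dropped += 1
            continue
        i = gidx.get(snp)
        if i is None:
            report.n_absent_from_gwas += 1
            continue
        ea, oa = gwas.effect_allele[i], gwas.other_allele[i]
        if (ea, oa) == (alt, ref):
            z_vals.append(gwas.z[i])
        elif (ea, oa) == (ref, alt):
            z_vals.append(-gwas.z[i])
            report.n_flipped += 1
        else:
            report.n_allele_mismatch_dropped += 1
            continue
        keep_rows.append(row)
    report.n_matched = len(keep_rows)
    ld_sub = ld.subset([model.snp_ids[r] for r in keep_rows]) if keep_rows else None
    W = model.W[keep_rows, :] if keep_rows else np.empty((0, model.W.shape[1]))
    sigma = ld_sub.sigma if ld_sub is not None else np.empty((0, 0))
    return W, np.asarray(z_vals), sigma, report


def regularized_pinv(M: np.ndarray, ratio: float = 1.0 / 30.0) -> tuple[np.ndarray, int]:
    """Eigenvalue-truncated pseudo-inverse of a symmetric PSD matrix.

    Keeps eigenvalues >= ratio * lambda_max; df is the retained count.
    A non-positive spectrum gives (0, df=0).
    """
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        return M.copy(), 0
    if not np.allclose(M, M.T, atol=1e-6):
        warnings.warn("matrix asymmetric beyond 1e-6; symmetrizing")
    M = (M + M.T) / 2.0
    lam, Q = np.linalg.eigh(M)
    lam_max = lam.max()
    if lam_max <= 0:
        return np.zeros_like(M), 0
    keep = lam >= ratio * lam_max
    df = int(keep.sum())
    Qk = Q[:, keep]
    pinv = Qk @ np.diag(1.0 / lam[keep]) @ Qk.T
    return pinv, df


def gene_test(
    W: np.ndarray,
    z: np.ndarray,
    sigma: np.ndarray,
    gene_id: str = "gene",
    eig_ratio: float = 1.0 / 30.0,
    ld_shrink: float = 0.0,
) -> AssocResult:
    """T = z'W (W' Sigma W)^- W'z against chi-square(df = retained rank).

    ``ld_shrink`` optionally blends Sigma toward identity for ill-conditioned
    reference panels; off by default.
    """
    W = np.asarray(W, dtype=float)
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if W.shape[0] != z.shape[0] or sigma.shape != (W.shape[0], W.shape[0]):
        raise ValueError(
            f"dimension mismatch: W {W.shape}, z {z.shape}, sigma {sigma.shape}"
        )
    if W.size == 0 or not np.any(W):
        return AssocResult(gene_id, np.nan, 0, np.nan, W.shape[0], 0, testable=False)
    if ld_shrink > 0:
        sigma = (1 - ld_shrink) * sigma + ld_shrink * np.eye(sigma.shape[0])
    v = W.T @ z
    A = W.T @ sigma @ W
    A_pinv, df = regularized_pinv(A, eig_ratio)
    if df == 0:
        return AssocResult(gene_id, np.nan, 0, np.nan, W.shape[0], 0, testable=False)
    stat = float(v @ A_pinv @ v)
    if stat < 0:
        if stat < -1e-8:
            raise ValueError(f"negative statistic {stat} beyond float tolerance")
        stat = 0.0
    pvalue = float(stats.chi2.sf(stat, df))
    return AssocResult(gene_id, stat, df, pvalue, W.shape[0], 0, testable=True)


def bonferroni(results: list[AssocResult], alpha: float = 0.05) -> list[AssocResult]:
    """Flag genome-wide significant genes; denominator counts testable genes only."""
    testable = [r for r in results if r.testable]
    if not testable:
        warnings.warn("no testable genes; all significance calls are False")
        for r in results:
            r.significant_bonferroni = False
        return results
    threshold = alpha / len(testable)
    for r in results:
        r.significant_bonferroni = bool(r.testable and r.pvalue < threshold)
    return results
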