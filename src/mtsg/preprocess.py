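"""Cohort/event filtering, dual-mechanism imputation and tensor assembly.

A gene's raw data is a subjects x events x tissues array with NaN holes.
Two missingness mechanisms are treated separately:

* **structural** — an event is biologically absent from a tissue (no subject
  with data in that tissue observes it).  Filled with the minimum observed
  ratio within the gene's splicing matrix, a conservative stand-in for
  biological zero.
* **technical** — a subject simply lacks coverage for that tissue/event.
  Filled by EM for a multivariate normal on the subject x (event, tissue)
  unfolding, fitted on a seeded bootstrap resample of subjects and applied
  as a single conditional-mean imputation.

Cohort filters (tissues with too few samples, subjects covering too few
tissues) iterate to a fixpoint because each drop changes the other side's
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .formats_io import SplicingTable


class MissingKind(str, Enum):
    OBSERVED = "observed"
    STRUCTURAL = "structural"
    TECHNICAL_MIXED = "technical-mixed"


class EmptyCohortError(ValueError):
    """No tissue/subject combination survives the cohort filters."""


@dataclass
class CohortSummary:
    """Subject x tissue availability (True where the subject has any data)."""

    presence: pd.DataFrame  # bool, index=subjects, columns=tissues

    @classmethod
    def from_tables(cls, tables: dict[str, list[SplicingTable]]) -> "CohortSummary":
        subjects = sorted({s for tabs in tables.values() for t in tabs for s in t.subject_ids})
        tissues = list(tables.keys())
        presence = pd.DataFrame(False, index=subjects, columns=tissues)
        for tissue, tabs in tables.items():
            for t in tabs:
                observed = ~np.all(np.isnan(t.ratios), axis=0)
                for subj, obs in zip(t.subject_ids, observed):
                    if obs:
                        presence.loc[subj, tissue] = True
        return cls(presence)

    def samples_per_tissue(self) -> pd.Series:
        return self.presence.sum(axis=0)

    def tissues_per_subject(self) -> pd.Series:
        return self.presence.sum(axis=1)


def filter_cohort(
    summary: CohortSummary,
    min_samples_per_tissue: int = 200,
    min_tissues_per_subject: int = 13,
) -> tuple[list[str], list[str]]:
    """Drop thin tissues and sparsely covered subjects, iterated to a fixpoint.

    A tissue is kept when at least ``min_samples_per_tissue`` of the kept
    subjects have data in it; a subject is kept when they have data in at
    least ``min_tissues_per_subject`` kept tissues.
    """
    presence = summary.presence
    tissues = list(presence.columns)
    subjects = list(presence.index)
    while True:
        sub = presence.loc[subjects, tissues]
        keep_t = [t for t in tissues if sub[t].sum() >= min_samples_per_tissue]
        sub = presence.loc[subjects, keep_t]
        keep_s = [s for s in subjects if sub.loc[s].sum() >= min_tissues_per_subject]
        if keep_t == tissues and keep_s == subjects:
            break
        tissues, subjects = keep_t, keep_s
        if not tissues or not subjects:
            raise EmptyCohortError("no cohort survives the tissue/subject filters")
    if not tissues or not subjects:
        raise EmptyCohortError("no cohort survives the tissue/subject filters")
    return tissues, subjects


def stack_tables(
    tables: list[SplicingTable], subjects: list[str] | None = None
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Stack per-tissue tables for one gene into an n x p x t array with NaN.

    The event set is the union across tissues; events absent from a tissue's
    table appear as all-NaN slabs there (structural candidates).
    """
    if subjects is None:
        subjects = sorted({s for t in tables for s in t.subject_ids})
    events = sorted({e for t in tables for e in t.event_ids})
    tissues = [t.tissue for t in tables]
    g = np.full((len(subjects), len(events), len(tissues)), np.nan)
    e_idx = {e: j for j, e in enumerate(events)}
    s_idx = {s: i for i, s in enumerate(subjects)}
    for k, t in enumerate(tables):
        cols = [s_idx[s] for s in t.subject_ids if s in s_idx]
        keep = [i for i, s in enumerate(t.subject_ids) if s in s_idx]
        for row, e in enumerate(t.event_ids):
            g[cols, e_idx[e], k] = t.ratios[row, keep]
    return g, subjects, events, tissues


def classify_missing(g_raw: np.ndarray) -> np.ndarray:
    """Label each (event, tissue) pair observed / structural / technical-mixed.

    A pair is structural iff no subject with any data in that tissue observes
    the event; remaining subject-level gaps are technical.
    """
    n, p, t = g_raw.shape
    kinds = np.empty((p, t), dtype=object)
    for k in range(t):
        active = ~np.all(np.isnan(g_raw[:, :, k]), axis=1)  # subjects with data in tissue k
        for j in range(p):
            col = g_raw[:, j, k]
            if not active.any() or np.all(np.isnan(col[active])):
                kinds[j, k] = MissingKind.STRUCTURAL
            elif np.any(np.isnan(col[active])) or np.any(np.isnan(col[~active])):
                kinds[j, k] = MissingKind.TECHNICAL_MIXED
            else:
                kinds[j, k] = MissingKind.OBSERVED
    return kinds


def filter_events(
    event_ids: list[str],
    missing_kind: np.ndarray,
    max_missing_tissues: int = 20,
    min_events_per_gene: int = 2,
) -> tuple[list[int], bool]:
    """Drop events structurally absent from too many tissues; flag testability.

    Returns (kept event indices, testable).  A gene left with fewer than
    ``min_events_per_gene`` events is untestable — a valid outcome, not an
    error.
    """
    kept = []
    for j in range(len(event_ids)):
        n_structural = sum(missing_kind[j, k] == MissingKind.STRUCTURAL
                           for k in range(missing_kind.shape[1]))
        if n_structural <= max_missing_tissues:
            kept.append(j)
    return kept, len(kept) >= min_events_per_gene


# ---------------------------------------------------------------------------
# EM imputation for a multivariate normal


def _em_mvn(data: np.ndarray, max_iter: int = 100, tol: float = 1e-5,
            ridge: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Fit (mu, Sigma) of an MVN to data with NaN entries by EM.

    Sufficient statistics include the conditional covariance of the missing
    block, so the estimate is a genuine EM fixed point, not iterative
    regression.  A small ridge keeps Sigma invertible when columns are
    nearly collinear or n is small.
    """
    n, m = data.shape
    if np.any(np.all(np.isnan(data), axis=0)):
        raise ValueError("a column is entirely missing; cannot fit EM")
    mu = np.nanmean(data, axis=0)
    filled = np.where(np.isnan(data), mu, data)
    sigma = np.cov(filled, rowvar=False, bias=True) + ridge * np.eye(m)
    miss = np.isnan(data)
    # group rows by missingness pattern so each pattern solves one system
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)
    for _ in range(max_iter):
        X = np.where(miss, 0.0, data)
        S_extra = np.zeros((m, m))
        for key, rows in patterns.items():
            mpat = np.frombuffer(key, dtype=bool)
            if not mpat.any():
                continue
            o = ~mpat
            rows = np.asarray(rows)
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(mpat, o)]
            coef = np.linalg.solve(Soo, Smo.T).T  # Smo @ Soo^-1
            cond_mean = mu[mpat] + (data[np.ix_(rows, o)] - mu[o]) @ coef.T
            X[np.ix_(rows, mpat)] = cond_mean
            cond_cov = sigma[np.ix_(mpat, mpat)] - coef @ Smo.T
            S_extra[np.ix_(mpat, mpat)] += len(rows) * cond_cov
        mu_new = X.mean(axis=0)
        Xc = X - mu_new
        sigma_new = (Xc.T @ Xc + S_extra) / n + ridge * np.eye(m)
        delta = max(np.max(np.abs(mu_new - mu)), np.max(np.abs(sigma_new - sigma)))
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    return mu, sigma


def em_impute(data: np.ndarray, seed: int, n_boot_tries: int = 5) -> np.ndarray:
    """Single imputation: EM on a seeded bootstrap resample, then conditional
    means on the original matrix.  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    n, m = data.shape
    fit_data = data
    for _ in range(n_boot_tries):
        idx = rng.integers(0, n, size=n)
        boot = data[idx]
        if not np.any(np.all(np.isnan(boot), axis=0)):
            fit_data = boot
            break
    mu, sigma = _em_mvn(fit_data)
    out = data.copy()
    miss = np.isnan(data)
    for i in np.where(miss.any(axis=1))[0]:
        mpat = miss[i]
        o = ~mpat
        Soo = sigma[np.ix_(o, o)]
        Smo = sigma[np.ix_(mpat, o)]
        coef = np.linalg.solve(Soo, Smo.T).T
        out[i, mpat] = mu[mpat] + coef @ (data[i, o] - mu[o])
    return out


@dataclass
class SplicingTensor:
    """The per-gene third-order array: subjects x events x tissues.

    ``mask`` is True where the value was directly observed; ``missing_kind``
    records, per (event, tissue), whether the pair was fully observed,
    structurally absent, or had technical subject-level gaps.
    """

    g: np.ndarray
    subject_ids: list[str]
    event_ids: list[str]
    tissue_ids: list[str]
    mask: np.ndarray
    missing_kind: np.ndarray

    def __post_init__(self) -> None:
        n, p, t = self.g.shape
        if (len(self.subject_ids), len(self.event_ids), len(self.tissue_ids)) != (n, p, t):
            raise ValueError("axis label lengths do not match tensor shape")
        if np.any(np.isnan(self.g)):
            raise ValueError("tensor still contains missing values after imputation")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.g.shape


def impute_tensor(
    g_raw: np.ndarray,
    missing_kind: np.ndarray,
    subject_ids: list[str],
    event_ids: list[str],
    tissue_ids: list[str],
    seed: int = 0,
) -> SplicingTensor:
    """Fill structural holes with the gene-matrix minimum, technical holes by
    EM-MVN conditional means (clipped to [0, 1]); observed cells untouched."""
    n, p, t = g_raw.shape
    g = g_raw.copy()
    observed_mask = ~np.isnan(g_raw)
    if observed_mask.sum() == 0:
        raise ValueError("gene has no observed splicing values")
    gene_min = np.nanmin(g_raw)
    for j in range(p):
        for k in range(t):
            if missing_kind[j, k] == MissingKind.STRUCTURAL:
                g[:, j, k] = np.where(np.isnan(g[:, j, k]), gene_min, g[:, j, k])
    if np.any(np.isnan(g)):
        flat = g.reshape(n, p * t)
        if np.any(np.all(np.isnan(flat), axis=0)):
            raise ValueError(
                "an (event, tissue) column is entirely missing after structural fill; "
                "it should have been filtered out"
            )
        flat = np.clip(em_impute(flat, seed=seed), 0.0, 1.0)
        g = flat.reshape(n, p, t)
    return SplicingTensor(
        g=g,
        subject_ids=list(subject_ids),
        event_ids=list(event_ids),
        tissue_ids=list(tissue_ids),
        mask=observed_mask,
        missing_kind=missing_kind,
    )


def impute_benchmark(complete_matrix: np.ndarray, mask_fraction: float = 0.10,
                     seed: int = 0) -> float:
    """Mask cells uniformly at random, impute by EM, return RMSE on masked cells.

    Mirrors the masking diagnostic used to compare imputation strategies on
    fully observed splicing matrices.
    """
    if not 0.0 < mask_fraction < 1.0:
        raise ValueError("mask_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    holes = rng.random(complete_matrix.shape) < mask_fraction
    # keep at least one observation per column so EM stays identifiable
    for j in np.where(np.all(holes, axis=0))[0]:
        holes[rng.integers(0, complete_matrix.shape[0]), j] = False
    data = np.where(holes, np.nan, complete_matrix)
    imputed = em_impute(data, seed=seed + 1)
    if not holes.any():
        return 0.0
    return float(np.sqrt(np.mean((imputed[holes] - complete_matrix[holes]) ** 2)))


def mean_impute(data: np.ndarray) -> np.ndarray:
    """Column-mean imputation baseline for the benchmark comparison."""
    mu = np.nanmean(data, axis=0)
    return np.where(np.isnan(data), mu, data)


def assemble_tensor(tensor: SplicingTensor) -> SplicingTensor:
    """Canonicalize axis order: subjects and events lexicographic, tissues as
    given.  Idempotent; makes downstream results invariant to input order."""
    s_order = np.argsort(np.asarray(tensor.subject_ids, dtype=object))
    e_order = np.argsort(np.asarray(tensor.event_ids, dtype=object))
    return SplicingTensor(
        g=tensor.g[np.ix_(s_order, e_order, range(len(tensor.tissue_ids)))],
        subject_ids=[tensor.subject_ids[i] for i in s_order],
        event_ids=[tensor.event_ids[j] for j in e_order],
        tissue_ids=list(tensor.tissue_ids),
        mask=tensor.mask[np.ix_(s_order, e_order, range(len(tensor.tissue_ids)))],
        missing_kind=tensor.missing_kind[np.ix_(e_order, range(len(tensor.tissue_ids)))],
    )


def prepare_gene_tensor(
    tables: list[SplicingTable],
    subjects: list[str] | None = None,
    max_missing_tissues: int = 20,
    min_events_per_gene: int = 2,
    seed: int = 0,
) -> SplicingTensor | None:
    """Full per-gene path: stack -> classify -> filter events -> impute -> sort.

    Returns None when the gene is untestable (fewer than
    ``min_events_per_gene`` events survive the structural-absence filter).
    """
    g_raw, subj, events, tissues = stack_tables(tables, subjects)
    kinds = classify_missing(g_raw)
    kept, testable = filter_events(events, kinds, max_missing_tissues, min_events_per_gene)
    if not testable:
        return None
    g_raw = g_raw[:, kept, :]
    kinds = kinds[kept, :]
    events = [events[j] for j in kept]
    tensor = impute_tensor(g_raw, kinds, subj, events, tissues, seed=seed)
    return assemble_tensor(tensor)
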