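"""Readers and writers for the external formats the pipeline consumes.

Splicing quantifications arrive as LeafCutter-style intron-excision-ratio
tables (one TSV per tissue), genotypes as VCF or a plain subject x SNP dosage
matrix, GWAS results as a summary-statistics TSV, and LD either as a square
TSV or computed on the fly from a reference genotype block.  Trained per-gene
models (the q x p SNP weight matrix W plus metadata) are persisted in a
single HDF5 container with one group per gene.

Coordinates are 1-based inclusive throughout (VCF convention); the cis
window is the closed interval [tss - window, tss + window].
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

MISSING_TOKENS = {"NA", "NaN", "nan", ""}

STORE_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class SplicingTable:
    """Intron-excision ratios for one tissue.

    ``ratios`` is an events x subjects array with NaN marking missing
    observations; every non-missing entry lies in [0, 1].
    """

    tissue: str
    event_ids: list[str]
    chroms: list[str]
    starts: np.ndarray  # 1-based inclusive
    ends: np.ndarray
    clusters: list[str]
    subject_ids: list[str]
    ratios: np.ndarray  # events x subjects, NaN = missing

    def __post_init__(self) -> None:
        if len(set(self.event_ids)) != len(self.event_ids):
            raise FormatError(f"duplicate event_id in tissue {self.tissue!r}")
        if np.any(self.starts > self.ends):
            raise FormatError("event with start > end")
        vals = self.ratios[~np.isnan(self.ratios)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise FormatError("splicing ratio outside [0, 1]")


@dataclass
class GenotypeBlock:
    """cis-window genotype dosages for one gene (subjects x SNPs, in [0, 2])."""

    gene_id: str
    tss: int
    X: np.ndarray
    snp_ids: list[str]
    positions: np.ndarray
    ref_allele: list[str]
    alt_allele: list[str]
    subject_ids: list[str]
    monomorphic: np.ndarray = field(default=None)  # bool per SNP
    n_multiallelic_skipped: int = 0

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length does not match dosage columns")
        if self.monomorphic is None:
            with np.errstate(invalid="ignore"):
                sd = np.nanstd(self.X, axis=0)
            self.monomorphic = sd == 0

    @property
    def q(self) -> int:
        return len(self.snp_ids)


@dataclass
class GwasStats:
    """Per-SNP GWAS association z-scores, one record per snp_id."""

    snp_id: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    z: np.ndarray
    n_dropped: int = 0  # records dropped for se <= 0

    def __post_init__(self) -> None:
        if len(set(self.snp_id)) != len(self.snp_id):
            raise FormatError("duplicate snp_id in GWAS table")
        if not np.all(np.isfinite(self.z)):
            raise FormatError("non-finite z-score in GWAS table")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "z": self.z,
            }
        ).set_index("snp_id")


@dataclass
class LdMatrix:
    """SNP x SNP correlation matrix with unit diagonal."""

    sigma: np.ndarray
    snp_ids: list[str]

    def __post_init__(self) -> None:
        s = self.sigma
        if s.shape[0] != s.shape[1] or s.shape[0] != len(self.snp_ids):
            raise ValueError("LD matrix shape mismatch")
        if not np.allclose(s, s.T, atol=1e-6):
            raise ValueError("LD matrix asymmetric beyond 1e-6")
        if not np.allclose(np.diag(s), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal not 1 within 1e-6")

    def subset(self, snp_ids: list[str]) -> "LdMatrix":
        idx = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in idx]
        if missing:
            raise KeyError(f"SNPs absent from LD matrix: {missing}")
        sel = [idx[s] for s in snp_ids]
        return LdMatrix(self.sigma[np.ix_(sel, sel)].copy(), list(snp_ids))


def parse_event_id(event_id: str) -> tuple[str, int, int, str]:
    """Split ``chr1:100:200:clu_7`` into (chrom, start, end, cluster)."""
    parts = event_id.split(":")
    if len(parts) != 4:
        raise FormatError(f"malformed event_id {event_id!r}; expected chrom:start:end:cluster")
    chrom, start, end, cluster = parts
    try:
        return chrom, int(start), int(end), cluster
    except ValueError as exc:
        raise FormatError(f"non-integer coordinate in event_id {event_id!r}") from exc


def read_splicing_table(path: str | Path, tissue_label: str) -> SplicingTable:
    """Read a LeafCutter-ratio TSV: chrom, start, end, event_id, then subjects."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "start", "end", "event_id"]
    if list(df.columns[:4]) != required:
        raise FormatError(
            f"{path}: first four columns must be {required}, got {list(df.columns[:4])}"
        )
    subject_ids = list(df.columns[4:])
    n_events = len(df)
    ratios = np.empty((n_events, len(subject_ids)))
    for j, subj in enumerate(subject_ids):
        col = df[subj]
        for i, tok in enumerate(col):
            tok = tok.strip()
            if tok in MISSING_TOKENS:
                ratios[i, j] = np.nan
            else:
                try:
                    ratios[i, j] = float(tok)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-numeric ratio {tok!r} at event row {i}, subject {subj!r}"
                    ) from exc
    event_ids = list(df["event_id"])
    parsed = [parse_event_id(e) for e in event_ids]
    return SplicingTable(
        tissue=tissue_label,
        event_ids=event_ids,
        chroms=[p[0] for p in parsed],
        starts=np.array([p[1] for p in parsed], dtype=np.int64),
        ends=np.array([p[2] for p in parsed], dtype=np.int64),
        clusters=[p[3] for p in parsed],
        subject_ids=subject_ids,
        ratios=ratios,
    )


def write_splicing_table(table: SplicingTable, path: str | Path) -> None:
    cols = {
        "chrom": table.chroms,
        "start": table.starts,
        "end": table.ends,
        "event_id": table.event_ids,
    }
    for j, subj in enumerate(table.subject_ids):
        cols[subj] = [("NA" if math.isnan(v) else repr(float(v))) for v in table.ratios[:, j]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes


def _read_vcf_block(
    path: str | Path, chrom: str, lo: int, hi: int
) -> tuple[np.ndarray, list, list, list, list, list, int]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    dosages, snp_ids, positions, refs, alts = [], [], [], [], []
    n_multi = 0
    for rec in vcf:
        if rec.CHROM != chrom or not (lo <= rec.POS <= hi):
            continue
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if "DS" in dict(rec.FORMAT or {}):
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
        else:
            # gt_types: 0=hom ref, 1=het, 2=hom alt, 3=missing (gts012)
            gts = np.asarray(rec.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(float)
        dosages.append(ds)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    X = np.array(dosages, dtype=float).T if dosages else np.empty((len(subjects), 0))
    return X, snp_ids, positions, refs, alts, subjects, n_multi


def _read_dosage_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plain dialect: snp_id, pos, ref, alt, then one column per subject."""
    df = pd.read_csv(path, sep="\t")
    required = ["snp_id", "pos", "ref", "alt"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"{path}: dosage TSV must start with columns {required}")
    meta = df[required]
    dos = df[df.columns[4:]]
    return meta, dos


def read_genotypes(
    path: str | Path,
    gene_id: str,
    chrom: str,
    tss: int,
    window_bp: int = 1_000_000,
) -> GenotypeBlock:
    """Load cis-window dosages for ``gene_id``: SNPs within tss +/- window_bp.

    Accepts a VCF (``.vcf``/``.vcf.gz``; dosage from DS if present, else GT)
    or a plain dosage TSV.  Multi-allelic VCF records are skipped and
    counted.  An empty window yields a zero-SNP block — the gene is marked
    untestable downstream, not an exception here.
    """
    lo, hi = tss - window_bp, tss + window_bp
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        X, snp_ids, positions, refs, alts, subjects, n_multi = _read_vcf_block(
            path, chrom, lo, hi
        )
    else:
        meta, dos = _read_dosage_tsv(path)
        keep = ((meta["pos"] >= lo) & (meta["pos"] <= hi)).to_numpy()
        meta = meta[keep]
        X = dos[keep].to_numpy(dtype=float).T
        snp_ids = list(meta["snp_id"])
        positions = list(meta["pos"])
        refs = list(meta["ref"])
        alts = list(meta["alt"])
        subjects = list(dos.columns)
        n_multi = 0
    return GenotypeBlock(
        gene_id=gene_id,
        tss=tss,
        X=X,
        snp_ids=snp_ids,
        positions=np.asarray(positions, dtype=np.int64),
        ref_allele=refs,
        alt_allele=alts,
        subject_ids=subjects,
        n_multiallelic_skipped=n_multi,
    )


def write_dosage_tsv(block: GenotypeBlock, path: str | Path) -> None:
    cols = {
        "snp_id": block.snp_ids,
        "pos": block.positions,
        "ref": block.ref_allele,
        "alt": block.alt_allele,
    }
    for i, subj in enumerate(block.subject_ids):
        cols[subj] = block.X[i, :]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def read_gwas(path: str | Path) -> GwasStats:
    """Read summary statistics; derive z = beta/se when no z column exists.

    Records with se <= 0 are dropped and counted in ``n_dropped``.
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"snp_id", "effect_allele", "other_allele"}
    if not needed.issubset(df.columns):
        raise FormatError(
            f"{path}: missing required columns {sorted(needed - set(df.columns))}; "
            f"expected snp_id, effect_allele, other_allele and z or (beta, se)"
        )
    n_dropped = 0
    if "z" in df.columns:
        z = df["z"].to_numpy(dtype=float)
    elif {"beta", "se"}.issubset(df.columns):
        ok = df["se"].to_numpy(dtype=float) > 0
        n_dropped = int((~ok).sum())
        df = df[ok]
        z = df["beta"].to_numpy(dtype=float) / df["se"].to_numpy(dtype=float)
    else:
        raise FormatError(f"{path}: need a z column or both beta and se columns")
    return GwasStats(
        snp_id=list(df["snp_id"]),
        effect_allele=[str(a).upper() for a in df["effect_allele"]],
        other_allele=[str(a).upper() for a in df["other_allele"]],
        z=z,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# LD


def compute_ld(X: np.ndarray, snp_ids: list[str]) -> LdMatrix:
    """Pearson correlation of dosage columns, symmetrized, unit diagonal.

    Zero-variance columns get zero off-diagonal correlation (their LD with
    anything is undefined; zero keeps the matrix PSD after the diagonal fix).
    """
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    Z = Xc / safe
    sigma = (Z.T @ Z) / X.shape[0]
    sigma = (sigma + sigma.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    return LdMatrix(sigma, list(snp_ids))


def load_or_compute_ld(source, snp_ids: list[str]) -> LdMatrix:
    """LD from a square TSV (header = snp_ids) or a reference GenotypeBlock."""
    if isinstance(source, GenotypeBlock):
        idx = {s: i for i, s in enumerate(source.snp_ids)}
        missing = [s for s in snp_ids if s not in idx]
        if missing:
            raise KeyError(f"SNPs absent from reference genotypes: {missing}")
        sel = [idx[s] for s in snp_ids]
        return compute_ld(source.X[:, sel], snp_ids)
    df = pd.read_csv(source, sep="\t", index_col=0)
    missing = [s for s in snp_ids if s not in df.index or s not in df.columns]
    if missing:
        raise KeyError(f"SNPs absent from LD file: {missing}")
    sub = df.loc[snp_ids, snp_ids].to_numpy(dtype=float)
    if not np.allclose(sub, sub.T, atol=1e-6):
        import warnings

        warnings.warn("LD matrix asymmetric beyond 1e-6; symmetrizing")
    sub = (sub + sub.T) / 2.0
    np.fill_diagonal(sub, 1.0)
    return LdMatrix(sub, list(snp_ids))


def write_ld(ld: LdMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.sigma, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# model store


@dataclass
class GeneModelRecord:
    """Persisted trained model for one gene."""

    gene_id: str
    W: np.ndarray  # q x p SNP weights
    snp_ids: list[str]
    ref_allele: list[str]
    alt_allele: list[str]
    c1: float
    c2: float
    d: np.ndarray  # canonical covariances
    rank: int
    seed: int
    chrom: str = "NA"
    tss: int = 0
    n_events: int = 0
    cp_fit: float = float("nan")
    kruskal_margin: int = 0
    config_hash: str = ""


class ModelStoreError(ValueError):
    pass


def write_model_store(models: list[GeneModelRecord], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = STORE_FORMAT_VERSION
        for m in models:
            g = f.create_group(f"genes/{m.gene_id}")
            g.create_dataset("W", data=m.W)
            g.create_dataset("d", data=m.d)
            g.create_dataset("snp_ids", data=np.array(m.snp_ids, dtype="S"))
            g.create_dataset("ref_allele", data=np.array(m.ref_allele, dtype="S"))
            g.create_dataset("alt_allele", data=np.array(m.alt_allele, dtype="S"))
            for key in (
                "gene_id", "c1", "c2", "rank", "seed", "chrom", "tss",
                "n_events", "cp_fit", "kruskal_margin", "config_hash",
            ):
                g.attrs[key] = getattr(m, key)


def read_model_store(path: str | Path) -> list[GeneModelRecord]:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ModelStoreError(f"cannot parse model store {path}: {exc}") from exc
    with f:
        version = f.attrs.get("format_version")
        if version != STORE_FORMAT_VERSION:
            raise ModelStoreError(
                f"model store version {version!r} incompatible with reader "
                f"version {STORE_FORMAT_VERSION}"
            )
        models = []
        genes = f.get("genes")
        names = sorted(genes.keys()) if genes is not None else []
        for name in names:
            g = genes[name]
            models.append(
                GeneModelRecord(
                    gene_id=str(g.attrs["gene_id"]),
                    W=g["W"][()],
                    snp_ids=[s.decode() for s in g["snp_ids"][()]],
                    ref_allele=[s.decode() for s in g["ref_allele"][()]],
                    alt_allele=[s.decode() for s in g["alt_allele"][()]],
                    c1=float(g.attrs["c1"]),
                    c2=float(g.attrs["c2"]),
                    d=g["d"][()],
                    rank=int(g.attrs["rank"]),
                    seed=int(g.attrs["seed"]),
                    chrom=str(g.attrs["chrom"]),
                    tss=int(g.attrs["tss"]),
                    n_events=int(g.attrs["n_events"]),
                    cp_fit=float(g.attrs["cp_fit"]),
                    kruskal_margin=int(g.attrs["kruskal_margin"]),
                    config_hash=str(g.attrs["config_hash"]),
                )
            )
    return models


def models_equal(a: GeneModelRecord, b: GeneModelRecord) -> bool:
    """Bit-exact equality of numeric payloads plus metadata equality."""
    for f_ in dataclasses.fields(GeneModelRecord):
        va, vb = getattr(a, f_.name), getattr(b, f_.name)
        if isinstance(va, np.ndarray):
            if va.shape != vb.shape or not np.array_equal(va, vb, equal_nan=True):
                return False
        elif isinstance(va, float) and math.isnan(va):
            if not (isinstance(vb, float) and math.isnan(vb)):
                return False
        elif va != vb:
            return False
    return True
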