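"""Per-gene model building and transcriptome-wide association orchestration.

``build_gene_model_from_arrays`` is the in-memory core:
preprocess -> CP decomposition at rank r = p -> sparse CCA -> SNP weights W.
``run_associate`` evaluates a populated model store against GWAS summary
statistics and an LD reference, applying Bonferroni over testable genes.

Statistical degeneracy at any stage (too few events, no cis-SNPs, an
all-zero sparse-CCA solution) marks the gene untestable and never aborts
the run; seeds derive from (global seed, gene id) so serial and parallel
execution agree.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, cpdecomp, formats_io, preprocess, scca

logger = logging.getLogger("mtsg")


@dataclass
class RunConfig:
    min_samples_per_tissue: int = 200
    min_tissues_per_subject: int = 13
    max_missing_tissues: int = 20
    min_events_per_gene: int = 2
    rank_multiplier: float = 1.0
    window_bp: int = 1_000_000
    n_perm: int = 25
    seed: int = 0
    tissue_whitelist: list[str] | None = None
    gene_whitelist: list[str] | None = None

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class BuildOutcome:
    gene_id: str
    model: formats_io.GeneModelRecord | None
    untestable_reason: str | None = None

    @property
    def testable(self) -> bool:
        return self.model is not None


def gene_seed(global_seed: int, gene_id: str) -> int:
    h = int(hashlib.sha256(gene_id.encode()).hexdigest()[:8], 16)
    return (global_seed * 1_000_003 + h) % (2**31 - 1)


def build_gene_model_from_arrays(
    gene_id: str,
    tensor: preprocess.SplicingTensor,
    genotypes: formats_io.GenotypeBlock,
    config: RunConfig | None = None,
) -> BuildOutcome:
    """CP decomposition + sparse CCA on a preprocessed tensor and cis-SNPs."""
    config = config or RunConfig()
    seed = gene_seed(config.seed, gene_id)
    n, p, t = tensor.shape
    if p < config.min_events_per_gene:
        return BuildOutcome(gene_id, None, "min_events")
    if genotypes.q == 0:
        return BuildOutcome(gene_id, None, "no_snps")
    if np.all(genotypes.monomorphic):
        return BuildOutcome(gene_id, None, "all_monomorphic")
    r = cpdecomp.choose_rank(p, config.rank_multiplier)
    _, margin = cpdecomp.kruskal_check(p, t, r)
    factors = cpdecomp.cp_als(tensor.g, r, seed=seed)
    # subjects must line up between splicing and genotypes
    common = [s for s in tensor.subject_ids if s in set(genotypes.subject_ids)]
    if len(common) < 10:
        return BuildOutcome(gene_id, None, "too_few_shared_subjects")
    t_idx = {s: i for i, s in enumerate(tensor.subject_ids)}
    g_idx = {s: i for i, s in enumerate(genotypes.subject_ids)}
    Y = factors.Y[[t_idx[s] for s in common], :]
    X = genotypes.X[[g_idx[s] for s in common], :]
    model = scca.scca_fit(
        X, Y, n_factors=p, seed=seed, n_perm=config.n_perm, snp_ids=genotypes.snp_ids
    )
    if model.degenerate or not np.any(model.W):
        return BuildOutcome(gene_id, None, "degenerate_scca")
    record = formats_io.GeneModelRecord(
        gene_id=gene_id,
        W=model.W,
        snp_ids=genotypes.snp_ids,
        ref_allele=genotypes.ref_allele,
        alt_allele=genotypes.alt_allele,
        c1=model.c1,
        c2=model.c2,
        d=model.d,
        rank=r,
        seed=seed,
        tss=genotypes.tss,
        n_events=p,
        cp_fit=factors.fit,
        kruskal_margin=margin,
        config_hash=config.hash(),
    )
    return BuildOutcome(gene_id, record)


def build_gene_model(
    gene_id: str,
    splicing_tables: list[formats_io.SplicingTable],
    genotype_path: str | Path,
    chrom: str,
    tss: int,
    config: RunConfig | None = None,
    subjects: list[str] | None = None,
) -> BuildOutcome:
    """File-level entry point: preprocess tables, load cis genotypes, build."""
    config = config or RunConfig()
    seed = gene_seed(config.seed, gene_id)
    tensor = preprocess.prepare_gene_tensor(
        splicing_tables,
        subjects=subjects,
        max_missing_tissues=config.max_missing_tissues,
        min_events_per_gene=config.min_events_per_gene,
        seed=seed,
    )
    if tensor is None:
        return BuildOutcome(gene_id, None, "min_events")
    block = formats_io.read_genotypes(genotype_path, gene_id, chrom, tss, config.window_bp)
    if block.q == 0:
        return BuildOutcome(gene_id, None, "no_snps")
    outcome = build_gene_model_from_arrays(gene_id, tensor, block, config)
    if outcome.testable:
        outcome.model.chrom = chrom
    return outcome


RESULT_COLUMNS = [
    "gene_id", "chrom", "tss", "n_snps", "n_events", "df", "stat",
    "pvalue", "bonferroni_significant",
]


def run_associate(
    models: list[formats_io.GeneModelRecord],
    gwas: formats_io.GwasStats,
    ld: formats_io.LdMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene harmonize + test, then Bonferroni across testable genes.

    Per-gene failures (no SNP overlap, missing LD coverage) are recorded as
    untestable rows and never abort the run; output rows sort by gene_id.
    """
    results: list[assoc.AssocResult] = []
    for m in sorted(models, key=lambda m: m.gene_id):
        try:
            W, z, sigma, report = assoc.harmonize(m, gwas, ld)
            if report.n_matched == 0:
                res = assoc.AssocResult(m.gene_id, np.nan, 0, np.nan, 0, 0, testable=False)
            else:
                res = assoc.gene_test(W, z, sigma, gene_id=m.gene_id)
                res.n_snps_dropped = len(m.snp_ids) - report.n_matched
        except Exception as exc:  # crash isolation: one bad gene never kills the run
            logger.warning("gene %s failed association: %s", m.gene_id, exc)
            res = assoc.AssocResult(m.gene_id, np.nan, 0, np.nan, 0, 0, testable=False)
        res.chrom, res.tss, res.n_events = m.chrom, m.tss, m.n_events
        results.append(res)
    assoc.bonferroni(results, alpha)
    rows = [
        {
            "gene_id": r.gene_id,
            "chrom": r.chrom,
            "tss": r.tss,
            "n_snps": r.n_snps_used,
            "n_events": r.n_events,
            "df": r.df,
            "stat": r.stat,
            "pvalue": r.pvalue,
            "bonferroni_significant": r.significant_bonferroni,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
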