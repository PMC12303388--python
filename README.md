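# mtsg — multi-tissue splicing gene models

`mtsg` builds per-gene predictive models of alternative splicing that borrow
strength across tissues, and tests those models against GWAS summary
statistics to nominate splicing-mediated risk genes. It is aimed at
statistical geneticists running transcriptome-wide association studies
(TWAS) who have multi-tissue intron-excision-ratio tables (LeafCutter
style), cis genotypes, and GWAS z-scores, but no individual-level trait
data.

## The model

For each gene, splicing ratios over `n` subjects, `p` splicing events and
`t` tissues form a third-order tensor **𝒢** (n × p × t). Missing values are
filled in two ways before decomposition: tissue-wide biological absences
take the minimum observed ratio of the gene's splicing matrix (a
conservative stand-in for biological zero), while subject-level technical
gaps are imputed by EM for a multivariate normal on the
subject × (event, tissue) unfolding.

The tensor is decomposed by canonical polyadic (CP) alternating least
squares at rank `r = p`:

    𝒢 ≈ Σₖ λₖ · Yₖ ∘ Cₖ ∘ Tₖ

giving subject (`Y`, n × r), splicing-event (`C`, p × r) and tissue
(`T`, t × r) loading matrices. The choice `r = p` is screened by the Kruskal
sufficient condition `min(2p + t, 3p) ≥ 2r + 2`, which holds whenever
`n > p` and `t ≥ 2`, so the factorization is essentially unique.

Sparse canonical correlation analysis (penalized matrix decomposition)
couples the subject loadings `Y` to the cis genotype matrix `X`
(SNPs within ±1 Mb of the TSS): the first pair `(w₁, u₁)` maximizes
`w₁ᵀXᵀYu₁` subject to `‖w‖₂ ≤ 1, ‖u‖₂ ≤ 1, ‖w‖₁ ≤ c₁, ‖u‖₁ ≤ c₂`, with the
penalties chosen by permutation; further pairs come from deflating `XᵀY`.
The `p` genotype-side vectors form the SNP weight matrix `W` (q × p) — the
gene's trained model.

Association with a trait needs only GWAS z-scores `z` and an LD matrix `Σ`
from a reference panel. Under the null, `Wᵀz ~ MVN(0, WᵀΣW)`, so

    T = zᵀ W (WᵀΣW)⁻ Wᵀ z  ~  χ²(df)

where the pseudo-inverse drops eigenvalues below 1/30 of the largest
(canonical pairs within a gene are correlated, so `WᵀΣW` is routinely
near-singular) and `df` is the retained eigenvalue count. Bonferroni
correction at α = 0.05 runs over testable genes only.

## Worked example

Everything below runs from synthetic data — the package ships a generator
that plants genotype-regulated splicing components with known causal SNPs:

```python
import numpy as np
from mtsg import (generate_synthetic_gene, classify_missing, impute_tensor,
                  assemble_tensor, build_gene_model_from_arrays, RunConfig,
                  run_associate, formats_io, nullsim)

syn = generate_synthetic_gene(n_train=300, p=4, t=5, q=30, n_causal=2,
                              h2_component=0.5, seed=11)
kinds = classify_missing(syn.g_raw)
tensor = assemble_tensor(impute_tensor(syn.g_raw, kinds, syn.subject_ids,
                                       syn.event_ids, syn.tissue_ids, seed=11))
out = build_gene_model_from_arrays("geneA", tensor, syn.genotypes, RunConfig(seed=11))
m = out.model
print("W shape:", m.W.shape, " nonzero weights:", int((m.W != 0).sum()))
print("CP fit:", round(m.cp_fit, 3), " Kruskal margin:", m.kruskal_margin)
print("true causal SNP indices:", syn.truth["causal_snps"])
print("top-weight SNP indices:", np.argsort(np.max(np.abs(m.W), axis=1))[-2:].tolist())
```

prints

```
W shape: (30, 4)  nonzero weights: 4
CP fit: 0.979  Kruskal margin: 2
true causal SNP indices: [4, 24]
top-weight SNP indices: [4, 24]
```

— the CP decomposition explains 97.9% of the tensor's Frobenius norm, the
uniqueness margin is positive, and the sparse weight matrix concentrates on
exactly the two planted causal SNPs. Testing the model against a simulated
GWAS whose trait runs through those SNPs:

```python
rng = np.random.default_rng(0)
gamma = np.zeros(30); gamma[syn.truth["causal_snps"]] = 1.0
L = np.linalg.cholesky(syn.ld.sigma)
X1 = rng.standard_normal((5000, 30)) @ L.T
Y1 = X1 @ gamma * 0.05 + rng.standard_normal(5000)
z = nullsim.marginal_ols_z(X1, Y1)
gwas = formats_io.GwasStats(list(m.snp_ids), list(m.alt_allele), list(m.ref_allele), z)
print(run_associate([m], gwas, syn.ld).to_string(index=False))
```

```
gene_id chrom     tss  n_snps  n_events  df      stat   pvalue  bonferroni_significant
  geneA    NA 5000000      30         4   2 24.019101 0.000006                    True
```

The statistic 24.02 on 2 retained degrees of freedom gives p ≈ 6×10⁻⁶ — the
gene is correctly flagged.

A command-line layer wraps the same functions: `mtsg synth` writes a
synthetic gene to disk in the external formats, `mtsg build` trains models
from a YAML config, `mtsg associate` produces the results TSV, and
`mtsg simulate-null` reports empirical type-I error rates.

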