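import numpy as np
import pytest

from mtsg import generate_synthetic_gene, prepare_gene_tensor


@pytest.fixture(scope="session")
def synthetic_gene():
    """One moderately sized synthetic gene with planted genetic structure."""
    return generate_synthetic_gene(
        n_train=200, p=4, t=5, q=30, n_causal=2, h2_component=0.5, seed=11
    )


@pytest.fixture(scope="session")
def synthetic_tensor(synthetic_gene):
    from mtsg import classify_missing, impute_tensor, assemble_tensor

    syn = synthetic_gene
    kinds = classify_missing(syn.g_raw)
    tensor = impute_tensor(
        syn.g_raw, kinds, syn.subject_ids, syn.event_ids, syn.tissue_ids, seed=7
    )
    return assemble_tensor(tensor)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_splicing_tsv(path, subjects, rows):
    """rows: list of (chrom, start, end, event_id, [cell tokens])."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tevent_id\t" + "\t".join(subjects) + "\n")
        for chrom, start, end, eid, cells in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{eid}\t" + "\t".join(cells) + "\n")
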