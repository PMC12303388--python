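import math

import numpy as np
import pytest

from mtsg import formats_io
from mtsg.formats_io import (
    FormatError,
    GeneModelRecord,
    GenotypeBlock,
    LdMatrix,
    ModelStoreError,
    compute_ld,
    load_or_compute_ld,
    models_equal,
    parse_event_id,
    read_genotypes,
    read_gwas,
    read_model_store,
    read_splicing_table,
    write_model_store,
    write_splicing_table,
)

from conftest import write_splicing_tsv


class TestSplicingTable:
    def test_small_table_parses_all_cells(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_splicing_tsv(path, ["s1", "s2"], [
            ("chr1", 100, 200, "chr1:100:200:clu_7", ["0.5", "0.25"]),
            ("chr1", 300, 400, "chr1:300:400:clu_7", ["0.1", "1.0"]),
        ])
        t = read_splicing_table(path, "liver")
        assert t.ratios.shape == (2, 2)
        assert not np.isnan(t.ratios).any()
        assert t.ratios[0, 1] == 0.25

    def test_na_token_becomes_missing_not_zero(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_splicing_tsv(path, ["s1"], [
            ("chr1", 100, 200, "chr1:100:200:clu_7", ["NA"]),
            ("chr1", 300, 400, "chr1:300:400:clu_7", ["0.0"]),
        ])
        t = read_splicing_table(path, "liver")
        assert math.isnan(t.ratios[0, 0])
        assert t.ratios[1, 0] == 0.0

    def test_event_id_parse(self):
        assert parse_event_id("chr1:100:200:clu_7") == ("chr1", 100, 200, "clu_7")
        with pytest.raises(FormatError):
            parse_event_id("chr1:100:200")

    def test_non_numeric_ratio_names_location(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_splicing_tsv(path, ["s1"], [
            ("chr1", 100, 200, "chr1:100:200:clu_7", ["bogus"]),
        ])
        with pytest.raises(FormatError, match="s1"):
            read_splicing_table(path, "liver")

    def test_duplicate_event_id_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_splicing_tsv(path, ["s1"], [
            ("chr1", 100, 200, "chr1:100:200:clu_7", ["0.1"]),
            ("chr1", 100, 200, "chr1:100:200:clu_7", ["0.2"]),
        ])
        with pytest.raises(FormatError, match="duplicate"):
            read_splicing_table(path, "liver")

    def test_writer_reader_roundtrip(self, tmp_path, synthetic_gene):
        syn = synthetic_gene
        table = formats_io.SplicingTable(
            tissue="tissue0",
            event_ids=list(syn.event_ids),
            chroms=["chr1"] * 4,
            starts=np.array([1000, 1100, 1200, 1300], dtype=np.int64),
            ends=np.array([1050, 1150, 1250, 1350], dtype=np.int64),
            clusters=["clu_1"] * 4,
            subject_ids=list(syn.subject_ids),
            ratios=syn.g_raw[:, :, 0].T,
        )
        path = tmp_path / "rt.tsv"
        write_splicing_table(table, path)
        back = read_splicing_table(path, "tissue0")
        assert back.event_ids == table.event_ids
        np.testing.assert_array_equal(back.ratios, table.ratios)


class TestGenotypes:
    def _dosage_file(self, tmp_path, positions):
        lines = ["snp_id\tpos\tref\talt\ta\tb"]
        for i, pos in enumerate(positions):
            lines.append(f"rs{i}\t{pos}\tA\tG\t{i % 3}\t1")
        path = tmp_path / "dos.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_cis_window_is_closed_interval(self, tmp_path):
        path = self._dosage_file(tmp_path, [3_999_999, 4_000_000, 5_000_000, 6_000_000, 6_000_001])
        block = read_genotypes(path, "g", "chr1", tss=5_000_000, window_bp=1_000_000)
        assert block.snp_ids == ["rs1", "rs2", "rs3"]

    def test_empty_window_gives_zero_snp_block(self, tmp_path):
        path = self._dosage_file(tmp_path, [1_000])
        block = read_genotypes(path, "g", "chr1", tss=50_000_000)
        assert block.q == 0

    def test_monomorphic_column_flagged(self, tmp_path):
        path = self._dosage_file(tmp_path, [5_000_000, 5_000_100])
        block = read_genotypes(path, "g", "chr1", tss=5_000_000)
        # column 'b' values are all 1 -> per-SNP dosages differ; check explicit case
        X = np.array([[0.0, 1.0], [0.0, 2.0]])
        b2 = GenotypeBlock("g", 1, X, ["a", "b"], np.array([1, 2]), ["A", "A"],
                           ["G", "G"], ["s1", "s2"])
        assert b2.monomorphic.tolist() == [True, False]
        assert block.q == 2

    def test_vcf_gt_dosage_and_missing(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chr1\t5000000\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
            "chr1\t5000100\trs2\tA\tG\t.\t.\t.\tGT\t./.\t0/0\n"
            "chr1\t5000200\trs3\tA\tG,C\t.\t.\t.\tGT\t0/1\t0/0\n"
        )
        block = read_genotypes(vcf, "g", "chr1", tss=5_000_000)
        assert block.snp_ids == ["rs1", "rs2"]
        assert block.n_multiallelic_skipped == 1
        assert block.X[0, 0] == 1.0 and block.X[1, 0] == 2.0
        assert np.isnan(block.X[0, 1]) and block.X[1, 1] == 0.0


class TestGwas:
    def _write(self, tmp_path, header, rows):
        path = tmp_path / "gwas.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_z_from_beta_se(self, tmp_path):
        path = self._write(tmp_path, "snp_id\teffect_allele\tother_allele\tbeta\tse",
                           ["rs1\tG\tA\t0.2\t0.1"])
        g = read_gwas(path)
        assert g.z[0] == pytest.approx(2.0)

    def test_explicit_z_passthrough_and_se0_dropped(self, tmp_path):
        path = self._write(tmp_path, "snp_id\teffect_allele\tother_allele\tz",
                           ["rs1\tG\tA\t-1.25"])
        assert read_gwas(path).z[0] == -1.25
        path2 = self._write(tmp_path, "snp_id\teffect_allele\tother_allele\tbeta\tse",
                            ["rs1\tG\tA\t0.2\t0.1", "rs2\tG\tA\t0.3\t0.0"])
        g = read_gwas(path2)
        assert g.n_dropped == 1 and g.snp_id == ["rs1"]

    def test_missing_columns_is_schema_error(self, tmp_path):
        path = self._write(tmp_path, "snp_id\tz", ["rs1\t1.0"])
        with pytest.raises(FormatError, match="effect_allele"):
            read_gwas(path)


class TestLd:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x + 3])
        ld = compute_ld(X, ["a", "b"])
        assert ld.sigma[0, 1] == pytest.approx(1.0)

    def test_agrees_with_two_pass_oracle(self, rng):
        X = rng.normal(size=(10, 5))
        ld = compute_ld(X, [f"s{i}" for i in range(5)])
        # naive two-pass Pearson correlation
        oracle = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                xi, xj = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
                oracle[i, j] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
        np.testing.assert_allclose(ld.sigma, oracle, atol=1e-12)

    def test_independent_columns_near_zero(self, rng):
        n = 4000
        X = rng.normal(size=(n, 2))
        ld = compute_ld(X, ["a", "b"])
        assert abs(ld.sigma[0, 1]) < 3 / np.sqrt(n)

    def test_identity_tsv_roundtrip(self, tmp_path):
        ld = LdMatrix(np.eye(3), ["a", "b", "c"])
        path = tmp_path / "ld.tsv"
        formats_io.write_ld(ld, path)
        back = load_or_compute_ld(path, ["a", "b", "c"])
        np.testing.assert_array_equal(back.sigma, np.eye(3))

    def test_missing_snp_raises(self, tmp_path):
        ld = LdMatrix(np.eye(2), ["a", "b"])
        path = tmp_path / "ld.tsv"
        formats_io.write_ld(ld, path)
        with pytest.raises(KeyError, match="zzz"):
            load_or_compute_ld(path, ["a", "zzz"])


class TestModelStore:
    def _record(self, gene_id="g1"):
        return GeneModelRecord(
            gene_id=gene_id,
            W=np.array([[0.5], [-0.5]]),
            snp_ids=["rs1", "rs2"],
            ref_allele=["A", "C"],
            alt_allele=["G", "T"],
            c1=1.3, c2=1.1,
            d=np.array([2.5]),
            rank=1, seed=42, chrom="chr1", tss=100, n_events=2,
            cp_fit=0.97, kruskal_margin=3, config_hash="abc",
        )

    def test_roundtrip_bit_exact(self, tmp_path):
        m = self._record()
        path = tmp_path / "store.h5"
        write_model_store([m], path)
        back = read_model_store(path)
        assert len(back) == 1 and models_equal(m, back[0])

    def test_empty_store_valid(self, tmp_path):
        path = tmp_path / "empty.h5"
        write_model_store([], path)
        assert read_model_store(path) == []

    def test_corrupted_file_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.h5"
        path.write_text("not hdf5 at all")
        with pytest.raises(ModelStoreError):
            read_model_store(path)

    def test_version_mismatch_raises(self, tmp_path):
        import h5py

        path = tmp_path / "v.h5"
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = 999
        with pytest.raises(ModelStoreError, match="version"):
            read_model_store(path)
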