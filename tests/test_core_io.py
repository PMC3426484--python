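import numpy as np
import pandas as pd
import pytest

from glycoscan import core_io
from glycoscan.core_io import (
    GlycoscanError,
    GroupScheme,
    HaplotypePanel,
    filter_maf,
    read_haplotype_vcf,
    read_tables,
    write_results_tsv,
)

from conftest import make_panel, single_group_scheme

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def write_vcf(tmp_path, body, name="fixture.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestVcfReader:
    def test_small_phased_fixture(self, tmp_path):
        """2 samples x 3 sites -> 4x3 matrix with ancestral-oriented codes."""
        p = write_vcf(
            tmp_path,
            "chr1\t100\trs1\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|1\n"
            "chr1\t200\trs2\tC\tT\t.\tPASS\tAA=C\tGT\t0|0\t0|1\n"
            "chr1\t300\trs3\tG\tA\t.\tPASS\tAA=G\tGT\t1|0\t0|0\n",
        )
        panel = read_haplotype_vcf(p)
        assert panel.haplotypes.shape == (4, 3)
        expected = np.array([[0, 0, 1], [1, 0, 0], [1, 0, 0], [1, 1, 0]]).T
        np.testing.assert_array_equal(panel.haplotypes, expected.T)
        assert panel.snps["ancestral_allele"].tolist() == ["A", "C", "G"]

    def test_ancestral_equal_to_alt_flips_codes(self, tmp_path):
        p = write_vcf(
            tmp_path,
            "chr1\t100\trs1\tA\tG\t.\tPASS\tAA=G\tGT\t0|1\t1|1\n",
        )
        panel = read_haplotype_vcf(p)
        # REF/ALT coding 0,1,1,1 becomes 1,0,0,0 after ancestral orientation
        np.testing.assert_array_equal(panel.haplotypes[:, 0], [1, 0, 0, 0])
        assert panel.snps.loc[0, "ancestral_allele"] == "G"
        assert panel.snps.loc[0, "derived_allele"] == "A"

    def test_unknown_ancestral_site_dropped(self, tmp_path):
        p = write_vcf(
            tmp_path,
            "chr1\t100\trs1\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|1\n"
            "chr1\t200\trs2\tC\tT\t.\tPASS\tAA=N\tGT\t0|0\t0|1\n",
        )
        panel = read_haplotype_vcf(p)
        assert panel.n_snps == 1
        assert panel.snps["snp_id"].tolist() == ["rs1"]

    def test_missing_tag_dropped_with_warning(self, tmp_path):
        p = write_vcf(
            tmp_path,
            "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "chr1\t200\trs2\tC\tT\t.\tPASS\tAA=C\tGT\t0|0\t0|1\n",
        )
        panel = read_haplotype_vcf(p)
        assert panel.snps["snp_id"].tolist() == ["rs2"]

    def test_unphased_genotype_errors_with_sample_and_site(self, tmp_path):
        p = write_vcf(
            tmp_path,
            "chr1\t100\trs1\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0/1\n",
        )
        with pytest.raises(GlycoscanError, match="S2.*chr1:100"):
            read_haplotype_vcf(p)

    def test_hand_parsed_fixture_agrees_cell_for_cell(self, tmp_path):
        """The reader must agree with a naive by-hand parse of a 20-line VCF."""
        rng = np.random.default_rng(7)
        lines = []
        for j in range(20):
            gts = ["|".join(map(str, rng.integers(0, 2, 2))) for _ in range(2)]
            lines.append(
                f"chr1\t{100 * (j + 1)}\tv{j}\tA\tG\t.\tPASS\tAA=A\tGT\t" + "\t".join(gts)
            )
        p = write_vcf(tmp_path, "\n".join(lines) + "\n")
        panel = read_haplotype_vcf(p)
        hand = np.array(
            [
                [int(a) for gt in line.split("\t")[9:] for a in gt.split("|")]
                for line in lines
            ]
        ).T
        np.testing.assert_array_equal(panel.haplotypes, hand)

    def test_roundtrip_write_then_read(self, tmp_path):
        rng = np.random.default_rng(1)
        panel = make_panel(rng.integers(0, 2, (8, 12)))
        path = core_io.write_haplotype_vcf(panel, tmp_path / "rt.vcf")
        back = read_haplotype_vcf(path)
        np.testing.assert_array_equal(back.haplotypes, panel.haplotypes)
        assert back.snps["position_bp"].tolist() == panel.snps["position_bp"].tolist()


class TestMafFilter:
    def test_rare_column_removed(self):
        H = np.zeros((100, 2), dtype=np.int8)
        H[:3, 0] = 1   # MAF 0.03
        H[:50, 1] = 1  # MAF 0.5
        panel = make_panel(H)
        out = filter_maf(panel, 0.05)
        assert out.n_snps == 1
        assert out.snps["snp_id"].tolist() == ["s1"]

    def test_boundary_is_inclusive(self):
        H = np.zeros((100, 1), dtype=np.int8)
        H[:95, 0] = 1  # derived 95/100 -> MAF exactly 0.05
        out = filter_maf(make_panel(H), 0.05)
        assert out.n_snps == 1

    def test_per_group_scope(self):
        # SNP rare globally (5/40) but common in G1 (5/10 = 0.5)
        H = np.zeros((40, 2), dtype=np.int8)
        H[:5, 0] = 1
        H[:20, 1] = 1
        panel = make_panel(H)
        groups = ["G1"] * 5 + ["G2"] * 15
        scheme = GroupScheme(
            ["G1", "G2"], dict(zip(panel.samples["sample_id"], groups))
        )
        global_kept = filter_maf(panel, 0.2)
        assert global_kept.snps["snp_id"].tolist() == ["s1"]
        # within G1 the first SNP has MAF 0.5 and survives; the second is
        # monomorphic in G1 and is dropped
        g1_kept = filter_maf(panel, 0.2, scope="per_group:G1", scheme=scheme)
        assert g1_kept.snps["snp_id"].tolist() == ["s0"]

    def test_empty_result_errors(self):
        H = np.zeros((100, 1), dtype=np.int8)
        H[0, 0] = 1
        with pytest.raises(GlycoscanError, match="no SNPs survive"):
            filter_maf(make_panel(H), 0.05)


class TestTables:
    def _write_inputs(self, tmp_path, ann_rows=None, edges_rows=None):
        (tmp_path / "genes.bed").write_text("chr1\t999\t2000\tGENEA\nchr1\t5000\t6000\tGENEB\n")
        ann = ann_rows or [
            ("GENEA", "precursor_biosynthesis", "upstream"),
            ("GENEB", "branching_early_golgi", "downstream"),
        ]
        pd.DataFrame(ann, columns=["gene_id", "sub_pathway", "part"]).to_csv(
            tmp_path / "annotation.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"sample_id": ["a", "b"], "population": ["p", "p"], "continental_group": ["G1", "G2"]}
        ).to_csv(tmp_path / "groups.tsv", sep="\t", index=False)
        edges = edges_rows or [("GENEA", "GENEB"), ("GENEB", "GENEA")]
        pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(
            tmp_path / "edges.tsv", sep="\t", index=False
        )

    def test_bed_coordinates_converted(self, tmp_path):
        self._write_inputs(tmp_path)
        catalog, ann, scheme, graph = read_tables(
            tmp_path / "genes.bed", tmp_path / "annotation.tsv",
            tmp_path / "groups.tsv", tmp_path / "edges.tsv",
        )
        row = catalog.table.set_index("gene_id").loc["GENEA"]
        assert (row["tx_start"], row["tx_end"]) == (1000, 2000)

    def test_duplicate_edge_orders_collapse(self, tmp_path):
        self._write_inputs(tmp_path)
        *_, graph = read_tables(
            tmp_path / "genes.bed", tmp_path / "annotation.tsv",
            tmp_path / "groups.tsv", tmp_path / "edges.tsv",
        )
        assert graph.graph.number_of_edges() == 1

    def test_bad_part_label_rejected(self, tmp_path):
        self._write_inputs(tmp_path, ann_rows=[("GENEA", "x", "upstrem"), ("GENEB", "x", "downstream")])
        with pytest.raises(GlycoscanError, match="upstrem"):
            read_tables(
                tmp_path / "genes.bed", tmp_path / "annotation.tsv",
                tmp_path / "groups.tsv", tmp_path / "edges.tsv",
            )

    def test_edge_with_unannotated_gene_rejected(self, tmp_path):
        self._write_inputs(tmp_path, edges_rows=[("GENEA", "GENEX")])
        with pytest.raises(GlycoscanError, match="GENEX"):
            read_tables(
                tmp_path / "genes.bed", tmp_path / "annotation.tsv",
                tmp_path / "groups.tsv", tmp_path / "edges.tsv",
            )


class TestResultWriter:
    def test_roundtrip_and_determinism(self, tmp_path):
        t = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "p": [0.1, np.nan, 0.25], "k": [1, 2, 3]}
        )
        write_results_tsv({"res": t}, tmp_path / "run1", manifest={"seed": 1})
        write_results_tsv({"res": t}, tmp_path / "run2", manifest={"seed": 1})
        b1 = (tmp_path / "run1/res.tsv").read_bytes()
        assert b1 == (tmp_path / "run2/res.tsv").read_bytes()
        back = core_io.read_results_tsv(tmp_path / "run1/res.tsv")
        assert back["p"].isna().tolist() == [False, True, False]
        assert back["p"].iloc[0] == 0.1
        assert back["k"].tolist() == [1, 2, 3]

    def test_empty_table_writes_header_only(self, tmp_path):
        t = pd.DataFrame(columns=["gene_id", "p"])
        write_results_tsv({"res": t}, tmp_path)
        assert (tmp_path / "res.tsv").read_text() == "gene_id\tp\n"


def test_panel_invariants_enforced():
    with pytest.raises(GlycoscanError, match="increasing"):
        make_panel(np.zeros((2, 2), dtype=np.int8), positions=[200, 100])
    with pytest.raises(GlycoscanError, match="allele codes"):
        make_panel(np.full((2, 2), 7, dtype=np.int8))
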