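"""Catalog construction: parsing, representative selection, universe counts."""

from __future__ import annotations

import textwrap

import pytest

from fntdcscan.genome_model import (
    GenomeModelError,
    GODag,
    Isoform,
    RawFeature,
    build_catalog,
    load_catalog,
    read_annotations,
    read_gff3,
    select_representative,
    write_annotation_table,
    write_gff3,
    write_protein_fasta,
)

from conftest import make_gene


def _write(path, text):
    path.write_text(textwrap.dedent(text))
    return path


class TestReadGff3:
    def test_identity_parse_and_mrna_linking(self, tmp_path):
        gff = _write(tmp_path / "a.gff3", """\
            ##gff-version 3
            chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1
            chr1\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=g1.1;Parent=g1
            chr1\tsrc\tmRNA\t1000\t1800\t.\t+\t.\tID=g1.2;Parent=g1
            chr1\tsrc\texon\t1000\t1500\t.\t+\t.\tID=e1;Parent=g1.1
            """)
        genes, isoforms = read_gff3(gff)
        assert len(genes) == 1
        g = genes[0]
        assert (g.chromosome, g.start, g.end, g.strand) == ("chr1", 1000, 2000, "+")
        assert sorted(isoforms["g1"]) == ["g1.1", "g1.2"]

    def test_end_before_start_is_an_error(self, tmp_path):
        gff = _write(tmp_path / "bad.gff3",
                     "chr1\tsrc\tgene\t2000\t1000\t.\t+\t.\tID=g1\n")
        with pytest.raises(GenomeModelError, match="line 1"):
            read_gff3(gff)

    def test_orphan_mrna_is_an_error(self, tmp_path):
        gff = _write(tmp_path / "orphan.gff3", """\
            chr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1
            chr1\tsrc\tmRNA\t1\t10\t.\t+\t.\tID=x.1;Parent=ghost
            """)
        with pytest.raises(GenomeModelError, match="ghost"):
            read_gff3(gff)

    def test_malformed_line_names_line_number(self, tmp_path):
        gff = _write(tmp_path / "trunc.gff3", """\
            chr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1
            chr1\tonly-three-fields
            """)
        with pytest.raises(GenomeModelError, match="line 2"):
            read_gff3(gff)


class TestSelectRepresentative:
    REC = RawFeature("g1", "gene", "chr1", 100, 200, "+", None)

    def test_longest_isoform_wins_and_go_unions(self):
        isos = [
            Isoform("g1.1", "g1", "M" * 200),
            Isoform("g1.2", "g1", "M" * 350),
        ]
        ann = {"g1.1": {"BP": {"GO:0000001"}}, "g1.2": {"BP": {"GO:0000002"}}}
        gene = select_representative(self.REC, isos, ann)
        assert gene.representative.isoform_id == "g1.2"
        assert gene.representative.protein_length == 350
        assert gene.go_bp == {"GO:0000001", "GO:0000002"}

    def test_length_tie_breaks_to_smaller_isoform_id(self):
        isos = [Isoform("g1.b", "g1", "M" * 300),
                Isoform("g1.a", "g1", "K" * 300)]
        gene = select_representative(self.REC, isos, {})
        assert gene.representative.isoform_id == "g1.a"

    def test_gene_keyed_annotations_are_accepted(self):
        isos = [Isoform("g1.1", "g1", "MKT")]
        gene = select_representative(
            self.REC, isos, {"g1": {"MF": {"GO:0000009"}}})
        assert gene.go_mf == {"GO:0000009"}

    def test_no_isoforms_keeps_gene_without_protein(self):
        gene = select_representative(self.REC, [], {})
        assert gene.representative is None
        assert gene.protein is None


class TestBuildCatalog:
    def test_universe_counts_only_bp_genes(self):
        genes = [
            make_gene(f"g{i}", start=1 + 10_000 * i,
                      go_bp={"GO:0000001"} if i < 6 else frozenset())
            for i in range(10)
        ]
        cat = build_catalog(genes)
        assert cat.universe_N == 6
        assert cat.term_K["GO:0000001"] == 6
        assert len(cat.genes["chr01"]) == 10
        assert len(cat.bp_order["chr01"]) == 6

    def test_duplicate_gene_id_rejected(self):
        genes = [make_gene("g1"), make_gene("g1", start=50_000)]
        with pytest.raises(GenomeModelError, match="duplicate"):
            build_catalog(genes)

    def test_empty_catalog_rejected(self):
        with pytest.raises(GenomeModelError, match="empty"):
            build_catalog([])

    def test_counts_invariant_to_input_order(self):
        genes = [
            make_gene(f"g{i}", start=1 + 10_000 * i,
                      go_bp={f"GO:000000{i % 3}"})
            for i in range(9)
        ]
        cat1 = build_catalog(genes)
        cat2 = build_catalog(reversed(genes))
        assert cat1.term_K == cat2.term_K
        assert cat1.universe_N == cat2.universe_N
        assert [g.gene_id for g in cat1.genes["chr01"]] == \
               [g.gene_id for g in cat2.genes["chr01"]]

    def test_sorted_by_start_then_end_then_id(self):
        genes = [
            make_gene("b", start=100, end=300),
            make_gene("a", start=100, end=300),
            make_gene("c", start=100, end=200),
            make_gene("d", start=50, end=500),
        ]
        cat = build_catalog(genes)
        assert [g.gene_id for g in cat.genes["chr01"]] == ["d", "c", "a", "b"]


class TestPropagation:
    DAG = GODag({
        "GO:0000003": {"GO:0000002"},
        "GO:0000002": {"GO:0000001"},
        "GO:0000001": set(),
    })

    def test_ancestors_accumulate_excluding_root(self):
        # child term on 2 genes, parent term on 1 distinct gene
        genes = [
            make_gene("g1", start=1, go_bp={"GO:0000003"}),
            make_gene("g2", start=20_000, go_bp={"GO:0000003"}),
            make_gene("g3", start=40_000, go_bp={"GO:0000002"}),
        ]
        cat = build_catalog(genes, dag=self.DAG, propagate=True)
        assert cat.term_K["GO:0000002"] == 3  # hand-walked DAG union
        assert "GO:0000001" not in cat.term_K  # root excluded

    def test_term_counts_monotone_toward_root(self):
        dag = GODag({
            "GO:0000004": {"GO:0000003"},
            "GO:0000003": {"GO:0000002"},
            "GO:0000002": {"GO:0000001"},
            "GO:0000001": set(),
        })
        genes = [
            make_gene("g1", start=1, go_bp={"GO:0000004"}),
            make_gene("g2", start=20_000, go_bp={"GO:0000003"}),
            make_gene("g3", start=40_000, go_bp={"GO:0000002"}),
        ]
        cat = build_catalog(genes, dag=dag, propagate=True)
        chain = ["GO:0000004", "GO:0000003", "GO:0000002"]
        counts = [cat.term_K[t] for t in chain]
        assert counts == sorted(counts)

    def test_cycle_detected(self):
        with pytest.raises(GenomeModelError, match="cycle"):
            GODag({"GO:0000001": {"GO:0000002"},
                   "GO:0000002": {"GO:0000001"}})


class TestAnnotationFormats:
    def test_gaf_columns_2_5_9(self, tmp_path):
        gaf = _write(tmp_path / "a.gaf", """\
            !gaf-version: 2.1
            DB\tg1\tSYMB\t\tGO:0000001\tREF\tIEA\t\tP\tname\t\tprotein\ttaxon:1\t2020\tDB
            DB\tg1\tSYMB\t\tGO:0000002\tREF\tIEA\t\tF\tname\t\tprotein\ttaxon:1\t2020\tDB
            """)
        df = read_annotations(gaf)
        assert set(zip(df["id"], df["go_id"], df["go_domain"])) == {
            ("g1", "GO:0000001", "BP"), ("g1", "GO:0000002", "MF")}

    def test_tsv_requires_domain_column(self, tmp_path):
        bad = _write(tmp_path / "bad.tsv", "id\tgo_id\ng1\tGO:1\n")
        with pytest.raises(GenomeModelError):
            read_annotations(bad)


class TestRoundTrip:
    def test_serialize_parse_is_identity(self, tmp_path):
        genes = [
            make_gene("g1", start=1, go_bp={"GO:0000001", "GO:0000002"},
                      go_mf={"GO:0000009"}),
            make_gene("g2", start=20_000, protein="MAAAKQRQISFVKSHFSRQL"),
            make_gene("g3", start=40_000, chromosome="chr02",
                      go_cc={"GO:0000005"}),
        ]
        cat = build_catalog(genes)
        write_gff3(cat, tmp_path / "g.gff3")
        write_protein_fasta(cat, tmp_path / "p.faa")
        write_annotation_table(cat, tmp_path / "a.tsv")
        cat2 = load_catalog(tmp_path / "g.gff3", tmp_path / "p.faa",
                            tmp_path / "a.tsv")
        assert cat2 == cat
        # and a second round trip is stable too
        write_gff3(cat2, tmp_path / "g2.gff3")
        assert (tmp_path / "g2.gff3").read_text() == \
               (tmp_path / "g.gff3").read_text()
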