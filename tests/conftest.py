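"""Shared fixtures: hand-built catalogs and seeded synthetic genomes."""

from __future__ import annotations

import pytest

from fntdcscan.genome_model import Gene, GeneCatalog, Isoform, build_catalog
from fntdcscan.synthetic_data import SimConfig, TruthTable, generate_genome


def make_gene(
    gene_id: str,
    chromosome: str = "chr01",
    start: int = 1,
    end: int | None = None,
    strand: str = "+",
    protein: str | None = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
    go_bp: set[str] = frozenset(),
    go_mf: set[str] = frozenset(),
    go_cc: set[str] = frozenset(),
) -> Gene:
    rep = Isoform(f"{gene_id}.1", gene_id, protein) if protein else None
    return Gene(
        gene_id=gene_id,
        chromosome=chromosome,
        start=start,
        end=end if end is not None else start + 999,
        strand=strand,
        representative=rep,
        go_bp=frozenset(go_bp),
        go_mf=frozenset(go_mf),
        go_cc=frozenset(go_cc),
    )


def linear_catalog(genes_spec: list[dict]) -> GeneCatalog:
    """Build a catalog from compact per-gene dicts, laid out 10 kb apart."""
    genes = []
    pos: dict[str, int] = {}
    for spec in genes_spec:
        chrom = spec.get("chromosome", "chr01")
        start = pos.get(chrom, 1)
        pos[chrom] = start + 10_000
        genes.append(make_gene(start=start, end=start + 999,
                               **{k: v for k, v in spec.items()
                                  if k != "chromosome"},
                               chromosome=chrom))
    return build_catalog(genes)


@pytest.fixture(scope="session")
def sim_genome(tmp_path_factory) -> tuple:
    """The reference synthetic genome: 3,000 genes, 15 planted clusters
    of 4-6 genes, 3 tandem arrays, default seed.  Written to disk and
    parsed back so downstream tests exercise the file round trip."""
    out = tmp_path_factory.mktemp("sim_genome")
    config = SimConfig(
        n_chromosomes=3,
        genes_per_chromosome=1000,
        n_planted_clusters=15,
        planted_cluster_size=(4, 6),
        seed=42,
    )
    catalog, truth, paths = generate_genome(config, out)
    return catalog, truth, paths, config


@pytest.fixture(scope="session")
def tandem_fixture() -> tuple:
    """A 1,000-gene genome holding one planted non-homologous cluster and
    one 5-copy tandem array at 95% target pairwise identity."""
    config = SimConfig(
        n_chromosomes=2,
        genes_per_chromosome=500,
        n_planted_clusters=1,
        planted_cluster_size=(4, 4),
        n_tandem_arrays=1,
        tandem_copies=(5, 5),
        tandem_identity=0.95,
        seed=7,
    )
    catalog, truth, _ = generate_genome(config)
    return catalog, truth


def recovered_clusters(calls, truth: TruthTable, catalog) -> int:
    """Count planted clusters whose term tops a call whose span holds at
    least three planted members."""
    index = catalog.gene_index()
    n = 0
    for pc in truth.planted_clusters:
        for c in calls:
            if c.chromosome != pc.chromosome or c.top_go != pc.go_id:
                continue
            inside = sum(
                1 for gid in pc.gene_ids
                if c.span_start <= index[gid].start
                and index[gid].end <= c.span_end
            )
            if inside >= 3:
                n += 1
                break
    return n
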