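"""Per-cluster file bundles, run summaries and cross-genome comparisons.

Each called cluster is written as a six-file TSV bundle (enrichment rows,
member genes, all span genes, removed tandem ids, filtered and full
alignment hit dumps) plus a pairwise percent-identity matrix of the
member proteins.  Run-level outputs are a one-row-per-call table, a BED6
track of call spans, size distributions and unknown-gene accounting, and
Venn-style GO-set comparisons between genomes.

Printed per-cluster means are truncated (not rounded) to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cluster_calling import FNTDCCall
from .enrichment import ENRICHMENT_COLUMNS, EnrichmentRow
from .genome_model import Gene, GeneCatalog
from .homology import passes_setting, write_hits

DATA_GENE_COLUMNS = [
    "Gene.stable.ID", "Sequence_desc.", "TERMS", "Chromosome.scaffold.name",
    "Gene.start..bp.", "Gene.end..bp.", "Strand", "Sequence_length",
    "Hit_desc.", "Hit_ACC", "E-Value", "Similarity",
]
DATA_ALLGENE_COLUMNS = DATA_GENE_COLUMNS + [
    "Bit-Score", "Alignment_length", "Positives",
]

CALL_TABLE_COLUMNS = [
    "ordinal", "name", "chromosome", "span_start", "span_end", "top_go",
    "top_p", "n_terms", "n_bp_genes", "n_all_genes", "n_removed",
    "all_go_ids",
]


def truncate2(x: float) -> float:
    """Truncate toward zero to two decimals (17.567 -> 17.56)."""
    return math.trunc(x * 100) / 100


@dataclass(frozen=True)
class ClusterFileBundle:
    summary_over: Path
    data_genes_with_bp: Path
    data_allgenes: Path
    removed_blast: Path
    blast_filtr: Path
    blast_everything: Path
    identity_matrix: Path


def _fmt_p(p: float) -> str:
    return f"{p:.6e}"


def _fmt_or(v: float) -> str:
    return "Inf" if math.isinf(v) else f"{v:.6g}"


def _gene_row(g: Gene) -> list[str]:
    return [
        g.gene_id,
        g.description,
        ";".join(sorted(g.go_bp | g.go_mf | g.go_cc)),
        g.chromosome,
        str(g.start),
        str(g.end),
        "1" if g.strand == "+" else "-1",
        str(g.representative.protein_length) if g.representative else "",
        "", "", "", "",  # external annotation-pipeline fields, not produced here
    ]


def write_bundle(
    call: FNTDCCall,
    catalog: GeneCatalog,
    out_dir: str | Path,
) -> ClusterFileBundle:
    """Write the six per-cluster TSVs (plus the identity matrix)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"cluster_{call.ordinal:03d}"
    bundle = ClusterFileBundle(
        summary_over=out / f"{stem}_SUMMARY_OVER.tsv",
        data_genes_with_bp=out / f"{stem}_DATA_GENES_WITH_BP.tsv",
        data_allgenes=out / f"{stem}_DATA_ALLGENES.tsv",
        removed_blast=out / f"{stem}_REMOVED_BLAST.tsv",
        blast_filtr=out / f"{stem}_BLAST____FILTR_.tsv",
        blast_everything=out / f"{stem}_BLAST____EVERYTHING.tsv",
        identity_matrix=out / f"{stem}_IDENTITY_MATRIX.tsv",
    )
    index = catalog.gene_index()

    with open(bundle.summary_over, "w") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in call.rows:
            fh.write("\t".join([
                r.go_id, _fmt_p(r.p_value), _fmt_or(r.odds_ratio),
                f"{r.exp_count:.6g}", str(r.count), str(r.size), r.term,
            ]) + "\n")

    members = [index[gid] for gid in call.member_bp_genes]
    span_genes = catalog.genes_in_span(
        call.chromosome, call.span_start, call.span_end)

    with open(bundle.data_genes_with_bp, "w") as fh:
        fh.write("\t".join(DATA_GENE_COLUMNS) + "\n")
        for g in members:
            fh.write("\t".join(_gene_row(g)) + "\n")

    with open(bundle.data_allgenes, "w") as fh:
        fh.write("\t".join(DATA_ALLGENE_COLUMNS) + "\n")
        for g in span_genes:
            fh.write("\t".join(_gene_row(g) + ["", "", ""]) + "\n")

    with open(bundle.removed_blast, "w") as fh:
        if call.removed_tandem:
            for gid in call.removed_tandem:
                fh.write(gid + "\n")
        else:
            fh.write("NONE\n")

    passing = [h for h in call.hits if passes_setting(h, call.setting)]
    write_hits(passing, bundle.blast_filtr)
    write_hits(call.hits, bundle.blast_everything)

    _write_identity_matrix(members, call, bundle.identity_matrix)
    return bundle


def _write_identity_matrix(
    members: Sequence[Gene], call: FNTDCCall, path: Path
) -> None:
    """Pairwise percent-identity matrix of member proteins (text stand-in
    for a multiple-alignment figure)."""
    ids = [g.gene_id for g in members]
    ident = {}
    for h in call.hits:
        ident[(h.query_id, h.subject_id)] = h.identity_pct
        ident[(h.subject_id, h.query_id)] = h.identity_pct
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(ids) + "\n")
        for a in ids:
            cells = []
            for b in ids:
                if a == b:
                    cells.append("100.00")
                else:
                    v = ident.get((a, b))
                    cells.append(f"{v:.2f}" if v is not None else "")
            fh.write(a + "\t" + "\t".join(cells) + "\n")


def read_bundle(
    bundle: ClusterFileBundle,
) -> tuple[list[EnrichmentRow], list[str], list[str], list[str]]:
    """Parse a written bundle back: rows, member ids, span ids, removed ids."""
    rows: list[EnrichmentRow] = []
    with open(bundle.summary_over) as fh:
        assert fh.readline().rstrip("\n").split("\t") == ENRICHMENT_COLUMNS
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(EnrichmentRow(
                go_id=f[0],
                p_value=float(f[1]),
                odds_ratio=math.inf if f[2] == "Inf" else float(f[2]),
                exp_count=float(f[3]),
                count=int(f[4]),
                size=int(f[5]),
                term=f[6],
            ))
    members = list(
        pd.read_csv(bundle.data_genes_with_bp, sep="\t", dtype=str,
                    keep_default_na=False)["Gene.stable.ID"]
    )
    span = list(
        pd.read_csv(bundle.data_allgenes, sep="\t", dtype=str,
                    keep_default_na=False)["Gene.stable.ID"]
    )
    removed = [
        line.strip() for line in open(bundle.removed_blast) if line.strip()
    ]
    if removed == ["NONE"]:
        removed = []
    return rows, members, span, removed


# ---------------------------------------------------------------------------
# run-level tables


def write_call_table(calls: Sequence[FNTDCCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_TABLE_COLUMNS) + "\n")
        for c in calls:
            n_all = len(c.member_bp_genes) + len(c.interspersed_genes)
            fh.write("\t".join([
                str(c.ordinal), c.name, c.chromosome, str(c.span_start),
                str(c.span_end), c.top_go, _fmt_p(c.top_p),
                str(len(c.rows)), str(len(c.member_bp_genes)), str(n_all),
                str(len(c.removed_tandem)), ";".join(c.go_ids),
            ]) + "\n")


def read_call_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"all_go_ids": str},
                     keep_default_na=False)
    return df


def call_table_go_set(path: str | Path) -> set[str]:
    """All enriched GO ids of a written call table."""
    df = read_call_table(path)
    out: set[str] = set()
    for cell in df["all_go_ids"]:
        if cell:
            out.update(cell.split(";"))
    return out


def write_bed_track(calls: Sequence[FNTDCCall], path: str | Path) -> None:
    """Call spans as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chromosome}\t{c.span_start - 1}\t{c.span_end}\t"
                f"FNTDC#{c.ordinal}|{c.name}\t0\t.\n"
            )


# ---------------------------------------------------------------------------
# distributions and accounting


def size_distributions(calls: Sequence[FNTDCCall]) -> pd.DataFrame:
    """Per-call size metrics: span kb, all genes in span, GO-BP genes.

    Tandem duplicates are not excluded from the sums.
    """
    if not calls:
        raise ValueError("size_distributions needs at least one call")
    rows = []
    for c in calls:
        rows.append({
            "ordinal": c.ordinal,
            "span_kb": (c.span_end - c.span_start + 1) / 1000.0,
            "n_genes": len(c.member_bp_genes) + len(c.interspersed_genes),
            "n_bp_genes": len(c.member_bp_genes),
        })
    return pd.DataFrame(rows)


def size_histograms(
    dist: pd.DataFrame, kb_bin: float = 10.0
) -> dict[str, pd.Series]:
    span_bins = (dist["span_kb"] // kb_bin * kb_bin).astype(float)
    return {
        "span_kb": span_bins.value_counts().sort_index(),
        "n_genes": dist["n_genes"].value_counts().sort_index(),
        "n_bp_genes": dist["n_bp_genes"].value_counts().sort_index(),
    }


def per_cluster_means(totals: Mapping[str, float], n_calls: int
                      ) -> dict[str, float]:
    """Totals over all calls -> truncated two-decimal per-cluster means."""
    if n_calls <= 0:
        raise ValueError("n_calls must be positive")
    return {key: truncate2(value / n_calls) for key, value in totals.items()}


def unknown_gene_stats(
    calls: Sequence[FNTDCCall], catalog: GeneCatalog
) -> dict[str, float]:
    """Totals and per-cluster means of unannotated genes inside call spans.

    Counts, over every called span: all genes, genes without a GO-BP tag,
    genes without any GO tag at all.  Means are totals divided by the
    number of calls, truncated to two decimals.
    """
    if not calls:
        raise ValueError("unknown_gene_stats needs at least one call")
    total = no_bp = no_any = 0
    for c in calls:
        span_genes = catalog.genes_in_span(
            c.chromosome, c.span_start, c.span_end)
        total += len(span_genes)
        no_bp += sum(1 for g in span_genes if not g.has_go_bp)
        no_any += sum(1 for g in span_genes if not g.has_any_go)
    means = per_cluster_means(
        {"genes": total, "no_go_bp": no_bp, "no_go_any": no_any}, len(calls)
    )
    return {
        "n_calls": len(calls),
        "total_genes": total,
        "total_no_go_bp": no_bp,
        "total_no_go_any": no_any,
        "mean_genes": means["genes"],
        "mean_no_go_bp": means["no_go_bp"],
        "mean_no_go_any": means["no_go_any"],
    }


# ---------------------------------------------------------------------------
# cross-genome GO-set comparison


def go_set_comparison(
    per_genome_go_sets: Mapping[str, set[str] | frozenset[str]],
) -> tuple[dict[str, int], dict[str, int]]:
    """Venn region counts over 2-4 genomes.

    Returns (region counts keyed by '&'-joined genome names, per-genome
    set sizes).  Region counts sum to the size of the union of all sets.
    """
    names = list(per_genome_go_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("go_set_comparison takes 2-4 genomes")
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(
                *(set(per_genome_go_sets[n]) for n in combo))
            outside = set.union(
                set(), *(set(per_genome_go_sets[n])
                         for n in names if n not in combo))
            regions["&".join(combo)] = len(inside - outside)
    sizes = {n: len(per_genome_go_sets[n]) for n in names}
    return regions, sizes


def go_region_members(
    per_genome_go_sets: Mapping[str, set[str] | frozenset[str]],
) -> dict[str, list[str]]:
    """The GO ids of every exclusive Venn region, sorted."""
    names = list(per_genome_go_sets)
    out: dict[str, list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(
                *(set(per_genome_go_sets[n]) for n in combo))
            outside = set.union(
                set(), *(set(per_genome_go_sets[n])
                         for n in names if n not in combo))
            out["&".join(combo)] = sorted(inside - outside)
    return out


def write_go_comparison(
    per_genome_go_sets: Mapping[str, set[str] | frozenset[str]],
    path: str | Path,
) -> None:
    """'common and specific GOs'-style TSV: one row per Venn region."""
    members = go_region_members(per_genome_go_sets)
    with open(path, "w") as fh:
        fh.write("region\tn_terms\tgo_ids\n")
        for region, terms in members.items():
            fh.write(f"{region}\t{len(terms)}\t{';'.join(terms)}\n")


def write_run_summary(
    calls: Sequence[FNTDCCall],
    catalog: GeneCatalog,
    path: str | Path,
) -> dict[str, float]:
    """Single-worksheet style summary: per-call rows + aggregate block."""
    aggregates: dict[str, float]
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_TABLE_COLUMNS) + "\n")
        for c in calls:
            n_all = len(c.member_bp_genes) + len(c.interspersed_genes)
            fh.write("\t".join([
                str(c.ordinal), c.name, c.chromosome, str(c.span_start),
                str(c.span_end), c.top_go, _fmt_p(c.top_p),
                str(len(c.rows)), str(len(c.member_bp_genes)), str(n_all),
                str(len(c.removed_tandem)), ";".join(c.go_ids),
            ]) + "\n")
    if calls:
        dist = size_distributions(calls)
        aggregates = {
            "n_calls": float(len(calls)),
            "mean_span_kb": float(dist["span_kb"].mean()),
            "mean_genes": float(dist["n_genes"].mean()),
            "mean_bp_genes": float(dist["n_bp_genes"].mean()),
            "n_terms_total": float(sum(len(c.rows) for c in calls)),
        }
    else:
        aggregates = {"n_calls": 0.0}
    agg_path = Path(path).with_suffix(".aggregates.tsv")
    with open(agg_path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in aggregates.items():
            fh.write(f"{key}\t{value:.6g}\n")
    return aggregates
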