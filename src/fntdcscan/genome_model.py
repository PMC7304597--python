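"""Canonical gene catalog built from GFF3 + protein FASTA + GO annotations.

The scanner operates on gene *order*, not base-pair distance: every
downstream module indexes genes by their rank along a chromosome, with a
separate rank order kept for the subset of genes that carry at least one
GO Biological Process (GO-BP) tag.  This module parses the three input
files, picks one representative isoform per gene (the longest protein,
carrying the union of all isoforms' GO tags), and assembles the ordered
:class:`GeneCatalog` that the window scanner consumes.

Coordinates are stored 1-based inclusive exactly as they appear in GFF3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import obonet
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

GO_DOMAINS = ("BP", "MF", "CC")

# GAF column 9 "aspect" codes → our domain labels
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


class GenomeModelError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class Isoform:
    """One protein-coding isoform of a gene."""

    isoform_id: str
    gene_id: str
    sequence: str

    @property
    def protein_length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise GenomeModelError(
                f"isoform {self.isoform_id!r} has an empty protein sequence"
            )


@dataclass(frozen=True)
class Gene:
    """A gene with its representative isoform and unioned GO tags.

    ``start``/``end`` are 1-based inclusive; ``representative`` is None for
    genes without any protein sequence (kept in the catalog for span
    accounting but excluded from homology analysis).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    representative: Isoform | None = None
    go_bp: frozenset[str] = frozenset()
    go_mf: frozenset[str] = frozenset()
    go_cc: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeModelError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise GenomeModelError(
                f"gene {self.gene_id!r}: bad strand {self.strand!r}"
            )

    @property
    def has_go_bp(self) -> bool:
        return len(self.go_bp) > 0

    @property
    def has_any_go(self) -> bool:
        return bool(self.go_bp or self.go_mf or self.go_cc)

    @property
    def protein(self) -> str | None:
        return self.representative.sequence if self.representative else None

    def sort_key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.gene_id)


class GODag:
    """A minimal GO DAG: term ids, is_a/part_of parents, labels.

    Used only for optional ancestor propagation of GO-BP annotations; the
    scan itself never walks the ontology.
    """

    def __init__(
        self,
        parents: Mapping[str, set[str]],
        names: Mapping[str, str] | None = None,
    ) -> None:
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(p) for t, p in parents.items()
        }
        # make sure every parent id is a node
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, frozenset())
        self.names: dict[str, str] = dict(names or {})
        self._ancestors: dict[str, frozenset[str]] = {}
        self._check_acyclic()

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, p in self.parents.items() if not p}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(t: str, stack: list[str]) -> None:
            if state.get(t) == 1:
                return
            if state.get(t) == 0:
                raise GenomeModelError(f"GO DAG contains a cycle through {t!r}")
            state[t] = 0
            for p in self.parents.get(t, ()):  # iterative enough for GO depth
                visit(p, stack + [t])
            state[t] = 1

        for t in self.parents:
            visit(t, [])

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors of ``term`` (transitive is_a/part_of)."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        frontier = set(self.parents.get(term, ()))
        while frontier:
            out |= frontier
            frontier = {
                gp for p in frontier for gp in self.parents.get(p, ())
            } - out
        res = frozenset(out)
        self._ancestors[term] = res
        return res

    @classmethod
    def from_obo(cls, path: str | Path) -> "GODag":
        graph = obonet.read_obo(str(path))
        parents: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for node, data in graph.nodes(data=True):
            names[node] = data.get("name", "")
            ps = set(data.get("is_a", []))
            for rel in data.get("relationship", []):
                kind, _, target = rel.partition(" ")
                if kind == "part_of":
                    ps.add(target.strip())
            parents[node] = ps
        return cls(parents, names)


@dataclass
class GeneCatalog:
    """Ordered per-chromosome gene lists plus the GO-BP universe counts.

    ``bp_order`` is, per chromosome, the ordered sub-list of genes carrying
    at least one GO-BP tag — the substrate of the master-window scan.
    ``universe_N`` and ``term_K`` describe the genome-wide background of
    the hypergeometric test.
    """

    genes: dict[str, list[Gene]]
    bp_order: dict[str, list[Gene]] = field(init=False)
    universe_N: int = field(init=False)
    term_K: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.bp_order = {
            c: [g for g in gl if g.has_go_bp] for c, gl in self.genes.items()
        }
        self.universe_N = sum(len(v) for v in self.bp_order.values())
        term_K: dict[str, int] = {}
        for gl in self.bp_order.values():
            for g in gl:
                for t in g.go_bp:
                    term_K[t] = term_K.get(t, 0) + 1
        self.term_K = term_K

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.genes)

    def all_genes(self) -> Iterable[Gene]:
        for c in self.chromosomes:
            yield from self.genes[c]

    def gene_index(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.all_genes()}

    def genes_in_span(self, chromosome: str, start: int, end: int) -> list[Gene]:
        """All genes whose span intersects [start, end] (1-based inclusive)."""
        return [
            g
            for g in self.genes.get(chromosome, [])
            if g.start <= end and g.end >= start
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneCatalog):
            return NotImplemented
        return self.genes == other.genes


# ---------------------------------------------------------------------------
# parsing


@dataclass
class RawFeature:
    """One gene or mRNA record lifted from GFF3 before assembly."""

    feature_id: str
    ftype: str
    chromosome: str
    start: int
    end: int
    strand: str
    parent: str | None
    description: str = ""


def read_gff3(path: str | Path) -> tuple[list[RawFeature], dict[str, list[str]]]:
    """Parse gene and mRNA/transcript features from a GFF3 file.

    Returns the gene features (in file order) and a mapping
    gene id → [isoform ids].  Raises :class:`GenomeModelError` naming the
    offending line number on malformed input.
    """
    genes: list[RawFeature] = []
    gene_ids: set[str] = set()
    isoforms: dict[str, list[str]] = {}
    pending: list[tuple[int, RawFeature]] = []  # mRNAs seen before their gene

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GenomeModelError(
                    f"{path}: malformed GFF3 at line {lineno}: expected 9 "
                    f"tab-separated fields"
                )
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise GenomeModelError(
                    f"{path}: malformed GFF3 at line {lineno}: {exc}"
                ) from exc
            ftype = feat.featuretype
            if ftype not in ("gene", "mRNA", "transcript"):
                continue
            if feat.end < feat.start:
                raise GenomeModelError(
                    f"{path}: line {lineno}: end {feat.end} < start {feat.start}"
                )
            fid = (feat.attributes.get("ID") or [None])[0]
            parent = (feat.attributes.get("Parent") or [None])[0]
            desc = (
                feat.attributes.get("description")
                or feat.attributes.get("Note")
                or [""]
            )[0]
            if ftype == "gene":
                if fid is None:
                    raise GenomeModelError(
                        f"{path}: line {lineno}: gene feature lacks an ID attribute"
                    )
                if fid in gene_ids:
                    raise GenomeModelError(
                        f"{path}: line {lineno}: duplicate gene id {fid!r}"
                    )
                gene_ids.add(fid)
                genes.append(
                    RawFeature(fid, "gene", feat.seqid, feat.start, feat.end,
                               feat.strand, None, desc)
                )
            else:
                if fid is None or parent is None:
                    raise GenomeModelError(
                        f"{path}: line {lineno}: {ftype} lacks ID/Parent attributes"
                    )
                pending.append(
                    (lineno,
                     RawFeature(fid, ftype, feat.seqid, feat.start, feat.end,
                                feat.strand, parent))
                )

    for lineno, mrna in pending:
        if mrna.parent not in gene_ids:
            raise GenomeModelError(
                f"{path}: line {lineno}: mRNA {mrna.feature_id!r} references "
                f"unknown gene {mrna.parent!r}"
            )
        isoforms.setdefault(mrna.parent, []).append(mrna.feature_id)

    if not genes:
        raise GenomeModelError(f"{path}: no gene features found")
    return genes, isoforms


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by the first whitespace-delimited header token."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq)
    return seqs


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated annotation table: id, go_id, go_domain[, term_name]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "go_id", "go_domain"}
    if not required.issubset(df.columns):
        raise GenomeModelError(
            f"{path}: annotation table must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    bad = set(df["go_domain"]) - set(GO_DOMAINS)
    if bad:
        raise GenomeModelError(f"{path}: unknown GO domains {sorted(bad)}")
    if "term_name" not in df.columns:
        df["term_name"] = ""
    return df[["id", "go_id", "go_domain", "term_name"]]


def read_gaf(path: str | Path) -> pd.DataFrame:
    """Read GO annotations from a GAF 2.x file (columns 2, 5, 9)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            aspect = _GAF_ASPECT.get(fields[8])
            if aspect is None:
                continue
            rows.append((fields[1], fields[4], aspect, ""))
    return pd.DataFrame(rows, columns=["id", "go_id", "go_domain", "term_name"])


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Auto-detect TSV-table vs GAF annotation format and read it."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!") or first.split("\t")[0] == "":
        return read_gaf(path)
    header = first.rstrip("\n").split("\t")
    if "go_id" in header:
        return read_annotation_table(path)
    return read_gaf(path)


def _annotation_maps(
    annotations: pd.DataFrame,
) -> dict[str, dict[str, set[str]]]:
    """id → {domain → set of GO ids}."""
    out: dict[str, dict[str, set[str]]] = {}
    for rid, go, dom in zip(
        annotations["id"], annotations["go_id"], annotations["go_domain"]
    ):
        out.setdefault(rid, {}).setdefault(dom, set()).add(go)
    return out


def select_representative(
    gene_record: RawFeature,
    isoforms: Sequence[Isoform],
    annotations: Mapping[str, Mapping[str, set[str]]],
) -> Gene:
    """Build a :class:`Gene` from its isoforms and annotation rows.

    The representative is the longest protein (ties broken by smallest
    isoform id); GO tags are the union over the gene id itself and all of
    its isoform ids, so annotation tables keyed either way are accepted.
    """
    rep: Isoform | None = None
    if isoforms:
        rep = min(isoforms, key=lambda i: (-i.protein_length, i.isoform_id))
    else:
        logger.warning(
            "gene %s has no isoform protein sequence; excluded from homology "
            "analysis", gene_record.feature_id,
        )

    go: dict[str, set[str]] = {d: set() for d in GO_DOMAINS}
    keys = [gene_record.feature_id] + [i.isoform_id for i in isoforms]
    for key in keys:
        for dom, terms in annotations.get(key, {}).items():
            go[dom] |= terms

    return Gene(
        gene_id=gene_record.feature_id,
        chromosome=gene_record.chromosome,
        start=gene_record.start,
        end=gene_record.end,
        strand=gene_record.strand,
        representative=rep,
        go_bp=frozenset(go["BP"]),
        go_mf=frozenset(go["MF"]),
        go_cc=frozenset(go["CC"]),
        description=gene_record.description,
    )


def propagate_bp(genes: Iterable[Gene], dag: GODag) -> list[Gene]:
    """Augment each gene's GO-BP set with all ancestors (roots excluded)."""
    roots = dag.roots
    out = []
    for g in genes:
        if not g.go_bp:
            out.append(g)
            continue
        extra: set[str] = set()
        for t in g.go_bp:
            extra |= dag.ancestors(t)
        out.append(replace(g, go_bp=frozenset(set(g.go_bp) | (extra - roots))))
    return out


def build_catalog(
    genes: Iterable[Gene],
    dag: GODag | None = None,
    propagate: bool = False,
) -> GeneCatalog:
    """Sort genes per chromosome and compute the GO-BP universe.

    Sort order is ascending start, then end, then gene id.  With
    ``propagate`` the GO-BP sets are first augmented with their ontology
    ancestors (the "true path rule"), excluding root terms.
    """
    gene_list = list(genes)
    if not gene_list:
        raise GenomeModelError("empty gene catalog")
    seen: set[str] = set()
    for g in gene_list:
        if g.gene_id in seen:
            raise GenomeModelError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    if propagate:
        if dag is None:
            raise GenomeModelError("propagate=True requires a GO DAG")
        gene_list = propagate_bp(gene_list, dag)
    by_chrom: dict[str, list[Gene]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=Gene.sort_key)
    return GeneCatalog(genes=by_chrom)


def load_catalog(
    gff3: str | Path,
    fasta: str | Path,
    annotations: str | Path,
    obo: str | Path | None = None,
    propagate: bool = False,
) -> GeneCatalog:
    """End-to-end loader: files in, ordered catalog out."""
    gene_records, isoform_ids = read_gff3(gff3)
    proteins = read_protein_fasta(fasta)
    ann = _annotation_maps(read_annotations(annotations))
    dag = GODag.from_obo(obo) if obo is not None else None

    genes = []
    for rec in gene_records:
        isos = [
            Isoform(iid, rec.feature_id, proteins[iid])
            for iid in isoform_ids.get(rec.feature_id, [])
            if iid in proteins and proteins[iid]
        ]
        genes.append(select_representative(rec, isos, ann))
    return build_catalog(genes, dag=dag, propagate=propagate)


# ---------------------------------------------------------------------------
# serialization (used by the synthetic generator and for round-tripping)


def write_gff3(catalog: GeneCatalog, path: str | Path) -> None:
    """Write the catalog as GFF3 with one mRNA per representative isoform."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in catalog.all_genes():
            attrs = f"ID={g.gene_id}"
            if g.description:
                attrs += f";description={g.description}"
            fh.write(
                f"{g.chromosome}\tfntdcscan\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            if g.representative is not None:
                fh.write(
                    f"{g.chromosome}\tfntdcscan\tmRNA\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.representative.isoform_id};"
                    f"Parent={g.gene_id}\n"
                )


def write_protein_fasta(catalog: GeneCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in catalog.all_genes():
            if g.representative is None:
                continue
            fh.write(f">{g.representative.isoform_id}\n")
            seq = g.representative.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_annotation_table(catalog: GeneCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgo_id\tgo_domain\tterm_name\n")
        for g in catalog.all_genes():
            for dom, terms in (("BP", g.go_bp), ("MF", g.go_mf), ("CC", g.go_cc)):
                for t in sorted(terms):
                    fh.write(f"{g.gene_id}\t{t}\t{dom}\t\n")
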