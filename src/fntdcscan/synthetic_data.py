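"""Seeded synthetic genomes with planted functional clusters.

The generator emits the exact inputs the scanner reads — GFF3 gene
models, protein FASTA, GO annotation TSV — plus a ground-truth table, so
the whole pipeline can be exercised end to end with a known answer key.

What it emulates:

* multi-chromosome gene catalogs with realistic gene lengths and
  intergenic gaps (order matters to the scanner; base pairs only feed the
  span reports);
* a background GO-BP vocabulary assigned i.i.d. per gene, so no
  background term clusters positionally beyond chance;
* a configurable fraction of genes with no GO-BP tag, and a sub-fraction
  with no GO tag at all (plant genomes leave more than a third of genes
  functionally unannotated);
* planted functional clusters: runs of consecutive GO-BP genes that share
  one dedicated GO-BP term while their proteins are independent random
  sequences (non-homologous by construction);
* planted tandem arrays: runs of adjacent genes whose proteins derive
  from one ancestor by per-site substitution, tuned so *pairwise* identity
  matches the requested target, all sharing a dedicated GO-BP term.

Planted-cluster and tandem-array terms are drawn from id ranges disjoint
from the background vocabulary, making the truth table unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_model import (
    Gene,
    GeneCatalog,
    GenomeModelError,
    Isoform,
    build_catalog,
    load_catalog,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 3
    genes_per_chromosome: int = 1000
    gene_length_bp: tuple[int, int] = (1_000, 6_000)
    intergenic_bp: tuple[int, int] = (500, 15_000)
    frac_no_go_bp: float = 0.38   # genes lacking any GO-BP tag
    frac_no_go_any: float = 0.20  # subset lacking any GO tag at all
    go_vocab_size: int = 500
    background_terms_per_gene: tuple[int, int] = (1, 4)
    n_planted_clusters: int = 15
    planted_cluster_size: tuple[int, int] = (3, 10)
    n_tandem_arrays: int = 3
    tandem_copies: tuple[int, int] = (3, 6)
    tandem_identity: float = 0.95  # target pairwise protein identity
    protein_length_aa: tuple[int, int] = (150, 450)
    isoform2_fraction: float = 0.10  # genes given a second, truncated isoform
    seed: int = 42

    def __post_init__(self) -> None:
        for frac in (self.frac_no_go_bp, self.frac_no_go_any,
                     self.tandem_identity, self.isoform2_fraction):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"fraction {frac} outside [0, 1]")
        if self.frac_no_go_any > self.frac_no_go_bp:
            raise SimulationError(
                "frac_no_go_any cannot exceed frac_no_go_bp"
            )
        for lo, hi in (self.gene_length_bp, self.intergenic_bp,
                       self.background_terms_per_gene,
                       self.planted_cluster_size, self.tandem_copies,
                       self.protein_length_aa):
            if lo > hi or lo < 0:
                raise SimulationError(f"empty sampling range ({lo}, {hi})")


@dataclass(frozen=True)
class PlantedCluster:
    chromosome: str
    gene_ids: tuple[str, ...]
    go_id: str


@dataclass(frozen=True)
class TandemArray:
    chromosome: str
    gene_ids: tuple[str, ...]
    go_id: str
    realized_identity: float  # mean pairwise Hamming identity


@dataclass
class TruthTable:
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    tandem_arrays: list[TandemArray] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tchromosome\tgene_ids\tgo_id\trealized_identity\n")
            for c in self.planted_clusters:
                fh.write(
                    f"cluster\t{c.chromosome}\t{','.join(c.gene_ids)}\t"
                    f"{c.go_id}\t\n"
                )
            for a in self.tandem_arrays:
                fh.write(
                    f"tandem\t{a.chromosome}\t{','.join(a.gene_ids)}\t"
                    f"{a.go_id}\t{a.realized_identity:.4f}\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        truth = cls()
        with open(path) as fh:
            fh.readline()
            for line in fh:
                kind, chrom, gids, go, ident = line.rstrip("\n").split("\t")
                ids = tuple(gids.split(","))
                if kind == "cluster":
                    truth.planted_clusters.append(
                        PlantedCluster(chrom, ids, go))
                else:
                    truth.tandem_arrays.append(
                        TandemArray(chrom, ids, go, float(ident)))
        return truth


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def mutate_protein(
    seq: str, target_identity: float, rng: np.random.Generator
) -> str:
    """Per-site substitution at rate (1 - target_identity), no indels.

    Replacements are uniform over the 19 alternative residues, so the
    realized Hamming identity concentrates at the target (a re-drawn site
    never silently restores the original residue).
    """
    if not 0.0 < target_identity <= 1.0:
        raise SimulationError("target_identity must be in (0, 1]")
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < (1.0 - target_identity)
    for i in np.nonzero(mask)[0]:
        alternatives = AMINO_ACIDS[AMINO_ACIDS != arr[i]]
        arr[i] = rng.choice(alternatives)
    return "".join(arr)


def hamming_identity(a: str, b: str) -> float:
    """Fraction of identical columns of two equal-length sequences."""
    if len(a) != len(b):
        raise SimulationError("hamming_identity needs equal-length sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _bp_term(i: int) -> str:
    return f"GO:{1000000 + i:07d}"


def _planted_term(i: int) -> str:
    return f"GO:{2000000 + i:07d}"


def _tandem_term(i: int) -> str:
    return f"GO:{3000000 + i:07d}"


def _pick_run(
    rng: np.random.Generator,
    candidates_per_chrom: dict[str, list[int]],
    run: int,
    used: dict[str, set[int]],
    max_tries: int = 200,
) -> tuple[str, list[int]]:
    """Pick a random run of ``run`` consecutive candidate positions."""
    chroms = sorted(c for c, idx in candidates_per_chrom.items()
                    if len(idx) >= run)
    if not chroms:
        raise SimulationError("no chromosome can host the requested run")
    for _ in range(max_tries):
        chrom = chroms[rng.integers(len(chroms))]
        idx = candidates_per_chrom[chrom]
        start = int(rng.integers(0, len(idx) - run + 1))
        chosen = idx[start : start + run]
        if not any(i in used[chrom] for i in chosen):
            used[chrom].update(chosen)
            return chrom, list(chosen)
    raise SimulationError(
        "could not place a planted feature; genome too small or too crowded"
    )


@dataclass
class _DraftGene:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    sequence: str
    go_bp: set[str]
    go_mf: set[str]
    go_cc: set[str]
    second_isoform: bool = False


def _draft_genome(config: SimConfig, rng: np.random.Generator
                  ) -> tuple[list[_DraftGene], TruthTable]:
    glo, ghi = config.gene_length_bp
    ilo, ihi = config.intergenic_bp
    plo, phi = config.protein_length_aa
    tlo, thi = config.background_terms_per_gene

    mf_vocab = [f"GO:{4000000 + i:07d}" for i in range(max(config.go_vocab_size // 2, 1))]
    cc_vocab = [f"GO:{5000000 + i:07d}" for i in range(max(config.go_vocab_size // 2, 1))]

    drafts: list[_DraftGene] = []
    by_chrom: dict[str, list[_DraftGene]] = {}
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c:02d}"
        pos = 1
        for j in range(1, config.genes_per_chromosome + 1):
            length = int(rng.integers(glo, ghi + 1))
            start, end = pos, pos + length - 1
            pos = end + 1 + int(rng.integers(ilo, ihi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            u = rng.random()
            go_bp: set[str] = set()
            go_mf: set[str] = set()
            go_cc: set[str] = set()
            if u >= config.frac_no_go_bp:
                n_terms = int(rng.integers(tlo, thi + 1))
                go_bp = {
                    _bp_term(int(t))
                    for t in rng.choice(config.go_vocab_size,
                                        size=min(n_terms, config.go_vocab_size),
                                        replace=False)
                }
                if rng.random() < 0.6:
                    go_mf = {mf_vocab[int(rng.integers(len(mf_vocab)))]}
                if rng.random() < 0.4:
                    go_cc = {cc_vocab[int(rng.integers(len(cc_vocab)))]}
            elif u >= config.frac_no_go_any:
                # BP-less but not annotation-free: give MF and/or CC
                go_mf = {mf_vocab[int(rng.integers(len(mf_vocab)))]}
                if rng.random() < 0.4:
                    go_cc = {cc_vocab[int(rng.integers(len(cc_vocab)))]}
            g = _DraftGene(
                gene_id=f"SYN{c:02d}G{j:05d}",
                chromosome=chrom,
                start=start,
                end=end,
                strand=strand,
                sequence=random_protein(int(rng.integers(plo, phi + 1)), rng),
                go_bp=go_bp,
                go_mf=go_mf,
                go_cc=go_cc,
                second_isoform=rng.random() < config.isoform2_fraction,
            )
            drafts.append(g)
            by_chrom.setdefault(chrom, []).append(g)

    truth = TruthTable()
    used: dict[str, set[int]] = {c: set() for c in by_chrom}

    # planted clusters live on consecutive GO-BP ranks
    bp_positions = {
        c: [i for i, g in enumerate(gl) if g.go_bp]
        for c, gl in by_chrom.items()
    }
    for ci in range(config.n_planted_clusters):
        size = int(rng.integers(config.planted_cluster_size[0],
                                config.planted_cluster_size[1] + 1))
        chrom, positions = _pick_run(rng, bp_positions, size, used)
        term = _planted_term(ci)
        members = []
        for i in positions:
            by_chrom[chrom][i].go_bp.add(term)
            members.append(by_chrom[chrom][i].gene_id)
        truth.planted_clusters.append(
            PlantedCluster(chrom, tuple(members), term))

    # tandem arrays occupy adjacent genes (tandem duplication is local)
    all_positions = {c: list(range(len(gl))) for c, gl in by_chrom.items()}
    per_copy = 1.0 - (1.0 - config.tandem_identity) / 2.0
    for ai in range(config.n_tandem_arrays):
        copies = int(rng.integers(config.tandem_copies[0],
                                  config.tandem_copies[1] + 1))
        chrom, positions = _pick_run(rng, all_positions, copies, used)
        term = _tandem_term(ai)
        base = random_protein(int(rng.integers(plo, phi + 1)), rng)
        seqs = [mutate_protein(base, per_copy, rng) for _ in positions]
        members = []
        for i, seq in zip(positions, seqs):
            g = by_chrom[chrom][i]
            g.sequence = seq
            g.go_bp.add(term)
            members.append(g.gene_id)
        pair_ids = [
            hamming_identity(seqs[i], seqs[j])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        ]
        truth.tandem_arrays.append(TandemArray(
            chrom, tuple(members), term,
            float(np.mean(pair_ids)) if pair_ids else 1.0,
        ))
    return drafts, truth


def _write_files(drafts: Sequence[_DraftGene], out_dir: Path) -> dict[str, Path]:
    paths = {
        "gff3": out_dir / "genome.gff3",
        "fasta": out_dir / "proteins.faa",
        "annotations": out_dir / "annotations.tsv",
    }
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in drafts:
            fh.write(
                f"{g.chromosome}\tfntdcscan-sim\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chromosome}\tfntdcscan-sim\tmRNA\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            if g.second_isoform:
                fh.write(
                    f"{g.chromosome}\tfntdcscan-sim\tmRNA\t{g.start}\t{g.end}"
                    f"\t.\t{g.strand}\t.\tID={g.gene_id}.2;Parent={g.gene_id}\n"
                )
    with open(paths["fasta"], "w") as fh:
        for g in drafts:
            for iso_id, seq in _isoforms(g):
                fh.write(f">{iso_id}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    with open(paths["annotations"], "w") as fh:
        fh.write("id\tgo_id\tgo_domain\tterm_name\n")
        for g in drafts:
            for dom, terms in (("BP", g.go_bp), ("MF", g.go_mf),
                               ("CC", g.go_cc)):
                for t in sorted(terms):
                    fh.write(f"{g.gene_id}\t{t}\t{dom}\t\n")
    return paths


def _isoforms(g: _DraftGene) -> list[tuple[str, str]]:
    isos = [(f"{g.gene_id}.1", g.sequence)]
    if g.second_isoform and len(g.sequence) > 3:
        isos.append((f"{g.gene_id}.2", g.sequence[: 2 * len(g.sequence) // 3]))
    return isos


def _draft_to_gene(g: _DraftGene) -> Gene:
    return Gene(
        gene_id=g.gene_id,
        chromosome=g.chromosome,
        start=g.start,
        end=g.end,
        strand=g.strand,
        representative=Isoform(f"{g.gene_id}.1", g.gene_id, g.sequence),
        go_bp=frozenset(g.go_bp),
        go_mf=frozenset(g.go_mf),
        go_cc=frozenset(g.go_cc),
    )


def generate_genome(
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> tuple[GeneCatalog, TruthTable, dict[str, Path]]:
    """Generate a synthetic genome; optionally write its input files.

    Returns the parsed catalog, the ground-truth table, and the written
    file paths (empty dict when ``out_dir`` is None).  Deterministic per
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    drafts, truth = _draft_genome(config, rng)
    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = _write_files(drafts, out)
        truth_path = out / "truth.tsv"
        truth.write(truth_path)
        paths["truth"] = truth_path
        catalog = load_catalog(paths["gff3"], paths["fasta"],
                               paths["annotations"])
    else:
        catalog = build_catalog(_draft_to_gene(g) for g in drafts)
    return catalog, truth, paths


def shuffle_go_labels(
    catalog: GeneCatalog, rng: np.random.Generator
) -> GeneCatalog:
    """Null model: permute complete GO-BP sets across GO-BP-carrying genes.

    Term frequencies (term_K) and the universe size are conserved; any
    positional clustering of terms is destroyed.
    """
    carriers = [g for g in catalog.all_genes() if g.has_go_bp]
    bp_sets = [g.go_bp for g in carriers]
    perm = rng.permutation(len(bp_sets))
    assignment = {
        carriers[i].gene_id: bp_sets[perm[i]] for i in range(len(carriers))
    }
    new_genes = []
    for g in catalog.all_genes():
        if g.gene_id in assignment:
            new_genes.append(replace(g, go_bp=assignment[g.gene_id]))
        else:
            new_genes.append(g)
    return build_catalog(new_genes)
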