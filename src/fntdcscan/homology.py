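"""Pairwise protein comparison and tandem-duplicate collapsing.

Tandem duplicates inside a candidate window would trivially share GO tags
and fake a functional cluster, so before every enrichment test the genes
of the window are compared all-against-all at the protein level and each
group of mutual homologs is collapsed to its first member by genomic
coordinate ("keep-first" rule).

Alignment is local (Smith–Waterman) with BLOSUM62 and affine gaps
(open 11, extend 1).  Four stringency presets control what counts as a
tandem duplicate, from permissive setting_1 (40% identity over 0.4 of
both sequence lengths — catches anciently diverged "hidden" duplicates)
to strict setting_4 (98% / 0.98 — only near-identical copies).

The all-vs-all driver uses a shared exact 5-mer word prescreen before
running the full alignment, in the spirit of BLAST's seed-and-extend:
pairs of unrelated proteins share no word and are skipped; any pair that
could pass even the loosest preset shares many.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_model import Gene

# Karlin–Altschul constants for gapped BLOSUM62 (open 11 / extend 1)
_KA_LAMBDA = 0.267
_KA_K = 0.041

_WORD_SIZE = 5

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(_BLOSUM62.alphabet) - {"*"}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local-alignment record (best HSP for the pair)."""

    query_id: str
    subject_id: str
    identity_pct: float        # matches / alignment columns * 100
    align_len: int             # columns, gaps included
    align_len_nogap: int       # columns, gap columns excluded
    mismatches: int
    gap_openings: int
    q_start: int               # 1-based inclusive on the query
    q_end: int
    s_start: int
    s_end: int
    q_len: int
    s_len: int
    score: float
    bit_score: float
    evalue: float

    @property
    def ratio_q(self) -> float:
        return self.align_len / self.q_len

    @property
    def ratio_s(self) -> float:
        return self.align_len / self.s_len

    @property
    def ratio_q_nogap(self) -> float:
        return self.align_len_nogap / self.q_len

    @property
    def ratio_s_nogap(self) -> float:
        return self.align_len_nogap / self.s_len


@dataclass(frozen=True)
class TandemSetting:
    """A stringency preset for the tandem-duplicate call."""

    name: str
    min_identity_pct: float
    min_ratio: float


SETTINGS: dict[str, TandemSetting] = {
    "setting_1": TandemSetting("setting_1", 40.0, 0.40),
    "setting_2": TandemSetting("setting_2", 70.0, 0.70),
    "setting_3": TandemSetting("setting_3", 90.0, 0.90),
    "setting_4": TandemSetting("setting_4", 98.0, 0.98),
}


@dataclass(frozen=True)
class TandemGroup:
    """A connected set of mutually homologous window genes."""

    members: frozenset[str]
    representative: str


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _validate(seq: str, label: str) -> str:
    if not seq:
        raise AlignmentError(f"{label}: empty protein sequence")
    seq = seq.rstrip("*")  # tolerate a trailing stop codon
    bad = set(seq) - _ALPHABET
    if bad:
        raise AlignmentError(
            f"{label}: non-amino-acid characters {sorted(bad)}"
        )
    return seq


def align_pair(
    protein_a: str,
    protein_b: str,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Best local gapped alignment of two proteins, BLAST-style statistics.

    Returns None when no alignment with positive score exists (possible
    only for pathological inputs).  The E-value comes from the
    Karlin–Altschul formula with standard gapped BLOSUM62 constants and a
    search space of q_len × s_len; it gates what is *recorded* (E ≤ 10),
    never what is tandem-called.
    """
    a = _validate(protein_a, query_id)
    b = _validate(protein_b, subject_id)
    alignments = _ALIGNER.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    c = aln.counts()
    identities = c.identities
    mismatches = c.mismatches
    gaps = c.gaps
    align_len = identities + mismatches + gaps
    gap_openings = c.open_insertions + c.open_deletions
    q_blocks, s_blocks = aln.aligned
    bit_score = (_KA_LAMBDA * aln.score - math.log(_KA_K)) / math.log(2.0)
    evalue = len(a) * len(b) * 2.0 ** (-bit_score)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=100.0 * identities / align_len,
        align_len=align_len,
        align_len_nogap=identities + mismatches,
        mismatches=mismatches,
        gap_openings=gap_openings,
        q_start=int(q_blocks[0][0]) + 1,
        q_end=int(q_blocks[-1][1]),
        s_start=int(s_blocks[0][0]) + 1,
        s_end=int(s_blocks[-1][1]),
        q_len=len(a),
        s_len=len(b),
        score=float(aln.score),
        bit_score=bit_score,
        evalue=evalue,
    )


def _words(seq: str) -> frozenset[str]:
    return frozenset(
        seq[i : i + _WORD_SIZE] for i in range(len(seq) - _WORD_SIZE + 1)
    )


def window_hits(
    genes: Sequence[Gene],
    max_evalue: float = 10.0,
    word_index: Mapping[str, frozenset[str]] | None = None,
) -> list[AlignmentHit]:
    """All-vs-all comparison of the window's proteins.

    Genes lacking a protein are skipped.  One hit per ordered-by-coordinate
    pair is recorded when the pair shares at least one exact 5-mer and the
    best alignment reaches E ≤ ``max_evalue``.  ``word_index`` lets callers
    reuse precomputed per-gene word sets across windows.
    """
    with_protein = [g for g in genes if g.protein]
    words: dict[str, frozenset[str]] = {}
    for g in with_protein:
        if word_index is not None and g.gene_id in word_index:
            words[g.gene_id] = word_index[g.gene_id]
        else:
            words[g.gene_id] = _words(g.protein.rstrip("*"))
    hits: list[AlignmentHit] = []
    for i, ga in enumerate(with_protein):
        for gb in with_protein[i + 1 :]:
            if words[ga.gene_id].isdisjoint(words[gb.gene_id]):
                continue
            hit = align_pair(ga.protein, gb.protein, ga.gene_id, gb.gene_id)
            if hit is not None and hit.evalue <= max_evalue:
                hits.append(hit)
    return hits


def passes_setting(hit: AlignmentHit, setting: TandemSetting) -> bool:
    """Does this pair count as a tandem duplicate under the preset?

    Requires minimum identity AND minimum alignment-length coverage of
    both the query and the subject (gap-included alignment length).
    """
    return (
        hit.identity_pct >= setting.min_identity_pct
        and hit.ratio_q >= setting.min_ratio
        and hit.ratio_s >= setting.min_ratio
    )


def tandem_groups(
    window_genes: Sequence[Gene],
    hits: Iterable[AlignmentHit],
    setting: TandemSetting,
) -> list[TandemGroup]:
    """Single-linkage connected components over pairs passing the preset.

    Singletons are not returned.  Each group's representative is its first
    member by ascending (start, end, gene_id).
    """
    by_id = {g.gene_id: g for g in window_genes}
    parent: dict[str, str] = {gid: gid for gid in by_id}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for hit in hits:
        if hit.query_id in parent and hit.subject_id in parent:
            if passes_setting(hit, setting):
                parent[find(hit.query_id)] = find(hit.subject_id)

    comps: dict[str, set[str]] = {}
    for gid in parent:
        comps.setdefault(find(gid), set()).add(gid)

    groups = []
    for members in comps.values():
        if len(members) < 2:
            continue
        rep = min(members, key=lambda gid: by_id[gid].sort_key())
        groups.append(TandemGroup(frozenset(members), rep))
    groups.sort(key=lambda gr: by_id[gr.representative].sort_key())
    return groups


def collapse(
    window_genes: Sequence[Gene],
    groups: Iterable[TandemGroup],
) -> tuple[list[Gene], list[str]]:
    """Drop all non-representative tandem members from the window.

    Returns the retained genes in their original order and the removed
    gene ids in coordinate order.  Idempotent: collapsing a collapsed
    window removes nothing further.
    """
    removed = {
        gid for gr in groups for gid in gr.members if gid != gr.representative
    }
    retained = [g for g in window_genes if g.gene_id not in removed]
    removed_sorted = sorted(
        removed,
        key=lambda gid: next(
            g.sort_key() for g in window_genes if g.gene_id == gid
        ),
    )
    return retained, removed_sorted


# ---------------------------------------------------------------------------
# BLAST-tabular style I/O

BLAST_COLUMNS = [
    "Query_id", "len_query", "Subject_id", "len_subject", "identity",
    "alignment_length", "mismatches", "gap_openings", "q_start", "q_end",
    "s_start", "s_end", "e-value", "bit_score", "len_algn_VS_len_query",
    "len_algn_VS_len_subj", "len_query_vs_len_subj",
    "len_algn_minus_gaps_vs_len_subj", "len_algn_minus_gaps_vs_len_query",
]


def hit_to_row(hit: AlignmentHit) -> list[str]:
    return [
        hit.query_id, str(hit.q_len), hit.subject_id, str(hit.s_len),
        f"{hit.identity_pct:.2f}", str(hit.align_len), str(hit.mismatches),
        str(hit.gap_openings), str(hit.q_start), str(hit.q_end),
        str(hit.s_start), str(hit.s_end), f"{hit.evalue:.2e}",
        f"{hit.bit_score:.1f}", f"{hit.ratio_q:.4f}", f"{hit.ratio_s:.4f}",
        f"{hit.q_len / hit.s_len:.4f}", f"{hit.ratio_s_nogap:.4f}",
        f"{hit.ratio_q_nogap:.4f}",
    ]


def write_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BLAST_COLUMNS) + "\n")
        for hit in hits:
            fh.write("\t".join(hit_to_row(hit)) + "\n")


def read_hits(path: str | Path) -> list[AlignmentHit]:
    """Read a BLAST outfmt-6-like TSV back into hits (pass-through fields).

    Supports both our own dumps and external aligner output with the same
    column layout; identity/length fields are taken verbatim.
    """
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 14:
                continue
            q_len = int(f[idx["len_query"]])
            s_len = int(f[idx["len_subject"]])
            align_len = int(f[idx["alignment_length"]])
            nogap_col = idx.get("len_algn_minus_gaps_vs_len_query")
            align_len_nogap = (
                round(float(f[nogap_col]) * q_len) if nogap_col is not None
                else align_len
            )
            bit = float(f[idx["bit_score"]])
            hits.append(AlignmentHit(
                query_id=f[idx["Query_id"]],
                subject_id=f[idx["Subject_id"]],
                identity_pct=float(f[idx["identity"]]),
                align_len=align_len,
                align_len_nogap=align_len_nogap,
                mismatches=int(f[idx["mismatches"]]),
                gap_openings=int(f[idx["gap_openings"]]),
                q_start=int(f[idx["q_start"]]),
                q_end=int(f[idx["q_end"]]),
                s_start=int(f[idx["s_start"]]),
                s_end=int(f[idx["s_end"]]),
                q_len=q_len,
                s_len=s_len,
                score=(bit * math.log(2.0) + math.log(_KA_K)) / _KA_LAMBDA,
                bit_score=bit,
                evalue=float(f[idx["e-value"]]),
            ))
    return hits
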