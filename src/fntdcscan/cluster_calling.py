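"""Genome-wide FNTDC calling: collapse, test, select, emit.

For every master window the scanner computes the all-vs-all protein hits
once, then for every sub-window of the scheme collapses tandem groups at
the chosen stringency, runs the hypergeometric GO-BP test and records the
best (lowest-P) enriched term.  The sub-window with the overall lowest P
is the best approximation of the cluster's length and position; a call is
emitted iff that P passes the threshold.  At most one call per master
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping

from .enrichment import DEFAULT_MIN_COUNT, EnrichmentRow, enrich_window
from .genome_model import Gene, GeneCatalog
from .homology import (
    AlignmentHit,
    SETTINGS,
    TandemSetting,
    collapse,
    tandem_groups,
    window_hits,
)
from .scanning import (
    DEFAULT_MASTER_SIZE,
    MasterWindow,
    SubWindow,
    SubWindowScheme,
    enumerate_master_windows,
    enumerate_sub_windows,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FNTDCCall:
    """One called functional non-tandem-duplicated cluster."""

    ordinal: int
    name: str                      # "<firstGeneId>_TO_<lastGeneId>"
    chromosome: str
    span_start: int                # bp, 1-based inclusive
    span_end: int
    sub_window: SubWindow
    master: MasterWindow
    member_bp_genes: tuple[str, ...]       # GO-BP genes of the winning sub-window
    interspersed_genes: tuple[str, ...]    # span genes lacking GO-BP
    removed_tandem: tuple[str, ...]
    rows: tuple[EnrichmentRow, ...]        # all enriched terms, ascending P
    setting: TandemSetting
    p_threshold: float
    hits: tuple[AlignmentHit, ...] = ()    # master-window hits (for reports)

    @property
    def top_go(self) -> str:
        return self.rows[0].go_id

    @property
    def top_p(self) -> float:
        return self.rows[0].p_value

    @property
    def go_ids(self) -> tuple[str, ...]:
        return tuple(r.go_id for r in self.rows)


@dataclass(frozen=True)
class ScanConfig:
    """Everything that determines a scan run."""

    master_size: int = DEFAULT_MASTER_SIZE
    scheme: SubWindowScheme = field(default_factory=SubWindowScheme)
    setting: TandemSetting = SETTINGS["setting_2"]
    p_threshold: float = 1e-6
    min_count: int = DEFAULT_MIN_COUNT
    propagate_go: bool = False
    max_evalue: float = 10.0
    seed: int = 0  # reserved for randomized tie handling; unused by default

    def replace(self, **kw) -> "ScanConfig":
        return dc_replace(self, **kw)


def _window_span_genes(
    catalog: GeneCatalog, chromosome: str, first: Gene, last: Gene
) -> list[Gene]:
    return catalog.genes_in_span(chromosome, first.start, last.end)


def call_master_window(
    master: MasterWindow,
    catalog: GeneCatalog,
    config: ScanConfig,
    term_names: Mapping[str, str] | None = None,
    word_index: Mapping[str, frozenset[str]] | None = None,
) -> FNTDCCall | None:
    """Evaluate every sub-window of one master window; keep the best.

    Tie-break between sub-windows with the same minimal P: fewer genes,
    then smaller offset.  The P threshold is applied only after the best
    sub-window is selected.
    """
    bp_genes = catalog.bp_order[master.chromosome][
        master.bp_start_rank : master.bp_end_rank
    ]
    first, last = bp_genes[0], bp_genes[-1]
    # hits computed once per master window over every gene in its span
    span_genes = _window_span_genes(catalog, master.chromosome, first, last)
    hits = window_hits(span_genes, max_evalue=config.max_evalue,
                       word_index=word_index)

    best: tuple[float, int, int] | None = None
    best_result: tuple[SubWindow, list[Gene], list[str], list[EnrichmentRow]] | None = None
    for sub in enumerate_sub_windows(master, config.scheme):
        sub_genes = bp_genes[sub.offset : sub.offset + sub.length]
        groups = tandem_groups(sub_genes, hits, config.setting)
        retained, removed = collapse(sub_genes, groups)
        rows = enrich_window(
            retained, catalog, min_count=config.min_count,
            p_threshold=1.0, term_names=term_names,
        )
        if not rows:
            continue
        key = (rows[0].p_value, sub.length, sub.offset)
        if best is None or key < best:
            best = key
            best_result = (sub, retained, removed, rows)

    if best is None or best[0] > config.p_threshold:
        return None

    sub, retained, removed, rows = best_result
    kept_rows = tuple(r for r in rows if r.p_value <= config.p_threshold)
    win_genes = bp_genes[sub.offset : sub.offset + sub.length]
    w_first, w_last = win_genes[0], win_genes[-1]
    span_start = min(g.start for g in win_genes)
    span_end = max(g.end for g in win_genes)
    interspersed = tuple(
        g.gene_id
        for g in catalog.genes_in_span(master.chromosome, span_start, span_end)
        if not g.has_go_bp
    )
    return FNTDCCall(
        ordinal=0,  # assigned genome-wide by scan_genome
        name=f"{w_first.gene_id}_TO_{w_last.gene_id}",
        chromosome=master.chromosome,
        span_start=span_start,
        span_end=span_end,
        sub_window=sub,
        master=master,
        member_bp_genes=tuple(g.gene_id for g in win_genes),
        interspersed_genes=interspersed,
        removed_tandem=tuple(removed),
        rows=kept_rows,
        setting=config.setting,
        p_threshold=config.p_threshold,
        hits=tuple(hits),
    )


def scan_genome(
    catalog: GeneCatalog,
    config: ScanConfig | None = None,
    term_names: Mapping[str, str] | None = None,
) -> list[FNTDCCall]:
    """Scan every chromosome; return calls in chromosome/position order.

    Deterministic for identical inputs and config.  Ordinals run 1..n.
    """
    config = config or ScanConfig()
    # per-gene 5-mer word sets, shared across all master windows
    word_index: dict[str, frozenset[str]] = {}
    from .homology import _words  # local import to keep the cache private

    for g in catalog.all_genes():
        if g.protein:
            word_index[g.gene_id] = _words(g.protein.rstrip("*"))

    calls: list[FNTDCCall] = []
    masters = enumerate_master_windows(catalog, config.master_size)
    for master in masters:
        call = call_master_window(
            master, catalog, config, term_names=term_names,
            word_index=word_index,
        )
        if call is not None:
            calls.append(call)
    calls = [dc_replace(c, ordinal=i + 1) for i, c in enumerate(calls)]
    logger.info(
        "scanned %d master windows, %d FNTDC calls (%s, P<=%g)",
        len(masters), len(calls), config.setting.name, config.p_threshold,
    )
    return calls
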