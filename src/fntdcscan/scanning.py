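"""Master-window and sub-window enumeration over the GO-BP gene order.

The genome is scanned in consecutive, non-overlapping master windows of
24 GO-BP-assigned genes (gene *ranks*, not base pairs — gene density
varies too much across plant genomes for kb windows to compare across
species).  Inside each master window a discrete set of sub-windows is
probed for GO enrichment; the default scheme probes 13 sub-windows of
6–24 genes, the exhaustive scheme every contiguous sub-span down to a
minimum length (253 sub-windows for a 24-gene master at minimum 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome_model import GeneCatalog

logger = logging.getLogger(__name__)

DEFAULT_MASTER_SIZE = 24
MIN_SUB_DEFAULT = 6

# length → offsets; 1+2+3+3+4 = 13 sub-windows for a full 24-gene master,
# the master itself included as the length-24 entry.
DEFAULT_SCHEME_ENTRIES: tuple[tuple[int, tuple[int, ...]], ...] = (
    (24, (0,)),
    (18, (0, 6)),
    (12, (0, 6, 12)),
    (8, (0, 8, 16)),
    (6, (0, 6, 12, 18)),
)


@dataclass(frozen=True)
class MasterWindow:
    """A block of consecutive GO-BP genes on one chromosome.

    Ranks index the chromosome's bp_order, 0-based half-open.
    """

    chromosome: str
    bp_start_rank: int
    bp_end_rank: int

    @property
    def size(self) -> int:
        return self.bp_end_rank - self.bp_start_rank


@dataclass(frozen=True)
class SubWindow:
    """(offset, length) in genes relative to the master window start."""

    offset: int
    length: int


@dataclass(frozen=True)
class SubWindowScheme:
    mode: str = "default"  # "default" | "exhaustive"
    min_length: int = MIN_SUB_DEFAULT
    entries: tuple[tuple[int, tuple[int, ...]], ...] = DEFAULT_SCHEME_ENTRIES

    def __post_init__(self) -> None:
        if self.mode not in ("default", "exhaustive"):
            raise ValueError(f"unknown scheme mode {self.mode!r}")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")

    @staticmethod
    def exhaustive(min_length: int = 3) -> "SubWindowScheme":
        return SubWindowScheme(mode="exhaustive", min_length=min_length)


def enumerate_master_windows(
    catalog: GeneCatalog,
    master_size: int = DEFAULT_MASTER_SIZE,
    min_trailing: int = MIN_SUB_DEFAULT,
) -> list[MasterWindow]:
    """Tile each chromosome's GO-BP gene order with non-overlapping blocks.

    A trailing block shorter than ``master_size`` is kept if it still has
    at least ``min_trailing`` genes (otherwise dropped, with a log note).
    """
    if master_size < MIN_SUB_DEFAULT:
        raise ValueError(f"master_size must be >= {MIN_SUB_DEFAULT}")
    windows: list[MasterWindow] = []
    n_dropped = 0
    for chrom in catalog.chromosomes:
        n_bp = len(catalog.bp_order[chrom])
        if n_bp < min_trailing:
            if n_bp:
                n_dropped += 1
                logger.warning(
                    "chromosome %s has only %d GO-BP genes; no windows",
                    chrom, n_bp,
                )
            continue
        for start in range(0, n_bp, master_size):
            end = min(start + master_size, n_bp)
            if end - start >= min_trailing:
                windows.append(MasterWindow(chrom, start, end))
            else:
                n_dropped += 1
    if n_dropped:
        logger.info("dropped %d short trailing/undersized blocks", n_dropped)
    return windows


def enumerate_sub_windows(
    master: MasterWindow,
    scheme: SubWindowScheme | None = None,
) -> list[SubWindow]:
    """Sub-windows probed inside one master window, deterministic order.

    Default mode emits the fixed scheme clipped to the master size (any
    entry that would overrun a short trailing master is skipped);
    exhaustive mode emits every (offset, length) with
    min_length ≤ length ≤ master size.  Order: length descending, offset
    ascending.
    """
    scheme = scheme or SubWindowScheme()
    size = master.size
    subs: list[SubWindow] = []
    if scheme.mode == "default":
        for length, offsets in scheme.entries:
            if length > size:
                continue
            for off in offsets:
                if off + length <= size:
                    subs.append(SubWindow(off, length))
    else:
        for length in range(size, scheme.min_length - 1, -1):
            for off in range(0, size - length + 1):
                subs.append(SubWindow(off, length))
    subs.sort(key=lambda s: (-s.length, s.offset))
    return subs


def exhaustive_count(master_size: int, min_length: int) -> int:
    """Closed form for the exhaustive sub-window count: Σ (M−ℓ+1)."""
    return sum(master_size - length + 1
               for length in range(min_length, master_size + 1))
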