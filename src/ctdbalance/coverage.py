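"""ChIP tag post-processing and window quantification.

Tags are mapped-read 5′ positions. The operations here mirror the standard
promoter-quantification chain: duplicate filtering with a data-driven
multiplicity cap, strand-aware promoter/TES windows, half-open interval
counting, and per-10-million depth scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneModel

__all__ = [
    "TagSet",
    "GenomicWindow",
    "deduplicate",
    "promoter_window",
    "tes_window",
    "count_window",
    "count_windows",
    "scale_per_10M",
    "read_bed_tags",
    "write_bed_tags",
]


@dataclass
class TagSet:
    """A named collection of mapped-read 5′ positions with total depth.

    ``chroms``, ``positions`` and ``strands`` are parallel arrays; tags are
    kept sorted by (chrom, position) so that window counting can use binary
    search. ``total_mapped`` is the library depth used for scaling and is
    re-derived from the arrays at construction.
    """

    name: str
    chroms: np.ndarray
    positions: np.ndarray
    strands: np.ndarray
    total_mapped: int = field(init=False)

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype=object)
        if not (len(self.chroms) == len(self.positions) == len(self.strands)):
            raise ValueError("chroms, positions, strands must be equal length")
        if len(self.positions) and self.positions.min() < 0:
            raise ValueError("tag positions must be >= 0")
        order = np.lexsort((self.positions, self.chroms.astype(str)))
        self.chroms = self.chroms[order]
        self.positions = self.positions[order]
        self.strands = self.strands[order]
        self.total_mapped = len(self.positions)
        self._index: dict | None = None

    def __len__(self) -> int:
        return len(self.positions)

    def by_chrom(self) -> dict:
        """chrom -> (positions, strands), positions sorted ascending."""
        if self._index is None:
            idx = {}
            if len(self.positions):
                chroms = self.chroms.astype(str)
                bounds = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
                starts = np.concatenate(([0], bounds))
                ends = np.concatenate((bounds, [len(chroms)]))
                for s, e in zip(starts, ends):
                    idx[chroms[s]] = (self.positions[s:e], self.strands[s:e])
            self._index = idx
        return self._index

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame) -> "TagSet":
        return cls(name, df["chrom"].to_numpy(), df["pos"].to_numpy(), df["strand"].to_numpy())


@dataclass(frozen=True)
class GenomicWindow:
    """A half-open genomic interval carrying a transcription orientation.

    The orientation never changes the extent of the window; it is used only
    to flip per-bin profiles into 5′→3′ order.
    """

    chrom: str
    start: int
    end: int
    orientation: str = "+"
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def _multiplicities(tags: TagSet) -> tuple[np.ndarray, np.ndarray]:
    """Unique (chrom, pos, strand) keys and their multiplicities."""
    keys = np.array(
        [f"{c}\t{p}\t{s}" for c, p, s in zip(tags.chroms, tags.positions, tags.strands)],
        dtype=object,
    )
    uniq, counts = np.unique(keys, return_counts=True)
    return uniq, counts


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (no interpolation): the ceil(q/100*n)-th order statistic."""
    values = np.sort(np.asarray(values))
    n = len(values)
    if n == 0:
        raise ValueError("empty distribution")
    k = max(1, math.ceil(q / 100.0 * n))
    return float(values[k - 1])


def deduplicate(tags: TagSet, drop_stacks: bool = False) -> tuple[TagSet, int]:
    """Cap per-position tag multiplicity at the 95th percentile threshold.

    The threshold ``t`` is the nearest-rank 95th percentile of the
    multiplicity distribution over occupied (chrom, position, strand) sites,
    rounded up to an integer. Stacks deeper than ``t`` are capped at ``t``
    (or removed entirely when ``drop_stacks`` is set).
    """
    if len(tags) == 0:
        raise ValueError("cannot deduplicate an empty TagSet")
    chrom_codes, chrom_levels = pd.factorize(tags.chroms.astype(str))
    strand_codes = (tags.strands.astype(str) == "-").astype(np.int64)
    keys = (chrom_codes.astype(np.int64) << 36) | (tags.positions << 1) | strand_codes
    uniq, counts = np.unique(keys, return_counts=True)
    t = int(math.ceil(nearest_rank_percentile(counts, 95.0)))
    keep = np.where(drop_stacks & (counts > t), 0, np.minimum(counts, t))
    kept = np.repeat(uniq, keep)
    out_c = chrom_levels[(kept >> 36)].astype(object)
    out_p = (kept >> 1) & ((1 << 35) - 1)
    out_s = np.where(kept & 1, "-", "+").astype(object)
    return TagSet(tags.name, out_c, out_p, out_s), t


def promoter_window(gene: GeneModel, half_width: int = 1000) -> GenomicWindow:
    """Promoter window [tss - half_width, tss + half_width), clipped at 0."""
    start = gene.tss - half_width
    end = gene.tss + half_width
    clipped = start < 0
    if clipped:
        warnings.warn(f"{gene.gene_id}: promoter window clipped at chromosome start")
        start = 0
    return GenomicWindow(gene.chrom, start, end, gene.strand, clipped)


def tes_window(gene: GeneModel, length: int = 2000) -> GenomicWindow:
    """Window of ``length`` bp immediately downstream of the TES (strand-aware)."""
    if gene.strand == "+":
        start, end = gene.tes, gene.tes + length
    else:
        start, end = gene.tes - length, gene.tes
    clipped = start < 0
    if clipped:
        warnings.warn(f"{gene.gene_id}: TES window clipped at chromosome start")
        start = 0
    return GenomicWindow(gene.chrom, start, end, gene.strand, clipped)


def count_window(tags: TagSet, window: GenomicWindow, strand: str | None = None) -> int:
    """Number of tags with 5′ position in [start, end); optionally one strand only."""
    idx = tags.by_chrom().get(window.chrom)
    if idx is None:
        return 0
    pos, strands = idx
    lo = np.searchsorted(pos, window.start, side="left")
    hi = np.searchsorted(pos, window.end, side="left")
    if strand is None:
        return int(hi - lo)
    return int(np.sum(strands[lo:hi] == strand))


def count_windows(tags: TagSet, windows: list[GenomicWindow]) -> np.ndarray:
    """Vectorized :func:`count_window` over a window list."""
    return np.array([count_window(tags, w) for w in windows], dtype=np.int64)


def scale_per_10M(count: float, total_mapped: int) -> float:
    """Scale a window count by 10 million over the library's mapped-tag total."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return count * 1e7 / total_mapped


def read_bed_tags(path, name: str | None = None) -> TagSet:
    """Read tags from 6-column BED (start is the 5′ position; end is ignored)."""
    chroms, positions, strands = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chroms.append(f[0])
            positions.append(int(f[1]))
            strands.append(f[5] if len(f) > 5 else "+")
    return TagSet(
        name or str(path),
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(strands, dtype=object),
    )


def write_bed_tags(tags: TagSet, path) -> None:
    """Write tags as 6-column BED (chrom, start, start+1, name, score, strand)."""
    with open(path, "w") as fh:
        for i, (c, p, s) in enumerate(zip(tags.chroms, tags.positions, tags.strands)):
            fh.write(f"{c}\t{p}\t{p + 1}\t{tags.name}_{i}\t0\t{s}\n")
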