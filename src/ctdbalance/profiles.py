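"""Metagene profiles, promoter heatmap matrices and GRO-seq window coverage.

Depth is defined as tag 5′-position counts per bin (no fragment extension);
an optional extension length smears each tag uniformly downstream when
fragment-style coverage is wanted. Rows of every matrix run 5′ -> 3′ in
transcription orientation (− strand genes are flipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import TagSet, count_window, GenomicWindow
from .genes import GeneModel

__all__ = [
    "ProfileMatrix",
    "metagene_profile",
    "heatmap_matrix",
    "groseq_windows",
    "groseq_rpkm",
    "fpkm_log",
]


@dataclass
class ProfileMatrix:
    """Gene x bin matrix anchored at TSS or TES, with optional per-row z-scores."""

    genes: list
    bin_size: int
    span: tuple  # (upstream bp, downstream bp), transcription orientation
    values: np.ndarray
    anchor: str = "TSS"
    zscored: bool = False

    def to_frame(self) -> pd.DataFrame:
        up, down = self.span
        centers = np.arange(-up, down, self.bin_size) + self.bin_size / 2
        return pd.DataFrame(self.values, index=self.genes, columns=centers)


def _window_counts(tags: TagSet, gene: GeneModel, anchor_pos: int, up: int, down: int,
                   bin_size: int, extend: int = 0) -> np.ndarray:
    """Per-bin tag counts around an anchor, flipped to transcription orientation."""
    n_bins = (up + down) // bin_size
    idx = tags.by_chrom().get(gene.chrom)
    if idx is None:
        return np.zeros(n_bins)
    pos = idx[0]
    s = 1 if gene.strand == "+" else -1
    if s == 1:
        lo, hi = anchor_pos - up, anchor_pos + down
    else:
        lo, hi = anchor_pos - down + 1, anchor_pos + up + 1
    if extend <= 0:
        a = np.searchsorted(pos, lo, side="left")
        b = np.searchsorted(pos, hi, side="left")
        rel = s * (pos[a:b] - anchor_pos) + up  # 0 .. up+down-1
        rel = rel[(rel >= 0) & (rel < up + down)]
        counts = np.bincount(rel // bin_size, minlength=n_bins)[:n_bins]
        return counts.astype(float)
    # fragment extension: each tag covers [p, p+extend) in transcription direction
    a = np.searchsorted(pos, lo - extend, side="left")
    b = np.searchsorted(pos, hi + extend, side="left")
    counts = np.zeros(n_bins)
    for p in pos[a:b]:
        rel = s * (p - anchor_pos) + up
        for r in range(max(0, rel), min(up + down, rel + extend)):
            counts[r // bin_size] += 1.0 / 1.0
    return counts


def metagene_profile(
    tags: TagSet,
    genes: list[GeneModel],
    anchor: str = "TSS",
    span: int = 5000,
    bin_size: int = 10,
    extend: int = 0,
) -> np.ndarray:
    """Average per-bin depth across genes in a window centered on TSS or TES."""
    if not genes:
        raise ValueError("empty gene set")
    half = span // 2
    rows = []
    for g in genes:
        pos = g.tss if anchor.upper() == "TSS" else g.tes
        rows.append(_window_counts(tags, g, pos, half, half, bin_size, extend))
    return np.mean(rows, axis=0)


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    """Per-row z-scores with sample (n-1) sd; constant rows map to zeros."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(values, dtype=float)
    np.divide(values - mu, sd, out=out, where=sd > 0)
    return out


def heatmap_matrix(
    tags: TagSet,
    genes: list[GeneModel],
    window: tuple = (500, 500),
    bin_size: int = 5,
    order_by: pd.Series | None = None,
    zscore: bool = True,
    extend: int = 0,
) -> ProfileMatrix:
    """Promoter heatmap matrix with per-gene (row) z-scores.

    ``window`` is (upstream, downstream) of the TSS in transcription
    orientation; the elongation mark conventionally uses (500, 1000). When
    ``order_by`` is given (e.g. the K7me2/K7ac ratio), rows are sorted by it
    from highest to lowest.
    """
    if order_by is not None:
        order = order_by.reindex([g.gene_id for g in genes]).sort_values(ascending=False).index
        gmap = {g.gene_id: g for g in genes}
        genes = [gmap[i] for i in order]
    up, down = window
    raw = np.array([_window_counts(tags, g, g.tss, up, down, bin_size, extend) for g in genes])
    values = _zscore_rows(raw) if zscore else raw
    return ProfileMatrix([g.gene_id for g in genes], bin_size, (up, down), values, "TSS", zscore)


def groseq_windows(
    tags: TagSet,
    genes: list[GeneModel],
    window: tuple = (500, 1000),
    bin_size: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sense and antisense promoter-window coverage matrices for stranded tags.

    Sense tags match the gene strand; antisense tags oppose it. Windows run
    -upstream..+downstream of the TSS at ``bin_size`` resolution.
    """
    up, down = window
    n_bins = (up + down) // bin_size
    sense_rows, anti_rows = [], []
    for g in genes:
        idx = tags.by_chrom().get(g.chrom)
        srow = np.zeros(n_bins)
        arow = np.zeros(n_bins)
        if idx is not None:
            pos, strands = idx
            s = 1 if g.strand == "+" else -1
            lo = g.tss - (up if s == 1 else down - 1)
            hi = g.tss + (down if s == 1 else up + 1)
            a = np.searchsorted(pos, lo, side="left")
            b = np.searchsorted(pos, hi, side="left")
            rel = s * (pos[a:b] - g.tss) + up
            ok = (rel >= 0) & (rel < up + down)
            rel = rel[ok]
            same = strands[a:b][ok] == g.strand
            if rel.size:
                srow = np.bincount(rel[same] // bin_size, minlength=n_bins)[:n_bins].astype(float)
                arow = np.bincount(rel[~same] // bin_size, minlength=n_bins)[:n_bins].astype(float)
        sense_rows.append(srow)
        anti_rows.append(arow)
    ids = [g.gene_id for g in genes]
    centers = np.arange(-up, down, bin_size) + bin_size / 2
    return (
        pd.DataFrame(sense_rows, index=ids, columns=centers),
        pd.DataFrame(anti_rows, index=ids, columns=centers),
    )


def groseq_rpkm(tags: TagSet, gene: GeneModel, sense_only: bool = True) -> float:
    """RPKM over TSS..TES: count * 1e9 / (gene length * total mapped tags)."""
    if gene.length <= 0:
        raise ValueError("zero-length gene")
    lo, hi = min(gene.start, gene.end), max(gene.start, gene.end)
    w = GenomicWindow(gene.chrom, lo, hi, gene.strand)
    c = count_window(tags, w, strand=gene.strand if sense_only else None)
    return c * 1e9 / (gene.length * tags.total_mapped)


def fpkm_log(fpkm) -> np.ndarray | float:
    """log10(FPKM + 1e-4): the pseudocount keeps silent genes at -4."""
    arr = np.asarray(fpkm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("FPKM must be >= 0")
    out = np.log10(arr + 1e-4)
    return float(out) if np.isscalar(fpkm) or arr.ndim == 0 else out
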