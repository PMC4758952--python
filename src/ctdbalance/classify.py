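"""Promoter positivity per mark, exclusion rules, and gene-class assignment.

A promoter is positive for a mark when (a) its 2 kb TSS window intersects a
region called enriched for that mark and (b) its window read count exceeds
the 10th percentile (nearest rank) of counts among region-overlapping
promoters (the 10% tail cut). Positive promoters whose TSS windows overlap
other positive TSS windows for the same mark are excluded (both set to NA);
positive genes lying inside other positive genes are excluded (internal
gene only). Classes:

- active:   S5p+, S7p+, S2p+ (TES window), FPKM > 1, H3K27me3-, H2Aub1-
- PRCr:     H3K27me3+, H2Aub1+, S5p+; 8WG16- and S2p- (TES)
- inactive: negative for all of H3K27me3, H2Aub1, S5p, S2p, 8WG16
- NA:       anything else (including exclusion-rule casualties)
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .coverage import GenomicWindow, nearest_rank_percentile, promoter_window
from .genes import GeneModel
from .peaks import BinnedTrack, EnrichedRegionSet

__all__ = [
    "classify_promoters",
    "max_peak_offset",
    "assign_gene_classes",
    "balanced_accuracy",
]


def _region_index(regions: EnrichedRegionSet) -> dict:
    """chrom -> (starts, ends) sorted by start, for binary-search overlap."""
    by_chrom: dict = {}
    for c, s, e, _ in regions.regions:
        by_chrom.setdefault(c, []).append((s, e))
    out = {}
    for c, ivs in by_chrom.items():
        ivs.sort()
        out[c] = (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
    return out


def _window_overlaps(index: dict, window: GenomicWindow) -> bool:
    if window.chrom not in index:
        return False
    starts, ends = index[window.chrom]
    i = np.searchsorted(starts, window.end, side="left")
    # regions are sorted and non-overlapping: only the predecessor can reach in
    return bool(i > 0 and ends[i - 1] > window.start)


def classify_promoters(
    genes: list[GeneModel],
    regions: EnrichedRegionSet,
    counts: dict | pd.Series,
    windows: dict | None = None,
    percentile: float = 10.0,
    percentile_population: str = "overlapping",
) -> pd.DataFrame:
    """Promoter status for one mark: positive / negative / NA per gene.

    ``counts`` maps gene_id -> promoter window count for this mark.
    ``windows`` optionally supplies the per-gene window (e.g. the post-TES
    window for the elongation mark); default is the 2 kb promoter window.
    ``percentile_population`` chooses the population over which the 10% tail
    cut is computed: "overlapping" (region-overlapping promoters, default)
    or "all".
    """
    if not genes:
        return pd.DataFrame(
            columns=["mark", "status", "promoter_count", "passed_region_overlap", "passed_percentile"]
        )
    counts = pd.Series(counts)
    win = {g.gene_id: (windows[g.gene_id] if windows else promoter_window(g)) for g in genes}
    ridx = _region_index(regions)
    overlap = {g.gene_id: _window_overlaps(ridx, win[g.gene_id]) for g in genes}

    pop = [
        float(counts[g.gene_id])
        for g in genes
        if overlap[g.gene_id] or percentile_population == "all"
    ]
    cut = nearest_rank_percentile(np.array(pop), percentile) if pop else math.inf

    rows = {}
    for g in genes:
        c = float(counts[g.gene_id])
        ok_overlap = overlap[g.gene_id]
        ok_pct = c > cut
        status = "positive" if (ok_overlap and ok_pct) else "negative"
        rows[g.gene_id] = {
            "mark": regions.mark,
            "status": status,
            "promoter_count": c,
            "passed_region_overlap": ok_overlap,
            "passed_percentile": ok_pct,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"

    # exclusion rules operate among positive genes only
    pos_ids = [g.gene_id for g in genes if df.loc[g.gene_id, "status"] == "positive"]
    pos = [g for g in genes if g.gene_id in set(pos_ids)]
    excluded = set()
    for i, a in enumerate(pos):
        wa = win[a.gene_id]
        for b in pos[i + 1 :]:
            wb = win[b.gene_id]
            if wa.chrom == wb.chrom and wa.start < wb.end and wb.start < wa.end:
                excluded.add(a.gene_id)
                excluded.add(b.gene_id)
    for a in pos:  # containment: only the internal gene is removed
        for b in pos:
            if a is b or a.chrom != b.chrom:
                continue
            if b.start <= a.start and a.end <= b.end:
                excluded.add(a.gene_id)
    df.loc[sorted(excluded), "status"] = "NA"
    return df


def max_peak_offset(track: BinnedTrack, gene: GeneModel) -> float | None:
    """Signed offset (bp, transcription orientation) of the track's maximum
    from the TSS. Ties are broken toward the TSS (smallest magnitude), and a
    symmetric up/downstream tie resolves downstream (positive offset).
    None if the track is all zero."""
    if track.bin_size > 10:
        warnings.warn("max_peak_offset expects a fine-binned track (<= 10 bp bins)")
    c = track.counts
    if c.max() == 0:
        return None
    centers = track.offset + (np.arange(len(c)) + 0.5) * track.bin_size
    s = 1 if gene.strand == "+" else -1
    offsets = s * (centers - gene.tss)
    at_max = offsets[c == c.max()]
    best = min(at_max, key=lambda o: (abs(o), -o))
    return float(best)


def assign_gene_classes(
    statuses: pd.DataFrame,
    fpkm: pd.Series,
    peak_offsets: pd.Series | None = None,
    promoter_overlaps: pd.Series | None = None,
    anchor_tolerance: float = 50.0,
    top_frac: float = 0.15,
) -> pd.DataFrame:
    """Assign active / PRCr / inactive / NA classes and cohort flags.

    ``statuses``: gene x mark frame of {positive, negative, NA}; must contain
    S5p, S7p, S2p (TES window), 8WG16, H3K27me3, H2Aub1. ``peak_offsets`` is
    the signed 8WG16 max-peak offset (NaN when undefined); genes whose
    offset magnitude exceeds ``anchor_tolerance`` are dropped from the
    TSS-anchored cohort. ``promoter_overlaps`` flags genes whose promoter
    window overlaps another gene's promoter (excluded from both active
    cohorts). top15/bottom15 are FPKM-rank cohorts among polycomb-negative
    genes.
    """
    required = ["S5p", "S7p", "S2p", "8WG16", "H3K27me3", "H2Aub1"]
    missing = [m for m in required if m not in statuses.columns]
    if missing:
        warnings.warn(f"missing mark status columns {missing}; affected genes set to NA")
    idx = statuses.index
    fpkm = fpkm.reindex(idx)

    def is_pos(mark):
        if mark not in statuses.columns:
            return pd.Series(False, index=idx)
        return statuses[mark] == "positive"

    def is_neg(mark):
        if mark not in statuses.columns:
            return pd.Series(False, index=idx)
        return statuses[mark] == "negative"

    active = (
        is_pos("S5p") & is_pos("S7p") & is_pos("S2p")
        & (fpkm > 1)
        & is_neg("H3K27me3") & is_neg("H2Aub1")
    )
    prcr = (
        is_pos("H3K27me3") & is_pos("H2Aub1") & is_pos("S5p")
        & is_neg("8WG16") & is_neg("S2p")
    )
    inactive = (
        is_neg("H3K27me3") & is_neg("H2Aub1") & is_neg("S5p")
        & is_neg("S2p") & is_neg("8WG16")
    )
    cls = pd.Series("NA", index=idx, name="gene_class")
    cls[inactive] = "inactive"
    cls[prcr] = "PRCr"
    cls[active] = "active"

    if promoter_overlaps is None:
        promoter_overlaps = pd.Series(False, index=idx)
    nonoverlapping = active & ~promoter_overlaps.reindex(idx).fillna(False).astype(bool)
    if peak_offsets is not None:
        off = peak_offsets.reindex(idx)
        anchored = nonoverlapping & off.notna() & (off.abs() <= anchor_tolerance)
    else:
        anchored = pd.Series(False, index=idx)

    polycomb_neg = is_neg("H3K27me3") & is_neg("H2Aub1")
    pool = fpkm[polycomb_neg].dropna()
    k = int(math.floor(top_frac * len(pool)))
    top_ids = pool.nlargest(k).index if k else []
    bot_ids = pool.nsmallest(k).index if k else []

    out = pd.DataFrame(
        {
            "gene_class": cls,
            "nonoverlapping_active": nonoverlapping,
            "tss_anchored_active": anchored,
            "top15": pd.Series(idx.isin(top_ids), index=idx),
            "bottom15": pd.Series(idx.isin(bot_ids), index=idx),
        }
    )
    out.index.name = "gene_id"
    return out


def balanced_accuracy(
    truth: pd.Series, predicted: pd.Series, classes=("active", "inactive"),
    count_na: bool = False,
) -> float:
    """Balanced accuracy of class recovery between two class labelings.

    By default genes the classifier abstained on (predicted NA or any label
    outside ``classes``) are excluded from each class's recall — NA is a
    no-call, not a miscall. With ``count_na=True`` abstentions count as
    errors.
    """
    truth, predicted = truth.align(predicted, join="inner")
    recalls = []
    for c in classes:
        in_class = truth == c
        if in_class.sum() == 0:
            continue
        if count_na:
            recalls.append((predicted[in_class] == c).mean())
        else:
            called = in_class & predicted.isin(classes)
            if called.sum() == 0:
                continue
            recalls.append((predicted[called] == c).mean())
    if not recalls:
        raise ValueError("no genes in the requested classes")
    return float(np.mean(recalls))
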