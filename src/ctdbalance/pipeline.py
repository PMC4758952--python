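"""End-to-end pipeline: simulate -> dedup -> peaks -> classify -> quantify
-> ratio -> associate, with plain-file (BED/TSV) handoff between stages.

Every stage is deterministic given the run configuration; outputs carry a
provenance header (parameters and input checksums, no timestamps) so that
identical configs give byte-identical run directories. Stages read cached
upstream outputs from the run directory when re-run individually.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, classify, profiles, ratios, synthetic
from .coverage import (
    TagSet,
    count_window,
    deduplicate,
    promoter_window,
    read_bed_tags,
    scale_per_10M,
    tes_window,
    write_bed_tags,
)
from .genes import GeneModel, read_gene_tables, write_gene_tables
from .peaks import (
    EnrichedRegionSet,
    SegmentationPrior,
    bin_tags,
    call_enriched_regions,
    read_regions_bed,
    write_regions_bed,
)

logger = logging.getLogger("ctdbalance")

__all__ = ["RunConfig", "run_pipeline", "quantify_marks", "call_all_regions",
           "classify_genes", "peak_offsets_8wg16"]

CLASSIFICATION_MARKS = ["S5p", "S7p", "S2p", "8WG16", "H3K27me3", "H2Aub1"]
RATIO_MARKS = ["K7me1", "K7me2", "K7ac"]
ALL_STAGES = ["simulate", "dedup", "callpeaks", "classify", "profiles", "ratio", "assoc"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run (fully serialized into the run log)."""

    outdir: str = "ctdbalance_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    synthetic: synthetic.SyntheticConfig | None = None
    promoter_half_width: int = 1000
    tes_window_length: int = 2000
    bin_size: int = 200
    fold_threshold: float = 2.0
    percentile_cut: float = 10.0
    percentile_population: str = "overlapping"
    max_block_bins: int = 100
    lasso_folds: int = 10
    subset_max_size: int = 5

    def __post_init__(self):
        if self.synthetic is None:
            self.synthetic = synthetic.SyntheticConfig(seed=self.seed)
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        if not 0 < self.percentile_cut < 100:
            raise ValueError("percentile_cut must be in (0, 100)")
        if self.bin_size <= 0 or self.fold_threshold <= 0:
            raise ValueError("bin_size and fold_threshold must be positive")

    def to_flat(self) -> dict:
        d = asdict(self)
        d.pop("synthetic")
        # outdir and the stage subset are run metadata, not content parameters:
        # cached-stage reruns must reproduce downstream files byte-identically
        flat = {k: v for k, v in d.items() if k not in ("stages", "outdir")}
        for k, v in self.synthetic.to_flat().items():
            flat[f"synthetic.{k}"] = v
        return flat


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _provenance(config: RunConfig, inputs: list[Path]) -> str:
    lines = [f"# {k}={v}" for k, v in sorted(config.to_flat().items())]
    lines += [f"# input:{p.name}={_checksum(p)}" for p in inputs]
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, inputs=()):
    with open(path, "w") as fh:
        fh.write(_provenance(config, list(inputs)))
        df.to_csv(fh, sep="\t", float_format="%.6g")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def quantify_marks(
    genes: list[GeneModel],
    tagsets: dict[str, TagSet],
    promoter_half_width: int = 1000,
    tes_window_length: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw and depth-scaled window counts per gene and mark.

    Promoter windows for all marks except the elongation mark S2p, which is
    counted in the post-TES window (its column is still named "S2p").
    """
    ids = [g.gene_id for g in genes]
    raw = pd.DataFrame(index=pd.Index(ids, name="gene_id"))
    scaled = pd.DataFrame(index=pd.Index(ids, name="gene_id"))
    for mark, ts in tagsets.items():
        if mark == "S2p":
            wins = [tes_window(g, tes_window_length) for g in genes]
        else:
            wins = [promoter_window(g, promoter_half_width) for g in genes]
        counts = np.array([count_window(ts, w) for w in wins], dtype=float)
        raw[mark] = counts
        scaled[mark] = [scale_per_10M(c, ts.total_mapped) for c in counts]
    return raw, scaled


def call_all_regions(
    tagsets: dict[str, TagSet],
    control_name: str = "mock",
    bin_size: int = 200,
    fold_threshold: float = 2.0,
    max_block: int | None = 100,
    span: tuple[int, int] | None = None,
    marks: list[str] | None = None,
) -> dict[str, EnrichedRegionSet]:
    """Enriched regions per mark against the shared control track."""
    control = tagsets[control_name]
    prior = SegmentationPrior(max_block=max_block)
    out = {}
    for mark, ts in tagsets.items():
        if mark == control_name or (marks is not None and mark not in marks):
            continue
        if len(ts) == 0:
            out[mark] = EnrichedRegionSet(mark)
            continue
        out[mark] = call_enriched_regions(
            ts, control, bin_size=bin_size, fold_threshold=fold_threshold,
            prior=prior, span=span, mark=mark,
        )
    return out


def peak_offsets_8wg16(
    tags: TagSet, genes: list[GeneModel], half_width: int = 500, bin_size: int = 5
) -> pd.Series:
    """Signed 8WG16 max-peak offset from the TSS per gene (NaN if no signal)."""
    vals = {}
    for g in genes:
        span = (max(0, g.tss - half_width), g.tss + half_width)
        track = bin_tags(tags, bin_size, chrom=g.chrom, span=span)
        off = classify.max_peak_offset(track, g)
        vals[g.gene_id] = np.nan if off is None else off
    return pd.Series(vals, name="peak_offset")


def _promoter_overlap_flags(genes: list[GeneModel], half_width: int) -> pd.Series:
    wins = sorted(
        ((g.chrom, *(lambda w: (w.start, w.end))(promoter_window(g, half_width)), g.gene_id) for g in genes),
        key=lambda t: (t[0], t[1]),
    )
    flags = {g.gene_id: False for g in genes}
    for (c1, s1, e1, id1), (c2, s2, e2, id2) in zip(wins, wins[1:]):
        if c1 == c2 and s2 < e1:
            flags[id1] = flags[id2] = True
    return pd.Series(flags)


def classify_genes(
    genes: list[GeneModel],
    regions: dict[str, EnrichedRegionSet],
    raw_counts: pd.DataFrame,
    fpkm: pd.Series,
    peak_offsets: pd.Series | None = None,
    promoter_half_width: int = 1000,
    tes_window_length: int = 2000,
    percentile: float = 10.0,
    percentile_population: str = "overlapping",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mark promoter statuses and the gene-class table."""
    statuses = {}
    for mark, regs in regions.items():
        if mark == "S2p":
            wins = {g.gene_id: tes_window(g, tes_window_length) for g in genes}
        else:
            wins = {g.gene_id: promoter_window(g, promoter_half_width) for g in genes}
        st = classify.classify_promoters(
            genes, regs, raw_counts[mark], windows=wins,
            percentile=percentile, percentile_population=percentile_population,
        )
        statuses[mark] = st["status"]
    statuses = pd.DataFrame(statuses)
    overlaps = _promoter_overlap_flags(genes, promoter_half_width)
    classes = classify.assign_gene_classes(
        statuses, fpkm, peak_offsets=peak_offsets, promoter_overlaps=overlaps
    )
    return statuses, classes


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages into the run directory; returns its path."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic
    run_log: dict = {}

    def stage_on(name):
        return name in config.stages

    current_stage = "setup"
    try:
        # ---- simulate -------------------------------------------------
        current_stage = "simulate"
        if stage_on("simulate"):
            logger.info("stage simulate")
            genes = synthetic.generate_genes(syn)
            tagsets = synthetic.generate_tags(genes, syn, run_log)
            fpkm_table, groseq, tsa = synthetic.generate_expression(genes, syn)
            write_gene_tables(genes, out / "genes.bed12", out / "genes_attrs.tsv")
            for mark, ts in tagsets.items():
                write_bed_tags(ts, out / f"tags_{mark}.bed")
            write_bed_tags(groseq, out / "tags_GROseq.bed")
            _write_tsv(fpkm_table, out / "fpkm.tsv", config)
            _write_tsv(tsa, out / "tsa_foldchange.tsv", config)
            with open(out / "config.txt", "w") as fh:
                for k, v in sorted(config.to_flat().items()):
                    fh.write(f"{k}={v}\n")
        genes = read_gene_tables(out / "genes.bed12", out / "genes_attrs.tsv")
        fpkm = _read_tsv(out / "fpkm.tsv")["fpkm"]
        marks = [m for m in syn.profile_params]

        # ---- dedup ----------------------------------------------------
        current_stage = "dedup"
        if stage_on("dedup"):
            logger.info("stage dedup")
            thresholds = {}
            for mark in marks:
                ts = read_bed_tags(out / f"tags_{mark}.bed", mark)
                if len(ts) == 0:
                    dd, t = ts, 0
                else:
                    dd, t = deduplicate(ts)
                thresholds[mark] = {"threshold": t, "total_before": len(ts), "total_after": len(dd)}
                write_bed_tags(dd, out / f"dedup_{mark}.bed")
            _write_tsv(
                pd.DataFrame(thresholds).T.rename_axis("mark"),
                out / "dedup_thresholds.tsv", config,
            )
        dedup_sets = {m: read_bed_tags(out / f"dedup_{m}.bed", m) for m in marks}

        # ---- callpeaks ------------------------------------------------
        span = (0, syn.chrom_length)
        current_stage = "callpeaks"
        if stage_on("callpeaks"):
            logger.info("stage callpeaks")
            regions = call_all_regions(
                dedup_sets, bin_size=config.bin_size,
                fold_threshold=config.fold_threshold,
                max_block=config.max_block_bins, span=span,
            )
            for mark, regs in regions.items():
                write_regions_bed(regs, out / f"regions_{mark}.bed")
        regions = {
            m: read_regions_bed(out / f"regions_{m}.bed", m)
            for m in marks if m != "mock"
        }

        raw_counts, scaled_counts = quantify_marks(
            genes, dedup_sets, config.promoter_half_width, config.tes_window_length
        )

        # ---- classify -------------------------------------------------
        current_stage = "classify"
        if stage_on("classify"):
            logger.info("stage classify")
            offsets = peak_offsets_8wg16(dedup_sets["8WG16"], genes)
            statuses, classes = classify_genes(
                genes, regions, raw_counts, fpkm, peak_offsets=offsets,
                promoter_half_width=config.promoter_half_width,
                tes_window_length=config.tes_window_length,
                percentile=config.percentile_cut,
                percentile_population=config.percentile_population,
            )
            _write_tsv(statuses, out / "promoter_status.tsv", config)
            _write_tsv(classes, out / "gene_classes.tsv", config)
        classes = _read_tsv(out / "gene_classes.tsv")

        # ---- profiles -------------------------------------------------
        current_stage = "profiles"
        if stage_on("profiles"):
            logger.info("stage profiles")
            _write_tsv(raw_counts, out / "raw_counts.tsv", config)
            _write_tsv(scaled_counts, out / "scaled_counts.tsv", config)
            active = [g for g in genes if classes.loc[g.gene_id, "gene_class"] == "active"]
            if active:
                prof = {}
                for mark in ("K7me1", "K7me2", "K7ac", "S5p", "S7p", "8WG16"):
                    prof[mark] = profiles.metagene_profile(dedup_sets[mark], active, "TSS")
                prof["S2p_TES"] = profiles.metagene_profile(dedup_sets["S2p"], active, "TES")
                centers = np.arange(-2500, 2500, 10) + 5
                _write_tsv(
                    pd.DataFrame(prof, index=pd.Index(centers, name="offset_bp")),
                    out / "metagene_profiles.tsv", config,
                )

        # ---- ratio ----------------------------------------------------
        current_stage = "ratio"
        if stage_on("ratio"):
            logger.info("stage ratio")
            active_ids = classes.index[classes["gene_class"] == "active"]
            rt = ratios.ratio_table(
                raw_counts.loc[active_ids, "K7me2"],
                raw_counts.loc[active_ids, "K7ac"],
                dedup_sets["K7me2"].total_mapped,
                dedup_sets["K7ac"].total_mapped,
            )
            rt["fpkm_log"] = profiles.fpkm_log(fpkm.loc[active_ids])
            _write_tsv(rt, out / "ratio_table.tsv", config)
            tsa = _read_tsv(out / "tsa_foldchange.tsv")["fold_change"]
            report = []
            try:
                cont = ratios.tsa_contingency(tsa, rt["quantile"])
                report.append(f"tsa_table=[[{cont.table[0,0]},{cont.table[0,1]}],[{cont.table[1,0]},{cont.table[1,1]}]]")
                report.append(f"tsa_fisher_p={cont.p_two_sided:.6g}")
                report.append(f"tsa_odds_ratio={cont.odds_ratio:.6g}")
            except ValueError as err:
                report.append(f"tsa_fisher_p=NA ({err})")
            for a, b in (("high", "low"), ("high", "medium"), ("medium", "low")):
                va = rt.loc[rt["quantile"] == a, "fpkm_log"]
                vb = rt.loc[rt["quantile"] == b, "fpkm_log"]
                if len(va) and len(vb):
                    p = ratios.wilcoxon_rank_sum(va, vb)
                    report.append(f"wilcoxon_mRNA_{a}_vs_{b}={p:.6g}")
            (out / "ratio_tests.txt").write_text(
                _provenance(config, []) + "\n".join(report) + "\n"
            )

        # ---- assoc ----------------------------------------------------
        current_stage = "assoc"
        if stage_on("assoc"):
            logger.info("stage assoc")
            active_ids = classes.index[classes["gene_class"] == "active"]
            mrna = pd.Series(
                profiles.fpkm_log(fpkm.loc[active_ids]), index=active_ids, name="mRNA"
            )
            cpg = pd.Series({g.gene_id: g.cpg for g in genes}).loc[active_ids]
            cpg.name = "CpG"
            table = assoc.build_mark_table(
                scaled_counts.loc[active_ids], mrna=mrna, cpg=cpg
            )
            model = assoc.CTDMarkModel(table, response="S2p")
            res = model.fit(seed=config.seed, folds=config.lasso_folds,
                            max_size=config.subset_max_size)
            _write_tsv(res.spearman, out / "assoc_spearman.tsv", config)
            _write_tsv(res.partial_correlations, out / "assoc_partial.tsv", config)
            _write_tsv(res.subset_table, out / "assoc_subsets.tsv", config)
            _write_tsv(res.lasso.coefficients.to_frame(), out / "assoc_lasso.tsv", config)
            (out / "assoc_summary.txt").write_text(
                _provenance(config, []) + res.summary() + "\n"
            )

        synthetic.write_run_log({**config.to_flat(), **run_log}, out / "run_log.txt")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {err}") from err
    return out
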