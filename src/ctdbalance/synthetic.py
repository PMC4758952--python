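"""Synthetic genome, ChIP tags and expression with planted dependency structure.

The generator emulates the statistical situation the downstream analysis is
meant to dissect: several promoter marks of RNA polymerase II (S5p, S7p,
unphosphorylated S2 detected as "8WG16", K7ac, K7me1/K7me2) co-vary through
a shared per-gene activity factor, while productive elongation (S2p,
measured after the TES) is generated by a linear structural model on the
standardized log scale,

    S2p = a*S7p + b*K7ac + c*S5p + d*K7me + noise,     a, b, c > 0, d < 0,

so that K7 methylation is marginally positively correlated with elongation
(through activity) but has a planted negative direct path once the other
initiation marks are held fixed. mRNA (FPKM) and nascent transcription
(GRO-seq) are coupled to the S2p latent mass. Three gene classes are
planted: active, polycomb-repressed (PRCr: H3K27me3+, H2Aub1+, S5p+ poised
polymerase, no S7p/S2p/8WG16) and inactive (FPKM = 0, background only).

Tags are independent draws from mark-specific spatial kernels around the
TSS (or gene body/TES for S2p) plus a uniform background; the mock track is
background only. Everything is a pure function of the config's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genes import GeneModel
from .coverage import TagSet

__all__ = [
    "SyntheticConfig",
    "DEFAULT_PROFILE_PARAMS",
    "generate_genes",
    "latent_mark_table",
    "generate_tags",
    "generate_expression",
    "write_run_log",
]

PROMOTER_MARKS = ["S5p", "S7p", "8WG16", "K7ac", "K7me1", "K7me2"]
ALL_MARKS = PROMOTER_MARKS + ["S2p", "mock", "H3K27me3", "H2Aub1"]

#: Spatial kernels, in transcription orientation relative to the TSS
#: (S2p relative to the gene body / TES). Shapes follow the qualitative
#: promoter anatomy of the marks: K7me1/2 sharp at the TSS, K7ac expanding
#: downstream up to ~+500 bp, 8WG16 with a secondary peak ~140 bp
#: downstream (promoter-proximal pausing), S2p broad over the gene body and
#: maximal after the TES, polycomb marks broad.
DEFAULT_PROFILE_PARAMS = {
    "K7me1": {"shape": "gaussian", "center": 0, "spread": 80},
    "K7me2": {"shape": "gaussian", "center": 0, "spread": 80},
    "K7ac": {"shape": "gaussian", "center": 250, "spread": 200},
    "8WG16": {"shape": "bimodal", "center": 0, "spread": 60, "center2": 140},
    "S5p": {"shape": "gaussian", "center": 0, "spread": 150},
    "S7p": {"shape": "gaussian", "center": 100, "spread": 200},
    "S2p": {"shape": "body+TES", "center": 400, "spread": 600, "body_frac": 0.35},
    "mock": {"shape": "uniform"},
    "H3K27me3": {"shape": "gaussian", "center": 0, "spread": 1200},
    "H2Aub1": {"shape": "gaussian", "center": 0, "spread": 1200},
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic run.

    sem_coefficients are the planted structural paths into S2p:
    a: S7p, b: K7ac, c: S5p (all > 0) and d: K7me (< 0). ``loading`` is the
    weight of the shared activity factor in each promoter mark (pairwise
    mark correlation = loading^2); ``me_pair_corr`` is the planted
    correlation between K7me1 and K7me2.
    """

    n_active: int = 500
    n_prcr: int = 150
    n_inactive: int = 350
    chrom: str = "chrS"
    chrom_length: int = 25_000_000
    gene_length_range: tuple = (2_000, 10_000)
    seed: int = 0
    sem_coefficients: dict = field(
        default_factory=lambda: {"a": 0.45, "b": 0.40, "c": 0.25, "d": -0.35}
    )
    noise_sd: float = 0.5
    loading: float = 0.85
    me_pair_corr: float = 0.93
    mass_log_sd: float = 0.8
    profile_params: dict = field(default_factory=lambda: dict(DEFAULT_PROFILE_PARAMS))
    depth_per_mark: int = 200_000
    background_rate: float = 1e-3
    fpkm_log_sd: float = 0.4
    flank: int = 10_000

    def __post_init__(self) -> None:
        if min(self.n_active, self.n_prcr, self.n_inactive) < 0:
            raise ValueError("gene counts must be >= 0")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")
        if self.chrom_length <= hi + 2 * self.flank:
            raise ValueError("chrom_length must exceed max gene length plus flanks")
        c = self.sem_coefficients
        if not (c["a"] > 0 and c["b"] > 0 and c["d"] < 0):
            raise ValueError("planted SEM requires a, b > 0 and d < 0")
        unknown = set(self.profile_params) - set(ALL_MARKS)
        if unknown:
            raise ValueError(f"unknown mark(s) in profile_params: {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return self.n_active + self.n_prcr + self.n_inactive

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def to_flat(self) -> dict:
        d = asdict(self)
        flat = {}
        for k, v in d.items():
            if isinstance(v, dict):
                for kk, vv in v.items():
                    if isinstance(vv, dict):
                        for k3, v3 in vv.items():
                            flat[f"{k}.{kk}.{k3}"] = v3
                    else:
                        flat[f"{k}.{kk}"] = vv
            else:
                flat[k] = v
        return flat


# gap reserved around each gene so that 2 kb promoter and TES windows of
# neighbouring genes cannot collide
_MIN_GAP = 5_000


def generate_genes(config: SyntheticConfig) -> list[GeneModel]:
    """Place non-overlapping genes of the three planted classes on one chromosome."""
    n = config.n_genes
    if n == 0:
        return []
    rng = config.rng(1)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    needed = 2 * config.flank + int(lengths.sum()) + n * _MIN_GAP
    if needed > config.chrom_length:
        raise ValueError(
            f"cannot place {n} genes on {config.chrom_length} bp "
            f"(need >= {needed} bp); increase chrom_length"
        )
    # distribute the leftover space as random extra gaps
    slack = config.chrom_length - needed
    extra = rng.multinomial(slack, np.full(n, 1.0 / n)) if slack > 0 else np.zeros(n, dtype=int)
    strands = rng.choice(["+", "-"], size=n)
    classes = np.array(
        ["active"] * config.n_active + ["PRCr"] * config.n_prcr + ["inactive"] * config.n_inactive
    )
    rng.shuffle(classes)

    # expression: planted downstream of the SEM for active genes (filled in
    # by latent_mark_table); PRCr low, inactive exactly zero
    genes = []
    cursor = config.flank
    for i in range(n):
        cursor += _MIN_GAP // 2 + int(extra[i])
        start = cursor
        end = start + int(lengths[i])
        cursor = end + _MIN_GAP // 2
        genes.append(
            GeneModel(
                gene_id=f"g{i:05d}",
                chrom=config.chrom,
                start=start,
                end=end,
                strand=str(strands[i]),
                fpkm=0.0,
                cpg=0.0,
                true_class=str(classes[i]),
            )
        )
    # attach latent-derived attributes (fpkm, cpg) deterministically
    lat = latent_mark_table(genes, config)
    for g in genes:
        g.fpkm = float(lat.loc[g.gene_id, "fpkm"])
        g.cpg = float(lat.loc[g.gene_id, "cpg"])
    return genes


def latent_mark_table(genes: list[GeneModel], config: SyntheticConfig) -> pd.DataFrame:
    """Per-gene latent (log-scale, standardized) mark masses and expression.

    This is the planted truth the downstream statistics must recover; tag
    sampling adds Poisson noise on top of it. Deterministic given the config
    seed and gene order.
    """
    rng = config.rng(2)
    n = len(genes)
    ids = [g.gene_id for g in genes]
    cls = np.array([g.true_class for g in genes])
    active = cls == "active"
    prcr = cls == "PRCr"

    w = config.loading
    res = math.sqrt(1 - w * w)
    lam = math.sqrt(config.me_pair_corr)
    A = rng.normal(size=n)
    def load(x=None):
        return w * A + res * rng.normal(size=n)

    out = pd.DataFrame(index=pd.Index(ids, name="gene_id"))
    out["activity"] = A
    out["S5p"] = load()
    out["S7p"] = load()
    out["8WG16"] = load()
    out["K7ac"] = load()
    k7me = load()
    out["K7me"] = k7me
    out["K7me1"] = lam * k7me + math.sqrt(1 - lam * lam) * rng.normal(size=n)
    out["K7me2"] = lam * k7me + math.sqrt(1 - lam * lam) * rng.normal(size=n)
    c = config.sem_coefficients
    out["S2p"] = (
        c["a"] * out["S7p"]
        + c["b"] * out["K7ac"]
        + c["c"] * out["S5p"]
        + c["d"] * k7me
        + config.noise_sd * rng.normal(size=n)
    )
    # CpG: positive covariate mildly correlated with activity
    out["cpg"] = 0.6 + 0.12 * (0.3 * A + math.sqrt(1 - 0.09) * rng.normal(size=n))
    out["cpg"] = out["cpg"].clip(lower=0.05)

    # PRCr: poised S5p only, moderate level; polycomb marks present
    prcr_s5p = rng.normal(-0.5, 0.7, size=n)
    polycomb = rng.normal(0.0, 0.7, size=n)
    out["prcr_S5p"] = np.where(prcr, prcr_s5p, np.nan)
    out["H3K27me3"] = np.where(prcr, polycomb, np.nan)
    out["H2Aub1"] = np.where(prcr, rng.normal(0.0, 0.7, size=n), np.nan)

    # expression coupled to elongation
    s2p_std = (out["S2p"] - out.loc[active, "S2p"].mean()) / (
        out.loc[active, "S2p"].std() if active.sum() > 1 else 1.0
    )
    log10_fpkm = 1.0 + 0.6 * s2p_std + config.fpkm_log_sd * rng.normal(size=n)
    fpkm = np.where(active, 10.0 ** log10_fpkm, 0.0)
    fpkm = np.where(prcr, 10.0 ** rng.normal(-1.5, 0.5, size=n), fpkm)
    out["fpkm"] = fpkm
    out["true_class"] = cls
    return out


def _kernel_positions(rng, gene: GeneModel, spec: dict, size: int, chrom_length: int) -> np.ndarray:
    s = 1 if gene.strand == "+" else -1
    shape = spec["shape"]
    if shape == "gaussian":
        off = rng.normal(spec["center"], spec["spread"], size=size)
        pos = gene.tss + s * off
    elif shape == "bimodal":
        pick = rng.random(size) < 0.5
        off = np.where(
            pick,
            rng.normal(spec["center"], spec["spread"], size=size),
            rng.normal(spec["center2"], spec["spread"], size=size),
        )
        pos = gene.tss + s * off
    elif shape == "body+TES":
        in_body = rng.random(size) < spec.get("body_frac", 0.35)
        body = gene.start + rng.random(size) * (gene.end - gene.start)
        tes = gene.tes + s * rng.normal(spec["center"], spec["spread"], size=size)
        pos = np.where(in_body, body, tes)
    else:
        raise ValueError(f"unknown kernel shape {shape!r}")
    return np.clip(np.round(pos), 0, chrom_length - 1).astype(np.int64)


def generate_tags(
    genes: list[GeneModel], config: SyntheticConfig, run_log: dict | None = None
) -> dict[str, TagSet]:
    """Sample per-mark tag sets from latent masses, kernels and background.

    Per-gene expected signal mass for each mark is exp(mass_log_sd * latent);
    the mock track is uniform background only; PRCr genes receive S5p and
    polycomb marks but no S7p/S2p/8WG16/K7 mass. Total tags per mark are a
    Poisson draw around ``depth_per_mark``.
    """
    lat = latent_mark_table(genes, config)
    rng = config.rng(3)
    cls = lat["true_class"].to_numpy()
    active = cls == "active"
    prcr = cls == "PRCr"

    bg_expect = config.background_rate * config.chrom_length
    sig_expect = max(0.0, config.depth_per_mark - bg_expect)
    out: dict[str, TagSet] = {}
    marks = list(config.profile_params)
    for mark in marks:
        spec = config.profile_params[mark]
        # per-gene mass weights
        if mark == "mock" or spec["shape"] == "uniform":
            weights = np.zeros(len(genes))
        elif mark in ("H3K27me3", "H2Aub1"):
            weights = np.where(prcr, np.exp(config.mass_log_sd * np.nan_to_num(lat[mark])), 0.0)
            weights[~prcr] = 0.0
        elif mark == "S5p":
            weights = np.where(active, np.exp(config.mass_log_sd * lat["S5p"]), 0.0)
            weights = np.where(
                prcr, np.exp(config.mass_log_sd * np.nan_to_num(lat["prcr_S5p"])), weights
            )
        else:
            weights = np.where(active, np.exp(config.mass_log_sd * lat[mark]), 0.0)

        wsum = weights.sum()
        n_sig = int(rng.poisson(sig_expect)) if (sig_expect > 0 and wsum > 0) else 0
        n_bg = int(rng.poisson(bg_expect)) if bg_expect > 0 else 0

        pos_parts = []
        if n_sig > 0:
            per_gene = rng.multinomial(n_sig, weights / wsum)
            for g, k in zip(genes, per_gene):
                if k:
                    pos_parts.append(_kernel_positions(rng, g, spec, int(k), config.chrom_length))
        if n_bg > 0:
            pos_parts.append(rng.integers(0, config.chrom_length, size=n_bg))
        pos = np.concatenate(pos_parts) if pos_parts else np.array([], dtype=np.int64)
        strands = rng.choice(["+", "-"], size=len(pos))
        out[mark] = TagSet(mark, np.full(len(pos), config.chrom, dtype=object), pos, strands.astype(object))
        if run_log is not None:
            run_log[f"tags.{mark}.signal"] = int(n_sig)
            run_log[f"tags.{mark}.background"] = int(n_bg)
    return out


def generate_expression(
    genes: list[GeneModel], config: SyntheticConfig
) -> tuple[pd.DataFrame, TagSet, pd.DataFrame]:
    """FPKM table, stranded GRO-seq tags and a TSA fold-change table.

    GRO-seq sense tags fall along gene bodies in proportion to expression;
    a small antisense component sits just upstream of the promoter
    (divergent transcription). TSA response is planted so that genes with a
    high K7me/K7ac latent ratio are enriched for >= 2-fold up-regulation
    under the deacetylase inhibitor.
    """
    lat = latent_mark_table(genes, config)
    rng = config.rng(4)
    fpkm_table = lat[["fpkm", "cpg", "true_class"]].copy()

    # GRO-seq: expected sense count ~ fpkm * length (RPKM tracks FPKM)
    lengths = np.array([g.length for g in genes], dtype=float)
    fpkm = lat["fpkm"].to_numpy()
    sense_w = fpkm * lengths
    depth = config.depth_per_mark
    chroms, poss, strs = [], [], []
    if sense_w.sum() > 0:
        n_sense = int(rng.poisson(depth * 0.9))
        per_gene = rng.multinomial(n_sense, sense_w / sense_w.sum())
        n_anti = int(rng.poisson(depth * 0.1))
        anti_per_gene = rng.multinomial(n_anti, sense_w / sense_w.sum())
        for g, k, ka in zip(genes, per_gene, anti_per_gene):
            s = 1 if g.strand == "+" else -1
            if k:
                p = g.start + rng.random(int(k)) * (g.end - g.start)
                poss.append(np.round(p).astype(np.int64))
                strs.append(np.full(int(k), g.strand, dtype=object))
            if ka:
                p = g.tss - s * np.abs(rng.normal(150, 200, size=int(ka)))
                poss.append(np.clip(np.round(p), 0, config.chrom_length - 1).astype(np.int64))
                strs.append(np.full(int(ka), "-" if g.strand == "+" else "+", dtype=object))
    pos = np.concatenate(poss) if poss else np.array([], dtype=np.int64)
    strand = np.concatenate(strs) if strs else np.array([], dtype=object)
    groseq = TagSet("GROseq", np.full(len(pos), config.chrom, dtype=object), pos, strand)

    # TSA fold changes for active genes, coupled to the latent K7me/K7ac balance
    active = lat["true_class"] == "active"
    ratio_latent = (lat["K7me2"] - lat["K7ac"]).to_numpy()
    if active.sum() > 1:
        z = (ratio_latent - ratio_latent[active].mean()) / ratio_latent[active].std()
    else:
        z = ratio_latent
    log2fc = 1.0 * z + rng.normal(0, 1.0, size=len(genes))
    tsa = pd.DataFrame(
        {"fold_change": np.power(2.0, log2fc)[active]},
        index=lat.index[active],
    )
    return fpkm_table, groseq, tsa


def write_run_log(run_log: dict, path) -> None:
    with open(path, "w") as fh:
        for k in sorted(run_log):
            fh.write(f"{k}={run_log[k]}\n")
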