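"""Gene models and annotation I/O.

A :class:`GeneModel` is the unit of classification throughout the package:
a strand-aware interval with a transcription start site (TSS), a
transcription end site (TES), an expression level (FPKM) and a CpG
covariate. Coordinates are 0-based half-open, as in BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["GeneModel", "genes_to_frame", "write_gene_tables", "read_gene_tables"]


@dataclass
class GeneModel:
    """A gene with strand-aware TSS/TES and expression attributes.

    On the + strand the TSS is ``start`` and the TES is ``end``; on the
    − strand the TSS is ``end - 1`` and the TES is ``start`` (transcription
    runs right-to-left, so "after the TES" means decreasing coordinates).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    fpkm: float = 0.0
    cpg: float = 0.0
    true_class: str | None = None
    tss: int = field(init=False)
    tes: int = field(init=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.fpkm < 0:
            raise ValueError(f"{self.gene_id}: fpkm must be >= 0")
        if self.strand == "+":
            self.tss, self.tes = self.start, self.end
        else:
            self.tss, self.tes = self.end - 1, self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def genes_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    """Tabulate genes as a DataFrame indexed by gene_id."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "tes": [g.tes for g in genes],
            "fpkm": [g.fpkm for g in genes],
            "cpg": [g.cpg for g in genes],
            "true_class": [g.true_class for g in genes],
        }
    ).set_index("gene_id")


def write_gene_tables(genes: list[GeneModel], bed12_path, attrs_path) -> None:
    """Write genes as BED12 plus a TSV attribute table (fpkm, cpg, class)."""
    with open(bed12_path, "w") as fh:
        for g in genes:
            L = g.end - g.start
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{L},\t0,\n"
            )
    df = genes_to_frame(genes)[["fpkm", "cpg", "true_class"]]
    df.to_csv(attrs_path, sep="\t")


def read_gene_tables(bed12_path, attrs_path=None) -> list[GeneModel]:
    """Read genes from BED12 (and an optional TSV attribute table)."""
    attrs = None
    if attrs_path is not None:
        attrs = pd.read_csv(attrs_path, sep="\t", index_col=0)
    genes = []
    with open(bed12_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            gid = f[3]
            kw = {}
            if attrs is not None and gid in attrs.index:
                row = attrs.loc[gid]
                kw = {
                    "fpkm": float(row["fpkm"]),
                    "cpg": float(row["cpg"]),
                    "true_class": None
                    if pd.isna(row.get("true_class"))
                    else str(row["true_class"]),
                }
            genes.append(
                GeneModel(gid, f[0], int(f[1]), int(f[2]), f[5], **kw)
            )
    return genes
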