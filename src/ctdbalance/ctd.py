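"""Heptad-repeat decomposition of the RPB1 C-terminal domain.

The CTD of the largest RNA polymerase II subunit is a tandem array of
heptapeptide repeats with consensus Y1-S2-P3-T4-S5-P6-S7. In vertebrates
several repeats substitute the position-7 serine with a lysine ("K7"
residues) that can be methylated or acetylated. This module chunks a
C-terminal protein sequence into repeats from a user-supplied frame offset
and reports the non-consensus position-7 residues.

The mouse RPB1 repeat numbering (K7 residues at repeats including 35, 40
and 47, eight in total) is reproduced by running :func:`parse_heptads` on
the CTD span of a public mouse RPB1 protein record (e.g. UniProt P08775)
with the offset of repeat 1; no sequence is bundled here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["HeptadRepeat", "parse_heptads", "find_k7", "find_consensus_frame", "repeats_to_frame"]

CONSENSUS = "YSPTSPS"


@dataclass(frozen=True)
class HeptadRepeat:
    index: int  # 1-based repeat number
    residues: str

    def __post_init__(self):
        if len(self.residues) != 7:
            raise ValueError("a heptad repeat has exactly 7 residues")

    @property
    def position7(self) -> str:
        return self.residues[6]

    @property
    def is_consensus(self) -> bool:
        return self.residues == CONSENSUS


def parse_heptads(sequence: str, start_offset: int = 0) -> tuple[list[HeptadRepeat], str]:
    """Chunk ``sequence[start_offset:]`` into consecutive non-overlapping
    7-mers; returns (repeats, trailing remainder shorter than 7)."""
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    span = sequence[start_offset:]
    if len(span) < 7:
        raise ValueError("fewer than 7 residues after start_offset")
    repeats = [
        HeptadRepeat(i + 1, span[i * 7 : i * 7 + 7]) for i in range(len(span) // 7)
    ]
    remainder = span[len(repeats) * 7 :]
    return repeats, remainder


def find_k7(repeats: list[HeptadRepeat]) -> tuple[list[int], int]:
    """Sorted 1-based indices of repeats with lysine at position 7, and count."""
    idx = sorted(r.index for r in repeats if r.position7 == "K")
    return idx, len(idx)


def find_consensus_frame(sequence: str) -> int:
    """Helper: offset of the first consensus repeat (Y-anchored auto-framing).

    Provided for convenience; positional repeat numbering normally requires
    the caller to supply the published frame offset explicitly.
    """
    i = sequence.upper().find(CONSENSUS)
    if i < 0:
        raise ValueError("no consensus heptad found")
    return i


def repeats_to_frame(repeats: list[HeptadRepeat], remainder: str = "") -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "repeat": [r.index for r in repeats],
            "residues": [r.residues for r in repeats],
            "position7": [r.position7 for r in repeats],
            "is_consensus": [r.is_consensus for r in repeats],
        }
    ).set_index("repeat")
    df.attrs["remainder"] = remainder
    return df
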