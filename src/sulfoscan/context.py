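"""Residue-class composition of sequence windows flanking tyrosine sites.

Tyrosylprotein sulfotransferases favour acidic sequence contexts, so the
+/-7-residue windows around candidate sulfotyrosines are expected to be
richer in D/E than windows around tyrosines at large.  Windows are
truncated (not padded) at protein termini, deduplicated by (accession,
position), and the central Y is excluded from composition counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import fasta as _pfasta


@dataclass(frozen=True)
class ResidueClassScheme:
    """Partition of the 20 standard residues into four chemical classes."""

    acidic: frozenset[str] = frozenset("DE")
    basic: frozenset[str] = frozenset("KRH")
    neutral: frozenset[str] = frozenset("AVLIMFWPG")
    polar: frozenset[str] = frozenset("STYNQC")

    def __post_init__(self) -> None:
        union = self.acidic | self.basic | self.neutral | self.polar
        total = len(self.acidic) + len(self.basic) + len(self.neutral) + len(self.polar)
        if union != frozenset("ACDEFGHIKLMNPQRSTVWY") or total != 20:
            raise ValueError("classes must partition the 20 standard residues")

    def classify(self, residue: str) -> str:
        for cls in ("acidic", "basic", "neutral", "polar"):
            if residue in getattr(self, cls):
                return cls
        raise KeyError(residue)


@dataclass(frozen=True)
class FlankWindow:
    accession: str
    y_position: int  # 1-based position of the central Y in the protein
    window: str  # <=15 residues, Y centred, truncated at termini
    origin: str  # foreground | background
    center_index: int = 7  # index of the central Y within the window

    def __post_init__(self) -> None:
        if self.window[self.center_index] != "Y":
            raise ValueError(f"window centre is not Y: {self.window!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by accession (first token of the header)."""
    seqs = {}
    with _pfasta.read(str(path)) as fh:
        for header, seq in fh:
            seqs[header.split()[0]] = seq
    return seqs


def extract_flanks(
    accession: str,
    protein_sequence: str,
    y_positions: Iterable[int],
    origin: str = "foreground",
    w: int = 7,
) -> list[FlankWindow]:
    """Windows of ``w`` residues either side of each listed Y position.

    Positions are 1-based and must index a Y; windows are truncated at the
    protein termini.
    """
    out = []
    for pos in y_positions:
        if not 1 <= pos <= len(protein_sequence) or protein_sequence[pos - 1] != "Y":
            raise ValueError(
                f"{accession}: position {pos} is not a Y in the protein sequence"
            )
        lo = max(0, pos - 1 - w)
        hi = min(len(protein_sequence), pos + w)
        out.append(
            FlankWindow(accession, pos, protein_sequence[lo:hi], origin, pos - 1 - lo)
        )
    return out


def class_composition(
    windows: Sequence[FlankWindow],
    scheme: ResidueClassScheme = ResidueClassScheme(),
    exclude_center: bool = True,
) -> pd.DataFrame:
    """Residue-class fractions of the flanking residues, per origin.

    Windows are deduplicated by (accession, position) so each site counts
    once regardless of how many peptidoforms cover it.  The central Y is
    excluded by default.  Fractions sum to 1 within each origin.
    """
    if not windows:
        raise ValueError("no windows supplied")
    seen: set[tuple[str, int, str]] = set()
    counts: dict[str, dict[str, int]] = {}
    for win in windows:
        key = (win.accession, win.y_position, win.origin)
        if key in seen:
            continue
        seen.add(key)
        c = counts.setdefault(
            win.origin, {"acidic": 0, "basic": 0, "neutral": 0, "polar": 0}
        )
        for i, residue in enumerate(win.window):
            if exclude_center and i == win.center_index:
                continue
            c[scheme.classify(residue)] += 1
    rows = []
    for origin in sorted(counts):
        total = sum(counts[origin].values())
        row: dict[str, object] = {"origin": origin, "n_residues": total}
        for cls in ("acidic", "basic", "neutral", "polar"):
            row[f"frac_{cls}"] = counts[origin][cls] / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
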