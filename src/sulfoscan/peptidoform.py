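"""Nonstrict peptidoform identities and per-peptidoform mass-error pooling.

A "nonstrict" peptidoform keeps the modified residue *type* and the
modification *count* but drops the site position: PEPSYR phosphorylated on
S4 at any charge pools with every other pS form of PEPSYR, while the pY
form of the same peptide is a distinct peptidoform.  Positional ambiguity
is deliberate — a labile sulfate leaves no fragment evidence to localise,
so site-level identities would fragment the PSM support.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .ingest import Modification, PsmRecord

logger = logging.getLogger(__name__)


def make_peptidoform_id(sequence: str, mods: Sequence[Modification]) -> str:
    """Canonical peptidoform id: sequence + sorted ``Name@Residue:count`` terms.

    Positions and charge are excluded by construction; an unmodified
    peptide's id is the bare sequence.
    """
    for m in mods:
        if m.position >= 1 and sequence[m.position - 1] != m.residue:
            raise ValueError(
                f"modification residue {m.residue}@{m.position} does not match "
                f"sequence {sequence}"
            )
    counts = Counter((m.name, m.residue) for m in mods)
    parts = [f"{name}@{residue}:{n}" for (name, residue), n in sorted(counts.items())]
    return "|".join([sequence] + parts)


@dataclass
class Peptidoform:
    """A peptidoform identity with the pooled mass errors of all its PSMs."""

    id: str
    sequence: str
    mod_composition: dict[tuple[str, str], int]
    mass_errors: list[float] = field(default_factory=list)
    psm_refs: list[tuple[str, str, int, int]] = field(default_factory=list)
    experiment_ids: set[str] = field(default_factory=set)
    protein_accessions: set[str] = field(default_factory=set)

    @property
    def n_psms(self) -> int:
        return len(self.mass_errors)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def _has_mod_on(self, name: str, residue: str) -> bool:
        return self.mod_composition.get((name, residue), 0) > 0

    @property
    def contains_Y(self) -> bool:
        return "Y" in self.sequence

    @property
    def contains_S(self) -> bool:
        return "S" in self.sequence

    @property
    def contains_T(self) -> bool:
        return "T" in self.sequence

    @property
    def has_pY(self) -> bool:
        return self._has_mod_on("Phospho", "Y")

    @property
    def has_pS(self) -> bool:
        return self._has_mod_on("Phospho", "S")

    @property
    def has_pT(self) -> bool:
        return self._has_mod_on("Phospho", "T")

    @property
    def has_deamidation(self) -> bool:
        return any(name == "Deamidated" for name, _ in self.mod_composition)

    @property
    def n_phospho(self) -> int:
        return sum(n for (name, _), n in self.mod_composition.items() if name == "Phospho")


def aggregate(
    records: Sequence[PsmRecord],
    protein_map: Mapping[str, set[str] | Sequence[str]] | None = None,
) -> list[Peptidoform]:
    """Group recalibrated PSMs into peptidoforms and pool their mass errors.

    ``protein_map`` maps peptide sequence -> protein accessions; sequences
    absent from it are kept with an empty accession set and logged.
    """
    protein_map = protein_map or {}
    forms: dict[str, Peptidoform] = {}
    unmapped: set[str] = set()
    for r in records:
        if r.mass_error_calibrated is None:
            raise ValueError("aggregate() requires recalibrated records")
        pid = make_peptidoform_id(r.peptide_sequence, r.modifications)
        pf = forms.get(pid)
        if pf is None:
            comp = Counter((m.name, m.residue) for m in r.modifications)
            accs = protein_map.get(r.peptide_sequence)
            if accs is None:
                unmapped.add(r.peptide_sequence)
                accs = set()
            pf = forms[pid] = Peptidoform(
                id=pid,
                sequence=r.peptide_sequence,
                mod_composition=dict(comp),
                protein_accessions=set(accs),
            )
        pf.mass_errors.append(r.mass_error_calibrated)
        pf.psm_refs.append((r.collection_id, r.run_id, r.scan_number, r.charge))
        pf.experiment_ids.add(r.experiment_id)
    if unmapped and protein_map:
        logger.info("%d peptide sequences missing from protein map", len(unmapped))
    return list(forms.values())


def filter_robust(
    peptidoforms: Sequence[Peptidoform],
    min_experiments: int = 3,
    min_psms: int = 90,
) -> list[Peptidoform]:
    """Keep robustly detected peptidoforms: >=3 experiments AND >=90 PSMs.

    Both bounds inclusive; applied as one conjunction (sequential
    application composes to the same set).
    """
    return [
        pf
        for pf in peptidoforms
        if pf.n_experiments >= min_experiments and pf.n_psms >= min_psms
    ]


def summary_frame(peptidoforms: Sequence[Peptidoform]) -> pd.DataFrame:
    """Peptidoform summary table (one row per peptidoform) for export."""
    rows = []
    for pf in peptidoforms:
        rows.append(
            {
                "peptidoform_id": pf.id,
                "sequence": pf.sequence,
                "n_psms": pf.n_psms,
                "n_experiments": pf.n_experiments,
                "contains_Y": pf.contains_Y,
                "contains_S": pf.contains_S,
                "contains_T": pf.contains_T,
                "has_pY": pf.has_pY,
                "has_pS": pf.has_pS,
                "has_pT": pf.has_pT,
                "has_deamidation": pf.has_deamidation,
                "protein_accessions": ";".join(sorted(pf.protein_accessions)),
            }
        )
    return pd.DataFrame(rows)


def write_summary(peptidoforms: Sequence[Peptidoform], path: str | Path) -> None:
    summary_frame(peptidoforms).to_csv(path, sep="\t", index=False)
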