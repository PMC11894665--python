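"""Reading, quality-filtering and recalibrating PSM tables.

A PSM (peptide-spectrum match) row carries provenance identifiers, the
peptide sequence with its modification string, the precursor mass error in
Da (observed minus theoretical neutral mass), and a PeptideProphet-style
q-value.  The pipeline order is fixed: FDR filter -> per-run median
recalibration -> phospho filter, so that the recalibration median is taken
over all confident PSMs of a run, not only the phosphorylated ones.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constants import MODIFICATION_MASSES, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

#: canonical column names of the PSM TSV dialect
REQUIRED_COLUMNS = (
    "collection_id",
    "dataset_id",
    "experiment_id",
    "run_id",
    "scan",
    "sequence",
    "mods",
    "charge",
    "mass_error_da",
    "q_value",
)

_CANONICAL_MOD_NAMES = {name.lower(): name for name in MODIFICATION_MASSES}


@dataclass(frozen=True)
class Modification:
    """One PTM assignment: 1-based position, residue letter, controlled name.

    Position 0 denotes an N-terminal modification.
    """

    position: int
    residue: str
    name: str
    mass_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"modification position must be >= 0, got {self.position}")


@dataclass
class PsmRecord:
    """One peptide-spectrum match with raw and calibrated mass error."""

    collection_id: str
    dataset_id: str
    experiment_id: str
    run_id: str
    scan_number: int
    peptide_sequence: str
    modifications: list[Modification]
    charge: int
    mass_error_raw: float
    q_value: float
    mass_error_calibrated: float | None = None
    instrument: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.peptide_sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"nonstandard residues {sorted(bad)} in {self.peptide_sequence}")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.scan_number < 1:
            raise ValueError(f"scan_number must be >= 1, got {self.scan_number}")
        for mod in self.modifications:
            if mod.position >= 1:
                if mod.position > len(self.peptide_sequence):
                    raise ValueError(
                        f"modification position {mod.position} beyond sequence "
                        f"{self.peptide_sequence}"
                    )
                seq_res = self.peptide_sequence[mod.position - 1]
                if seq_res != mod.residue:
                    raise ValueError(
                        f"modification residue {mod.residue} at position {mod.position} "
                        f"does not match sequence residue {seq_res}"
                    )


def normalize_mod_name(name: str) -> str:
    """Map a modification name onto the controlled vocabulary, case-insensitively.

    Unknown names are carried through verbatim (they never match filters).
    """
    return _CANONICAL_MOD_NAMES.get(name.strip().lower(), name.strip())


def parse_mods(mods_field: str) -> list[Modification]:
    """Parse the compact ``pos-residue-name;...`` modification grammar.

    Example: ``"7-S-Phospho;10-Y-Phospho"``; the empty string means
    unmodified.
    """
    mods_field = mods_field.strip()
    if not mods_field:
        return []
    out = []
    for token in mods_field.split(";"):
        parts = token.strip().split("-", 2)
        if len(parts) != 3:
            raise ValueError(f"unparsable modification token {token!r}")
        pos_s, residue, raw_name = parts
        name = normalize_mod_name(raw_name)
        out.append(
            Modification(
                position=int(pos_s),
                residue=residue.strip(),
                name=name,
                mass_delta=MODIFICATION_MASSES.get(name, 0.0),
            )
        )
    return out


def format_mods(mods: Iterable[Modification]) -> str:
    return ";".join(f"{m.position}-{m.residue}-{m.name}" for m in mods)


class PsmTableError(Exception):
    """Configuration-level problem with a PSM table (missing columns, etc.)."""


def read_psm_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[PsmRecord]:
    """Read a PSM TSV into records, rejecting rows that violate invariants.

    Parameters
    ----------
    path:
        Tab-separated file with the canonical columns (see
        ``REQUIRED_COLUMNS``); an ``instrument`` column is optional.
    dialect:
        Optional mapping from canonical column name to the name actually
        used in the file, e.g. ``{"sequence": "Peptide"}``.

    Row-level failures (bad modification strings, invariant violations) are
    collected and logged; the read aborts only if more than half the rows
    fail.
    """
    path = Path(path)
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {canon: dialect.get(canon, canon) for canon in REQUIRED_COLUMNS}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise PsmTableError(f"{path}: missing required columns {missing}")
    instrument_col = dialect.get("instrument", "instrument")
    has_instrument = instrument_col in df.columns

    records: list[PsmRecord] = []
    n_rejected = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            records.append(
                PsmRecord(
                    collection_id=rowd[colmap["collection_id"]],
                    dataset_id=rowd[colmap["dataset_id"]],
                    experiment_id=rowd[colmap["experiment_id"]],
                    run_id=rowd[colmap["run_id"]],
                    scan_number=int(rowd[colmap["scan"]]),
                    peptide_sequence=rowd[colmap["sequence"]].strip().upper(),
                    modifications=parse_mods(rowd[colmap["mods"]]),
                    charge=int(rowd[colmap["charge"]]),
                    mass_error_raw=float(rowd[colmap["mass_error_da"]]),
                    q_value=float(rowd[colmap["q_value"]]),
                    instrument=rowd.get(instrument_col) if has_instrument else None,
                )
            )
        except (ValueError, KeyError) as exc:
            n_rejected += 1
            logger.warning("%s: rejecting row %d: %s", path, idx, exc)
    if n_rejected:
        logger.info("%s: rejected %d of %d rows", path, n_rejected, len(df))
    if len(df) > 0 and n_rejected > len(df) / 2:
        raise PsmTableError(
            f"{path}: {n_rejected}/{len(df)} rows failed to parse"
        )
    return records


def write_psm_table(records: Sequence[PsmRecord], path: str | Path) -> None:
    """Write records in the canonical TSV dialect (inverse of read_psm_table)."""
    rows = []
    for r in records:
        rows.append(
            {
                "collection_id": r.collection_id,
                "dataset_id": r.dataset_id,
                "experiment_id": r.experiment_id,
                "run_id": r.run_id,
                "scan": r.scan_number,
                "sequence": r.peptide_sequence,
                "mods": format_mods(r.modifications),
                "charge": r.charge,
                "mass_error_da": repr(r.mass_error_raw),
                "q_value": repr(r.q_value),
                "instrument": r.instrument or "",
            }
        )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["instrument"]).to_csv(
        path, sep="\t", index=False
    )


def filter_fdr(records: Sequence[PsmRecord], q_threshold: float = 0.01) -> list[PsmRecord]:
    """Keep PSMs with q-value strictly below the threshold (default q < 0.01)."""
    return [r for r in records if r.q_value < q_threshold]


def recalibrate(records: Sequence[PsmRecord]) -> list[PsmRecord]:
    """Subtract the per-run median mass error from each PSM's raw error.

    Recalibration is performed per raw file (run_id), so a run-level
    instrument miscalibration offset cancels exactly.  Singleton runs get a
    calibrated error of 0 (the median of one element is itself).  Returns
    new records; input order is preserved.  Idempotent: a second pass
    subtracts a zero median.
    """
    by_run: dict[str, list[float]] = {}
    for r in records:
        by_run.setdefault(r.run_id, []).append(r.mass_error_raw)
    medians = {run: statistics.median(v) for run, v in by_run.items()}
    for run, vals in by_run.items():
        if len(vals) == 1:
            logger.info("run %s has a single PSM; calibrated error set to 0", run)
    return [
        replace(r, mass_error_calibrated=r.mass_error_raw - medians[r.run_id])
        for r in records
    ]


def filter_phospho(records: Sequence[PsmRecord]) -> list[PsmRecord]:
    """Keep PSMs carrying at least one Phospho on S, T or Y."""
    return [
        r
        for r in records
        if any(m.name == "Phospho" and m.residue in "STY" for m in r.modifications)
    ]
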