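"""Monoisotopic mass constants for the sulfation/phosphorylation problem.

Tyrosine sulfation (+SO3) and phosphorylation (+HPO3) are near isobaric:
the adduct masses differ by ~0.0095 Da, which is why a sulfopeptide can be
captured inside the precursor tolerance window of a phosphopeptide search
and misidentified.  All masses here are monoisotopic and derived from
atomic compositions via pyteomics, not hand-typed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

#: Monoisotopic mass of the phosphoryl adduct HPO3 (phosphorylation), Da.
PHOSPHO_MASS: float = _pmass.calculate_mass(formula="HPO3")

#: Monoisotopic mass of the sulfonate adduct SO3 (sulfation), Da.
SULFO_MASS: float = _pmass.calculate_mass(formula="SO3")

#: Mass difference between a phosphorylated and a sulfated residue, Da.
SULFO_PHOSPHO_DELTA: float = PHOSPHO_MASS - SULFO_MASS

#: 13C - 12C mass difference (isotopomer spacing), Da.
C13_C12_DELTA: float = 13.00335483507 - 12.0

#: Deamidation (N/Q -> D/E): +O -NH ... net OH - NH2 + ... = +0.984016 Da.
DEAMIDATION_MASS: float = _pmass.calculate_mass(formula="O") - _pmass.calculate_mass(
    formula="NH"
)

#: Proton mass, Da (charge carrier).
PROTON_MASS: float = _pmass.nist_mass["H+"][0][0]

#: Water, Da (peptide bond condensation / y-ion terminus).
WATER_MASS: float = _pmass.calculate_mass(formula="H2O")

#: Apparent precursor shift of the "deamidation isotopomer artifact": the
#: instrument selects the +1 isotope peak (+1.003 Da) and the search engine
#: wrongly adds deamidation (+0.984 Da), leaving a net ~+0.0193 Da error.
DEAMIDATION_ARTIFACT_SHIFT: float = C13_C12_DELTA - DEAMIDATION_MASS

#: Monoisotopic residue masses for the 20 standard amino acids, Da.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

STANDARD_RESIDUES: frozenset[str] = frozenset(RESIDUE_MASSES)

#: Modification name -> monoisotopic mass delta (Da), controlled vocabulary.
MODIFICATION_MASSES: dict[str, float] = {
    "Phospho": PHOSPHO_MASS,
    "Sulfo": SULFO_MASS,
    "Oxidation": _pmass.calculate_mass(formula="O"),
    "Deamidated": DEAMIDATION_MASS,
    "Carbamidomethyl": _pmass.calculate_mass(formula="CH2CONH2") - _pmass.calculate_mass(formula="H"),
}


def ppm_window(neutral_mass: float, ppm: float) -> float:
    """Half-width in Da of a +/- `ppm` tolerance window at `neutral_mass`.

    E.g. +/-10 ppm at 2000 Da is +/-0.02 Da — wide enough to capture a
    sulfopeptide (delta 0.0095 Da) inside a phosphopeptide's window.
    """
    return neutral_mass * ppm * 1e-6


@dataclass(frozen=True)
class MassConstants:
    """Bundle of the constants above, for passing through the pipeline."""

    phospho_mass: float = PHOSPHO_MASS
    sulfo_mass: float = SULFO_MASS
    sulfo_phospho_delta: float = SULFO_PHOSPHO_DELTA
    c13_c12_delta: float = C13_C12_DELTA
    deamidation_mass: float = DEAMIDATION_MASS
    proton_mass: float = PROTON_MASS
    water_mass: float = WATER_MASS
    residue_masses: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_MASSES))
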