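"""Dual-hypothesis MS2 assessment of suspected sulfopeptides.

Sulfate is fully labile under collisional fragmentation: b/y fragments of
a sulfopeptide match the *unmodified* series while the precursor retains
the +79.9568 Da.  A retained phosphate, in contrast, shifts every
fragment spanning the site by +79.9663 Da.  Each spectrum is therefore
annotated twice — once under the original Y[Phospho] interpretation and
once under the rewritten Y{Sulfo} interpretation (ProForma curly braces =
full neutral loss) — and the hypothesis explaining more of the sequence
and more of the total ion current wins.  Interpretations are addressed by
Universal Spectrum Identifiers (USIs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import (
    MODIFICATION_MASSES,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
)
from .ingest import Modification, PsmRecord

#: modification names treated as fully labile (curly-brace ProForma notation)
LABILE_MODS = frozenset({"Sulfo"})


@dataclass(frozen=True)
class SpectrumInterpretation:
    """A peptide sequence + positioned modifications + precursor charge.

    Each modification is rendered in ProForma as ``[Name]`` if its mass is
    retained on fragments or ``{Name}`` if fully labile (lost from every
    fragment while still counted in the precursor mass).
    """

    sequence: str
    modifications: tuple[Modification, ...]
    charge: int

    @property
    def proforma(self) -> str:
        by_pos: dict[int, list[Modification]] = {}
        for m in self.modifications:
            by_pos.setdefault(m.position, []).append(m)
        out = []
        for nterm_mod in by_pos.get(0, []):
            out.append(_render_tag(nterm_mod.name) + "-")
        for i, residue in enumerate(self.sequence, start=1):
            out.append(residue)
            for m in by_pos.get(i, []):
                out.append(_render_tag(m.name))
        return "".join(out)

    def precursor_neutral_mass(self) -> float:
        mass = WATER_MASS + sum(RESIDUE_MASSES[r] for r in self.sequence)
        mass += sum(MODIFICATION_MASSES.get(m.name, m.mass_delta) for m in self.modifications)
        return mass

    def precursor_mz(self) -> float:
        return (self.precursor_neutral_mass() + self.charge * PROTON_MASS) / self.charge


def _render_tag(name: str) -> str:
    return "{%s}" % name if name in LABILE_MODS else "[%s]" % name


_TAG_RE = re.compile(r"([A-Z])((?:\[[^\]]+\]|\{[^}]+\})*)")
_NTERM_RE = re.compile(r"^((?:\[[^\]]+\]|\{[^}]+\})+)-")
_MOD_RE = re.compile(r"\[([^\]]+)\]|\{([^}]+)\}")


def parse_proforma(proforma: str) -> tuple[str, tuple[Modification, ...]]:
    """Parse the ``[Name]`` / ``{Name}`` ProForma subset used here."""
    mods: list[Modification] = []
    m = _NTERM_RE.match(proforma)
    rest = proforma
    if m:
        for tag in _MOD_RE.finditer(m.group(1)):
            name = tag.group(1) or tag.group(2)
            mods.append(
                Modification(0, "", name, MODIFICATION_MASSES.get(name, 0.0))
            )
        rest = proforma[m.end():]
    sequence = []
    pos = 0
    idx = 0
    while idx < len(rest):
        match = _TAG_RE.match(rest, idx)
        if not match:
            raise ValueError(f"unparsable ProForma string {proforma!r} at {rest[idx:]!r}")
        residue, tags = match.group(1), match.group(2)
        pos += 1
        sequence.append(residue)
        for tag in _MOD_RE.finditer(tags):
            name = tag.group(1) or tag.group(2)
            mods.append(
                Modification(pos, residue, name, MODIFICATION_MASSES.get(name, 0.0))
            )
        idx = match.end()
    return "".join(sequence), tuple(mods)


@dataclass(frozen=True)
class Usi:
    """Universal Spectrum Identifier addressing one spectrum interpretation.

    Serialized form:
    ``mzspec:<CollectionID>:<msRunComponent>:scan:<ScanNumber>:<ProForma>/<charge>``
    """

    collection_id: str
    ms_run_component: str
    scan_number: int
    interpretation: SpectrumInterpretation
    index_flag: str = "scan"

    def serialize(self) -> str:
        return (
            f"mzspec:{self.collection_id}:{self.ms_run_component}:"
            f"{self.index_flag}:{self.scan_number}:"
            f"{self.interpretation.proforma}/{self.interpretation.charge}"
        )


def parse_usi(usi: str) -> Usi:
    parts = usi.split(":", 5)
    if len(parts) != 6 or parts[0] != "mzspec":
        raise ValueError(f"not a valid USI: {usi!r}")
    _, collection, run, index_flag, scan, interp = parts
    proforma, _, charge = interp.rpartition("/")
    sequence, mods = parse_proforma(proforma)
    return Usi(
        collection_id=collection,
        ms_run_component=run,
        scan_number=int(scan),
        index_flag=index_flag,
        interpretation=SpectrumInterpretation(sequence, mods, int(charge)),
    )


def build_usi(psm: PsmRecord, interpretation: SpectrumInterpretation) -> str:
    """Serialize the USI for a PSM under a given interpretation."""
    for name, value in (
        ("collection_id", psm.collection_id),
        ("run_id", psm.run_id),
        ("scan_number", psm.scan_number),
    ):
        if not value:
            raise ValueError(f"PSM missing {name}; cannot build USI")
    return Usi(
        collection_id=psm.collection_id,
        ms_run_component=psm.run_id,
        scan_number=psm.scan_number,
        interpretation=interpretation,
    ).serialize()


def theoretical_fragments(
    interpretation: SpectrumInterpretation,
    max_fragment_charge: int = 2,
) -> list[tuple[str, int, int, float]]:
    """b and y fragment m/z values under the interpretation's hypotheses.

    Mass-retaining (square-bracket) modifications add their delta to every
    fragment containing the site; labile (curly-brace) modifications add
    nothing to any fragment.  Fragment charges run 1..min(2, precursor
    charge).  Returns (ion_type, index, charge, m/z) tuples.
    """
    seq = interpretation.sequence
    L = len(seq)
    unknown = set(seq) - set(RESIDUE_MASSES)
    if unknown:
        raise ValueError(f"unknown residues {sorted(unknown)}")
    # per-residue retained modification mass (position 0 counts toward b ions)
    retained = np.zeros(L)
    nterm_extra = 0.0
    for m in interpretation.modifications:
        if m.name in LABILE_MODS:
            continue
        delta = MODIFICATION_MASSES.get(m.name, m.mass_delta)
        if m.position == 0:
            nterm_extra += delta
        else:
            retained[m.position - 1] += delta
    residue = np.array([RESIDUE_MASSES[r] for r in seq]) + retained
    prefix = np.cumsum(residue)  # prefix[i-1] = sum of residues 1..i
    total = prefix[-1]
    charges = range(1, min(max_fragment_charge, interpretation.charge) + 1)
    out = []
    for i in range(1, L):
        b_neutral = prefix[i - 1] + nterm_extra  # b ion: residues + N-term mods
        y_neutral = total - prefix[i - 1] + WATER_MASS
        for z in charges:
            out.append(("b", i, z, (b_neutral + z * PROTON_MASS) / z))
            out.append(("y", L - i, z, (y_neutral + z * PROTON_MASS) / z))
    return out


@dataclass
class SpectrumAnnotation:
    """Matched fragments and summary metrics under one hypothesis."""

    matches: list[tuple[str, int, int, float, float, float]]
    tic_fraction_annotated: float
    residues_supported: float
    n_theoretical: int


def match_peaks(
    peaks: Sequence[tuple[float, float]],
    theoretical: Sequence[tuple[str, int, int, float]],
    tolerance: float = 0.05,
    sequence_length: int | None = None,
) -> SpectrumAnnotation:
    """Match theoretical ions to observed peaks within an m/z tolerance.

    For each theoretical ion, the most intense peak within +/-tolerance is
    selected (ties broken by smallest |delta m/z|).  The annotated TIC
    fraction counts each observed peak once even if it matches several
    ions; residue support is the fraction of inter-residue bonds covered
    by at least one matched b or y ion.
    """
    if sequence_length is None:
        sequence_length = max(
            (idx + 1 for ion, idx, _, _ in theoretical if ion == "b"), default=0
        )
    peaks = sorted(peaks)
    mzs = np.array([p[0] for p in peaks])
    intens = np.array([p[1] for p in peaks])
    total_intensity = float(intens.sum()) if len(peaks) else 0.0
    matches = []
    matched_peak_idx: set[int] = set()
    covered_bonds: set[int] = set()
    for ion, idx, z, tmz in theoretical:
        lo = np.searchsorted(mzs, tmz - tolerance, side="left")
        hi = np.searchsorted(mzs, tmz + tolerance, side="right")
        if lo == hi:
            continue
        cand = np.arange(lo, hi)
        best = max(cand, key=lambda j: (intens[j], -abs(mzs[j] - tmz)))
        matches.append((ion, idx, z, tmz, float(mzs[best]), float(intens[best])))
        matched_peak_idx.add(int(best))
        covered_bonds.add(idx if ion == "b" else sequence_length - idx)
    tic = (
        float(intens[sorted(matched_peak_idx)].sum()) / total_intensity
        if total_intensity > 0
        else 0.0
    )
    n_bonds = max(sequence_length - 1, 1)
    return SpectrumAnnotation(
        matches=matches,
        tic_fraction_annotated=tic,
        residues_supported=len(covered_bonds) / n_bonds,
        n_theoretical=len(theoretical),
    )


@dataclass
class HypothesisVerdict:
    verdict: str  # sulfo-favored | phospho-favored | inconclusive
    sulfo: SpectrumAnnotation
    phospho: SpectrumAnnotation


def compare_hypotheses(
    peaks: Sequence[tuple[float, float]],
    sulfo_interp: SpectrumInterpretation,
    phospho_interp: SpectrumInterpretation,
    tolerance: float = 0.05,
) -> HypothesisVerdict:
    """Score a spectrum under both interpretations and pick the winner.

    Sulfation is favoured when it does at least as well on both sequence
    support and annotated TIC fraction and strictly better on at least one
    of them; the reverse favours phosphorylation; anything else is
    inconclusive.  (A complementary b/y pair covers the same bond, so on a
    near-complete spectrum sequence support can tie at 1.0 under both
    hypotheses while the TIC fraction still separates them cleanly.)
    """
    if sulfo_interp.sequence != phospho_interp.sequence or (
        sulfo_interp.charge != phospho_interp.charge
    ):
        raise ValueError("hypotheses must share sequence and charge")
    L = len(sulfo_interp.sequence)
    ann_s = match_peaks(peaks, theoretical_fragments(sulfo_interp), tolerance, L)
    ann_p = match_peaks(peaks, theoretical_fragments(phospho_interp), tolerance, L)

    def _dominates(a: SpectrumAnnotation, b: SpectrumAnnotation) -> bool:
        return (
            a.residues_supported >= b.residues_supported
            and a.tic_fraction_annotated >= b.tic_fraction_annotated
            and (
                a.residues_supported > b.residues_supported
                or a.tic_fraction_annotated > b.tic_fraction_annotated
            )
        )

    if _dominates(ann_s, ann_p):
        verdict = "sulfo-favored"
    elif _dominates(ann_p, ann_s):
        verdict = "phospho-favored"
    else:
        verdict = "inconclusive"
    return HypothesisVerdict(verdict, ann_s, ann_p)


def alternative_interpretations(
    psm: PsmRecord,
    strategy: str = "deterministic",
    seed: int = 0,
) -> list[SpectrumInterpretation]:
    """Rewrite a phospho PSM into its sulfation hypothesis interpretations.

    - Every Y[Phospho] becomes Y{Sulfo}.
    - If phosphorylation sits only on non-Y residues, one phosphorylation
      is removed and a {Sulfo} placed on a tyrosine (lowest index by
      default; ``strategy="seeded-random"`` picks randomly).
    - If the peptide has >=2 phosphorylations and >=2 tyrosines, a doubly
      rewritten variant is also emitted.

    Deamidated peptidoforms are refused: their precursor shifts are
    dominated by the isotopomer artifact, not by sulfation.
    """
    if any(m.name == "Deamidated" for m in psm.modifications):
        raise ValueError("deamidated peptidoforms are not assessed for sulfation")
    seq = psm.peptide_sequence
    y_positions = [i + 1 for i, r in enumerate(seq) if r == "Y"]
    if not y_positions:
        raise ValueError("no tyrosine in sequence; sulfation hypothesis impossible")
    phosphos = [m for m in psm.modifications if m.name == "Phospho"]
    if not phosphos:
        raise ValueError("PSM carries no phosphorylation to rewrite")
    rng = np.random.default_rng(seed)

    def _sulfo(pos: int) -> Modification:
        return Modification(pos, seq[pos - 1], "Sulfo", MODIFICATION_MASSES["Sulfo"])

    def _rewrite_once(mods: tuple[Modification, ...]) -> tuple[Modification, ...] | None:
        """One phospho->sulfo replacement: prefer Y[Phospho]->Y{Sulfo},
        else drop a phospho and sulfate a still-unmodified tyrosine."""
        cur_phospho = [m for m in mods if m.name == "Phospho"]
        if not cur_phospho:
            return None
        py = [m for m in cur_phospho if m.residue == "Y"]
        if py:
            target = (
                py[int(rng.integers(len(py)))] if strategy == "seeded-random" else py[0]
            )
            return tuple(_sulfo(m.position) if m is target else m for m in mods)
        taken = {m.position for m in mods}
        free_y = [p for p in y_positions if p not in taken]
        if not free_y:
            return None
        if strategy == "seeded-random":
            drop = cur_phospho[int(rng.integers(len(cur_phospho)))]
            y_pos = int(rng.choice(free_y))
        else:
            drop = cur_phospho[0]
            y_pos = free_y[0]
        return tuple(m for m in mods if m is not drop) + (_sulfo(y_pos),)

    variants: list[tuple[Modification, ...]] = []
    single = _rewrite_once(tuple(psm.modifications))
    if single is None:
        raise ValueError("no feasible sulfation rewrite for this PSM")
    variants.append(single)
    # repeat the replacement when double sulfation is possible
    if len(phosphos) >= 2 and len(y_positions) >= 2:
        double = _rewrite_once(single)
        if double is not None:
            variants.append(double)
    return [
        SpectrumInterpretation(seq, tuple(v), psm.charge) for v in variants
    ]


def original_interpretation(psm: PsmRecord) -> SpectrumInterpretation:
    """The PSM's search-engine interpretation (all modifications retained)."""
    return SpectrumInterpretation(
        psm.peptide_sequence, tuple(psm.modifications), psm.charge
    )
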