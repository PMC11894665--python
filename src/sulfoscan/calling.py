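"""Rule-based annotation of peptidoform mass-error histograms.

Automates the expert read of a peptidoform's fitted mixture: each
component is classed as supporting double sulfation (ss, mean near
-0.019 Da), single sulfation (s, near -0.0095 Da), plain phosphorylation
(p, near 0 Da) or none of these; a histogram type like "ss/s/p" is the
slash-joined set of classes present.  A peptidoform is "Convincing" if
any component supports sulfation, "Undetermined" if a component sits in
the ambiguous (-0.006, -0.004) Da band, otherwise "Not Convincing".
Convincing calls are crossed with sulfation-linked biological context
(known sY / Golgi / secreted / transmembrane annotations) to shortlist
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import SULFO_PHOSPHO_DELTA
from .gmm import BinAssignment, GmmModel
from .peptidoform import Peptidoform

CLASS_ORDER = ("ss", "s", "p")

CONVINCING = "Convincing"
UNDETERMINED = "Undetermined"
NOT_CONVINCING = "Not Convincing"

NO_PRIOR = "No prior knowledge"

#: custom annotation term -> context label shown in candidate tables
CONTEXT_LABELS = {
    "known_sY": "Sulfated",
    "Golgi": "Golgi",
    "Secreted": "Secreted",
    "Transmembrane": "Transmembrane",
}


@dataclass(frozen=True)
class CallingThresholds:
    """Numeric criteria replacing the manual histogram read.

    ``center_tolerance`` quantifies "centered near" the expected sulfation
    shifts; ``p_tolerance`` is the wider band accepted as plain
    phosphorylation; ``undetermined_range`` is the ambiguous band between
    an s and a p component.  ``wide_sd`` is reported but not used as a
    gate by default.
    """

    s_center: float = -SULFO_PHOSPHO_DELTA  # -0.009516 Da
    ss_center: float = -2.0 * SULFO_PHOSPHO_DELTA  # -0.019032 Da
    center_tolerance: float = 0.002
    p_tolerance: float = 0.004
    undetermined_range: tuple[float, float] = (-0.006, -0.004)
    wide_sd: float = 0.004

    def __post_init__(self) -> None:
        lo, hi = self.undetermined_range
        if not (lo < hi < 0):
            raise ValueError("undetermined_range must satisfy lower < upper < 0")
        if self.center_tolerance <= 0 or self.p_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class HistogramCall:
    peptidoform_id: str
    label: str
    histogram_type: str
    component_classes: list[str]
    context: set[str] = field(default_factory=set)
    is_candidate: bool = False


def classify_components(
    model: GmmModel, thresholds: CallingThresholds = CallingThresholds()
) -> tuple[list[str], str]:
    """Class each mixture component as ss / s / p / other; derive the type.

    The histogram type lists the distinct classes present (excluding
    "other") in the fixed order ss, s, p, joined by "/".
    """
    classes = []
    for _, mean, _ in model.components:
        if abs(mean - thresholds.ss_center) <= thresholds.center_tolerance:
            classes.append("ss")
        elif abs(mean - thresholds.s_center) <= thresholds.center_tolerance:
            classes.append("s")
        elif abs(mean) <= thresholds.p_tolerance:
            classes.append("p")
        else:
            classes.append("other")
    present = set(classes)
    histogram_type = "/".join(c for c in CLASS_ORDER if c in present)
    return classes, histogram_type


def score_histogram(
    model: GmmModel, thresholds: CallingThresholds = CallingThresholds()
) -> HistogramCall:
    """Label a fitted model Convincing / Undetermined / Not Convincing.

    Convincing: any component classed s or ss.  Undetermined: otherwise,
    some component mean inside the ambiguous band; these always fall
    between an s and a p profile, so their type is reported as "s/p".
    """
    classes, histogram_type = classify_components(model, thresholds)
    if any(c in ("s", "ss") for c in classes):
        label = CONVINCING
    else:
        lo, hi = thresholds.undetermined_range
        if any(lo < mean < hi for _, mean, _ in model.components):
            label = UNDETERMINED
            histogram_type = "s/p"
        else:
            label = NOT_CONVINCING
    return HistogramCall(
        peptidoform_id="",
        label=label,
        histogram_type=histogram_type,
        component_classes=classes,
    )


def contextualize(
    peptidoform: Peptidoform,
    term_members: Mapping[str, set[str]],
) -> set[str]:
    """Biological-context labels from the peptidoform's protein annotations.

    ``term_members`` maps custom term name -> protein accession set.  A
    peptidoform with no sulfation-linked term membership gets the single
    label "No prior knowledge".
    """
    labels: set[str] = set()
    for term, label in CONTEXT_LABELS.items():
        members = term_members.get(term, set())
        if peptidoform.protein_accessions & set(members):
            labels.add(label)
    if not labels:
        labels = {NO_PRIOR}
    return labels


def call_peptidoform(
    peptidoform: Peptidoform,
    model: GmmModel,
    term_members: Mapping[str, set[str]] | None = None,
    thresholds: CallingThresholds = CallingThresholds(),
    require_context: bool = True,
) -> HistogramCall:
    """Full call for one peptidoform: label, type, context, candidacy.

    Deamidated peptidoforms are never candidates (their apparent shifts
    are dominated by the isotopomer artifact and they are excluded from
    fragment-level assessment).
    """
    call = score_histogram(model, thresholds)
    call.peptidoform_id = peptidoform.id
    call.context = contextualize(peptidoform, term_members or {})
    has_context = call.context != {NO_PRIOR}
    call.is_candidate = (
        call.label == CONVINCING
        and not peptidoform.has_deamidation
        and (has_context or not require_context)
    )
    return call


def shortlist_candidates(
    calls: Sequence[HistogramCall],
    peptidoforms: Mapping[str, Peptidoform],
    require_context: bool = True,
) -> pd.DataFrame:
    """Candidate table: Convincing calls grouped by protein.

    One row per (protein accession, peptide sequence) with the histogram
    types observed, the peptidoform count per type, and context labels.
    """
    rows = []
    for call in calls:
        if call.label != CONVINCING:
            continue
        pf = peptidoforms[call.peptidoform_id]
        if pf.has_deamidation:
            continue
        if require_context and call.context == {NO_PRIOR}:
            continue
        accs = sorted(pf.protein_accessions) or [""]
        for acc in accs:
            rows.append(
                {
                    "protein_accession": acc,
                    "sequence": pf.sequence,
                    "histogram_type": call.histogram_type,
                    "peptidoform_id": pf.id,
                    "context": ";".join(sorted(call.context)),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "protein_accession",
                "sequence",
                "histogram_types",
                "n_peptidoforms",
                "context",
            ]
        )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["protein_accession", "sequence"])
        .agg(
            histogram_types=("histogram_type", lambda s: "; ".join(sorted(set(s)))),
            n_peptidoforms=("peptidoform_id", "nunique"),
            context=("context", "first"),
        )
        .reset_index()
    )
    return grouped.sort_values(["protein_accession", "sequence"]).reset_index(drop=True)


_COMPOSITION_FEATURES = (
    "contains_S",
    "contains_T",
    "contains_Y",
    "has_pS",
    "has_pT",
    "has_pY",
)


def bin_composition(
    assignments: Sequence[BinAssignment],
    peptidoforms: Mapping[str, Peptidoform],
    bin_names: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-bin residue/PTM composition fractions of assigned peptidoforms.

    For each bin: the fraction of assigned peptidoforms containing S/T/Y,
    carrying pS/pT/pY, and — among pT-containing peptidoforms — the
    fraction that also contains a Y.  Empty bins get NaN fractions, not
    zeros.
    """
    from .gmm import standard_bins

    names = list(bin_names) if bin_names is not None else [b.name for b in standard_bins()]
    by_bin: dict[str, list[Peptidoform]] = {name: [] for name in names}
    for a in assignments:
        for name in a.assigned_bins:
            if name in by_bin:
                by_bin[name].append(peptidoforms[a.peptidoform_id])
    rows = []
    for name in names:
        members = by_bin[name]
        n = len(members)
        row: dict[str, object] = {"bin": name, "n_peptidoforms": n}
        for feat in _COMPOSITION_FEATURES:
            row[f"frac_{feat}"] = (
                float(np.mean([getattr(pf, feat) for pf in members])) if n else np.nan
            )
        pt = [pf for pf in members if pf.has_pT]
        row["frac_pT_with_Y"] = (
            float(np.mean([pf.contains_Y for pf in pt])) if pt else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
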