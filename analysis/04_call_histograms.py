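#!/usr/bin/env python
"""Automated histogram calling for Y-containing peptidoforms assigned to a
Bin of Interest: label each fitted mixture Convincing / Undetermined /
Not Convincing, derive its ss/s/p histogram type, attach biological
context from the custom annotation terms, and shortlist candidates.

Writes results/calls.tsv and results/candidates.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from sulfoscan import build_custom_terms, call_peptidoform, shortlist_candidates
from sulfoscan.pipeline import read_model_report


def load_peptidoforms(path):
    """Light-weight peptidoform stand-ins from the summary table."""
    from sulfoscan.peptidoform import Peptidoform

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = {}
    for row in df.itertuples(index=False):
        comp = {}
        if row.has_pY:
            comp[("Phospho", "Y")] = 1
        if row.has_pS:
            comp[("Phospho", "S")] = 1
        if row.has_pT:
            comp[("Phospho", "T")] = 1
        if row.has_deamidation:
            comp[("Deamidated", "N")] = 1
        pf = Peptidoform(
            id=row.peptidoform_id,
            sequence=row.sequence,
            mod_composition=comp,
            protein_accessions=set(
                a for a in str(row.protein_accessions).split(";") if a
            ),
        )
        out[pf.id] = pf
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--models", default="results/gmm_models.tsv")
    ap.add_argument("--peptidoforms", default="results/peptidoforms.tsv")
    ap.add_argument("--annotations", default="results/build/annotations.tsv")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    outdir = Path(args.outdir)

    models, assignments = read_model_report(args.models)
    peptidoforms = load_peptidoforms(args.peptidoforms)
    terms = build_custom_terms(pd.read_csv(args.annotations, sep="\t", dtype=str))
    term_members = {t: term.members for t, term in terms.items()}

    calls = []
    for a in assignments:
        pf = peptidoforms[a.peptidoform_id]
        if not pf.contains_Y or not any(b.startswith("BOI") for b in a.assigned_bins):
            continue
        calls.append(
            call_peptidoform(pf, models[pf.id], term_members, require_context=True)
        )
    pd.DataFrame(
        [
            {
                "peptidoform_id": c.peptidoform_id,
                "label": c.label,
                "histogram_type": c.histogram_type,
                "context": ";".join(sorted(c.context)),
                "is_candidate": c.is_candidate,
            }
            for c in calls
        ]
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)

    candidates = shortlist_candidates(calls, peptidoforms, require_context=True)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    n_conv = sum(c.label == "Convincing" for c in calls)
    print(
        f"{len(calls)} Y-containing BOI peptidoforms called; "
        f"{n_conv} convincing; {len(candidates)} candidate rows"
    )
    if not candidates.empty:
        print(candidates.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
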