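#!/usr/bin/env python
"""Aggregate calibrated PSMs into peptidoforms, fit 1-3 component Gaussian
mixtures to each robust peptidoform's mass errors, select k by the
strong-evidence BIC rule, and assign peptidoforms to mass-error bins.

Writes results/peptidoforms.tsv, results/gmm_models.tsv and
results/bin_composition.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from sulfoscan import (
    aggregate,
    assign_bins,
    bin_composition,
    filter_robust,
    fit_peptidoform,
)
from sulfoscan.peptidoform import write_summary
from sulfoscan.pipeline import _write_model_report


def load_calibrated(path):
    from sulfoscan import read_psm_table

    records = read_psm_table(path)
    calibrated = pd.read_csv(path, sep="\t")["mass_error_calibrated_da"]
    for r, c in zip(records, calibrated):
        r.mass_error_calibrated = float(c)
    return records


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--psms", default="results/psms_calibrated.tsv")
    ap.add_argument("--protein-map", default="results/build/protein_map.tsv")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = load_calibrated(args.psms)
    pm = pd.read_csv(args.protein_map, sep="\t", dtype=str)
    protein_map = {r.sequence: set(r.accessions.split(";")) for r in pm.itertuples()}
    forms = aggregate(records, protein_map)
    robust = filter_robust(forms)
    print(f"{len(forms)} peptidoforms; {len(robust)} robust (>=3 experiments, >=90 PSMs)")
    write_summary(robust, outdir / "peptidoforms.tsv")

    models, assignments = {}, []
    for pf in robust:
        model = fit_peptidoform(pf.mass_errors, seed=args.seed)
        models[pf.id] = model
        assignments.append(assign_bins(model, peptidoform_id=pf.id))
    _write_model_report(models, assignments, outdir / "gmm_models.tsv")

    by_id = {pf.id: pf for pf in robust}
    comp = bin_composition(assignments, by_id)
    comp.to_csv(outdir / "bin_composition.tsv", sep="\t", index=False)
    n_boi = sum(
        1 for a in assignments if any(b.startswith("BOI") for b in a.assigned_bins)
    )
    k_counts = pd.Series([m.selected_k for m in models.values()]).value_counts().to_dict()
    print(f"selected k counts: {k_counts}")
    print(f"{n_boi} peptidoforms assigned to a BOI; composition:")
    print(comp.to_string(index=False))


if __name__ == "__main__":
    main()
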