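#!/usr/bin/env python
"""Residue-class composition of +/-7-residue windows around tyrosines:
candidate sulfotyrosine sites (convincing histograms) versus all tyrosine
sites covered by modelled peptidoforms.

Writes results/flank_composition.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from sulfoscan import class_composition, extract_flanks, read_fasta


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--peptidoforms", default="results/peptidoforms.tsv")
    ap.add_argument("--calls", default="results/calls.tsv")
    ap.add_argument("--fasta", default="results/build/proteins.fasta")
    ap.add_argument("--out", default="results/flank_composition.tsv")
    args = ap.parse_args()

    proteins = read_fasta(args.fasta)
    pf = pd.read_csv(args.peptidoforms, sep="\t", keep_default_na=False)
    calls = pd.read_csv(args.calls, sep="\t")
    convincing = set(calls.loc[calls["label"] == "Convincing", "peptidoform_id"])

    windows = []
    for row in pf.itertuples(index=False):
        if "Y" not in row.sequence:
            continue
        for acc in str(row.protein_accessions).split(";"):
            seq = proteins.get(acc)
            if not seq:
                continue
            start = seq.find(row.sequence)
            if start < 0:
                continue
            positions = [
                start + i + 1 for i, r in enumerate(row.sequence) if r == "Y"
            ]
            windows += extract_flanks(acc, seq, positions, "background")
            if row.peptidoform_id in convincing:
                windows += extract_flanks(acc, seq, positions, "foreground")

    table = class_composition(windows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)
    print(table.to_string(index=False))
    t = table.set_index("origin")
    if {"foreground", "background"} <= set(t.index):
        print(
            f"acidic flank fraction: foreground "
            f"{100 * t.loc['foreground', 'frac_acidic']:.2f}% vs background "
            f"{100 * t.loc['background', 'frac_acidic']:.2f}%"
        )


if __name__ == "__main__":
    main()
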