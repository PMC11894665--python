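#!/usr/bin/env python
"""Over-representation analysis of the proteins behind BOI- and
DECOY-assigned peptidoforms against the fitted-model background, using
the five custom sulfation-context terms plus the GO-style GMT terms.

Writes results/enrichment_BOI.tsv and results/enrichment_DECOY.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from sulfoscan import build_custom_terms, read_gmt, run_ora
from sulfoscan.enrichment import results_frame
from sulfoscan.pipeline import read_model_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--models", default="results/gmm_models.tsv")
    ap.add_argument("--peptidoforms", default="results/peptidoforms.tsv")
    ap.add_argument("--annotations", default="results/build/annotations.tsv")
    ap.add_argument("--gmt", default="results/build/go_terms.gmt")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    outdir = Path(args.outdir)

    _, assignments = read_model_report(args.models)
    pf = pd.read_csv(args.peptidoforms, sep="\t", keep_default_na=False)
    accs_by_id = {
        r.peptidoform_id: {a for a in str(r.protein_accessions).split(";") if a}
        for r in pf.itertuples(index=False)
    }
    terms = build_custom_terms(pd.read_csv(args.annotations, sep="\t", dtype=str))
    terms.update(read_gmt(args.gmt))
    background = sorted(set().union(*accs_by_id.values()))

    for group in ("BOI", "DECOY"):
        fg = sorted(
            {
                acc
                for a in assignments
                if any(b.startswith(group) for b in a.assigned_bins)
                for acc in accs_by_id[a.peptidoform_id]
            }
        )
        results = run_ora(fg, background, terms, q_cutoff=None, min_set_size=1)
        table = results_frame(results)
        table.to_csv(outdir / f"enrichment_{group}.tsv", sep="\t", index=False)
        custom = table[table["category"] == "custom"]
        print(f"{group}: foreground {len(fg)} of {len(background)} proteins")
        print(custom.to_string(index=False))


if __name__ == "__main__":
    main()
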