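#!/usr/bin/env python
"""Dual-hypothesis MS2 assessment of candidate sulfopeptides.

For a sample of candidate (convincing, non-deamidated) peptidoforms, take
one PSM each, build the original phospho USI and the rewritten Y{Sulfo}
alternative, generate a synthetic spectrum under the full-neutral-loss
hypothesis, and score both interpretations against it.

Writes results/ms2_assessment.tsv with USIs, per-hypothesis metrics and
the verdict.
"""

import argparse
from pathlib import Path

import pandas as pd

from sulfoscan import (
    build_usi,
    compare_hypotheses,
    filter_fdr,
    original_interpretation,
    read_psm_table,
)
from sulfoscan.simulate import generate_spectrum
from sulfoscan.spectra import alternative_interpretations


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--psms", default="results/build/psms.tsv")
    ap.add_argument("--calls", default="results/calls.tsv")
    ap.add_argument("--out", default="results/ms2_assessment.tsv")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--max-peptidoforms", type=int, default=10)
    args = ap.parse_args()

    calls = pd.read_csv(args.calls, sep="\t")
    wanted = set(
        calls.loc[calls["is_candidate"] == True, "peptidoform_id"]  # noqa: E712
    )
    records = filter_fdr(read_psm_table(args.psms))

    from sulfoscan import make_peptidoform_id

    by_id = {}
    for r in records:
        pid = make_peptidoform_id(r.peptide_sequence, r.modifications)
        if pid in wanted and pid not in by_id:
            by_id[pid] = r

    rows = []
    for i, (pid, psm) in enumerate(sorted(by_id.items())[: args.max_peptidoforms]):
        try:
            alts = alternative_interpretations(psm)
        except ValueError as exc:
            rows.append({"peptidoform_id": pid, "verdict": f"refused: {exc}"})
            continue
        sulfo_interp = alts[0]
        phospho_interp = original_interpretation(psm)
        peaks = generate_spectrum(
            sulfo_interp, "full-neutral-loss", noise_fraction=0.05, seed=args.seed + i
        )
        v = compare_hypotheses(peaks, sulfo_interp, phospho_interp)
        rows.append(
            {
                "peptidoform_id": pid,
                "usi_original": build_usi(psm, phospho_interp),
                "usi_alternative": build_usi(psm, sulfo_interp),
                "sulfo_tic_fraction": round(v.sulfo.tic_fraction_annotated, 4),
                "phospho_tic_fraction": round(v.phospho.tic_fraction_annotated, 4),
                "sulfo_residues_supported": round(v.sulfo.residues_supported, 4),
                "phospho_residues_supported": round(v.phospho.residues_supported, 4),
                "verdict": v.verdict,
            }
        )

    table = pd.DataFrame(rows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)
    if not table.empty:
        print(table[["peptidoform_id", "verdict"]].to_string(index=False))
        print(f"wrote {args.out}")
    else:
        print("no candidate peptidoforms to assess")


if __name__ == "__main__":
    main()
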