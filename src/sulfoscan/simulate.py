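"""Synthetic phosphoproteome build generator with known ground truth.

Emulates the statistical structure of a large, per-run-miscalibrated PSM
collection: each synthetic peptidoform belongs to a hidden class —

- ``p``            correctly assigned phosphorylation (mass error ~ 0 Da)
- ``s``            one sulfotyrosine misassigned as phospho (~ -0.0095 Da)
- ``ss``           two sulfotyrosines misassigned (~ -0.019 Da)
- ``s/p``          sometimes sulfated, sometimes phosphorylated (mixture)
- ``ss/s/p``       three-way mixture
- ``deam_artifact`` +1-isotopomer selection plus spurious deamidation
                    (net ~ +0.0193 Da)
- ``decoy_shift``   mirror-image positive shift control (~ +0.0095 Da)

PSMs inherit a per-run calibration offset, Gaussian scatter, and q-values
with a configurable failing fraction.  Proteins carry the peptide with
acidity-biased flanks around true sulfation sites, and sulfated proteins
are preferentially tagged with sulfation-linked annotation terms, so every
downstream stage (recalibration, GMM binning, calling, enrichment, flank
composition, MS2 assessment) has a planted truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEAMIDATION_ARTIFACT_SHIFT,
    MODIFICATION_MASSES,
    SULFO_PHOSPHO_DELTA,
)
from .ingest import Modification, PsmRecord, write_psm_table
from .peptidoform import make_peptidoform_id
from .spectra import SpectrumInterpretation, theoretical_fragments

CLASSES = ("p", "s", "ss", "s/p", "ss/s/p", "deam_artifact", "decoy_shift")

_RESIDUE_POOL = "ACDEFGHIKLMNPQSTVWY"  # no internal R/K beyond the terminus


def class_means(true_class: str) -> list[float]:
    """True component means (Da) for a peptidoform class."""
    d = SULFO_PHOSPHO_DELTA
    return {
        "p": [0.0],
        "s": [-d],
        "ss": [-2 * d],
        "s/p": [-d, 0.0],
        "ss/s/p": [-2 * d, -d, 0.0],
        "deam_artifact": [DEAMIDATION_ARTIFACT_SHIFT],
        "decoy_shift": [SULFO_PHOSPHO_DELTA],
    }[true_class]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic build (all units Da where masses)."""

    seed: int = 0
    n_peptidoforms: int = 200
    psm_count_range: tuple[int, int] = (90, 500)
    n_runs: int = 40
    n_experiments: int = 8
    run_offset_range: tuple[float, float] = (-0.01, 0.01)
    error_sd: float = 0.002
    #: correctly assigned phosphorylation dominates; positive-shift artifact
    #: classes outnumber the sulfated ones (as in real builds, where DECOY
    #: bins are far more populated than BOIs), which also keeps the per-run
    #: error median — and hence the recalibration — essentially unbiased
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "p": 0.60,
            "s": 0.08,
            "ss": 0.04,
            "s/p": 0.06,
            "ss/s/p": 0.03,
            "deam_artifact": 0.12,
            "decoy_shift": 0.07,
        }
    )
    mixture_weights: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "s/p": (0.5, 0.5),
            "ss/s/p": (1 / 3, 1 / 3, 1 / 3),
        }
    )
    peptide_length_range: tuple[int, int] = (7, 30)
    flank_length: int = 10
    acidic_flank_bias: float = 0.3
    #: probability that a sulfated-class peptidoform is reported with the
    #: phospho on a T instead of the true sY (search-engine ambiguity)
    pt_misassign_prob: float = 0.1
    q_fail_fraction: float = 0.1
    annotation_probs: dict[str, float] = field(
        default_factory=lambda: {
            "known_sY": 0.6,
            "Secreted": 0.4,
            "Golgi": 0.4,
            "Transmembrane": 0.15,
        }
    )
    annotation_background_rate: float = 0.05
    n_go_terms: int = 8
    #: spectrum noise: number of noise peaks as a fraction of true peaks,
    #: and relative intensity scale of noise
    spectrum_noise_fraction: float = 0.05
    spectrum_noise_rel_intensity: float = 0.2

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if self.error_sd <= 0:
            raise ValueError("error_sd must be positive")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")


@dataclass
class TruthRecord:
    """Ground truth for one planted peptidoform."""

    peptidoform_id: str
    true_class: str
    component_means: list[float]
    component_weights: list[float]
    sy_peptide_positions: list[int]  # 1-based within the peptide
    sy_protein_positions: list[int]  # 1-based within the protein
    protein_accession: str
    planted_terms: list[str]
    n_psms_planted: int  # FDR-passing PSMs


@dataclass
class SyntheticBuild:
    """In-memory synthetic build plus writers for the on-disk dialects."""

    config: GeneratorConfig
    psms: list[PsmRecord]
    proteins: dict[str, str]  # accession -> sequence
    protein_map: dict[str, set[str]]  # peptide sequence -> accessions
    annotation_table: pd.DataFrame
    go_terms: dict[str, tuple[str, set[str]]]  # term_id -> (name, members)
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "peptidoform_id": t.peptidoform_id,
                    "true_class": t.true_class,
                    "component_means": ";".join(repr(m) for m in t.component_means),
                    "component_weights": ";".join(repr(w) for w in t.component_weights),
                    "sy_peptide_positions": ";".join(map(str, t.sy_peptide_positions)),
                    "sy_protein_positions": ";".join(map(str, t.sy_protein_positions)),
                    "protein_accession": t.protein_accession,
                    "planted_terms": ";".join(t.planted_terms),
                    "n_psms_planted": t.n_psms_planted,
                }
                for t in self.truth
            ]
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write psms.tsv, proteins.fasta, annotations.tsv, go_terms.gmt,
        protein_map.tsv and truth.tsv; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "psms": outdir / "psms.tsv",
            "fasta": outdir / "proteins.fasta",
            "annotations": outdir / "annotations.tsv",
            "gmt": outdir / "go_terms.gmt",
            "protein_map": outdir / "protein_map.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_psm_table(self.psms, paths["psms"])
        with open(paths["fasta"], "w") as fh:
            for acc in sorted(self.proteins):
                fh.write(f">{acc} synthetic protein\n{self.proteins[acc]}\n")
        self.annotation_table.to_csv(paths["annotations"], sep="\t", index=False)
        with open(paths["gmt"], "w") as fh:
            for term_id in sorted(self.go_terms):
                name, members = self.go_terms[term_id]
                fh.write("\t".join([term_id, name] + sorted(members)) + "\n")
        pd.DataFrame(
            [
                {"sequence": seq, "accessions": ";".join(sorted(accs))}
                for seq, accs in sorted(self.protein_map.items())
            ]
        ).to_csv(paths["protein_map"], sep="\t", index=False)
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _apportion(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment so class counts are exact."""
    raw = {c: proportions.get(c, 0.0) * n for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _draw_sequence(rng: np.random.Generator, length: int, n_y: int, need: str = "") -> str:
    """Tryptic-like peptide: uniform random residues (tyrosine included at
    its natural uniform rate), K/R terminus, at least ``n_y`` tyrosines,
    plus any residues listed in ``need``."""
    while True:
        body = rng.choice(list(_RESIDUE_POOL), size=length - 1)
        seq = list(body) + [str(rng.choice(["K", "R"]))]
        interior = list(range(length - 1))
        if n_y > len(interior):
            raise ValueError("peptide too short for requested tyrosine count")
        missing_y = n_y - sum(1 for r in seq[:-1] if r == "Y")
        if missing_y > 0:
            free = [i for i in interior if seq[i] != "Y"]
            for slot in rng.choice(free, size=missing_y, replace=False):
                seq[int(slot)] = "Y"
        s = "".join(seq)
        if all(r in s for r in need):
            return s


def _plant_mods(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    true_class: str,
    seq: str,
) -> tuple[list[Modification], list[int]]:
    """Reported modifications and the true sY peptide positions for a class."""
    y_pos = [i + 1 for i, r in enumerate(seq) if r == "Y"]
    st_pos = [i + 1 for i, r in enumerate(seq) if r in "ST"]
    t_pos = [i + 1 for i, r in enumerate(seq) if r == "T"]

    def phospho(p: int) -> Modification:
        return Modification(p, seq[p - 1], "Phospho", MODIFICATION_MASSES["Phospho"])

    if true_class in ("s", "s/p"):
        sy = [int(rng.choice(y_pos))]
        # the search engine sometimes parks the phospho on a T instead
        if t_pos and rng.random() < cfg.pt_misassign_prob:
            mods = [phospho(int(rng.choice(t_pos)))]
        else:
            mods = [phospho(sy[0])]
        return mods, sy
    if true_class in ("ss", "ss/s/p"):
        sy = sorted(int(p) for p in rng.choice(y_pos, size=2, replace=False))
        return [phospho(p) for p in sy], sy
    if true_class == "deam_artifact":
        nq_pos = [i + 1 for i, r in enumerate(seq) if r in "NQ"]
        deam_p = int(rng.choice(nq_pos))
        mods = [
            phospho(int(rng.choice(st_pos))),
            Modification(
                deam_p, seq[deam_p - 1], "Deamidated", MODIFICATION_MASSES["Deamidated"]
            ),
        ]
        return mods, []
    # p and decoy_shift: plain phosphorylation on S or T
    return [phospho(int(rng.choice(st_pos)))], []


def generate_build(config: GeneratorConfig | None = None) -> SyntheticBuild:
    """Generate a full synthetic build; deterministic given the seed."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    counts = _apportion(cfg.class_proportions, cfg.n_peptidoforms)
    classes = [c for c in CLASSES for _ in range(counts[c])]
    rng.shuffle(classes)

    # runs grouped under experiments; per-run miscalibration offsets
    run_ids = [f"run{j:03d}" for j in range(cfg.n_runs)]
    run_experiment = {
        run: f"exp{j % cfg.n_experiments:02d}" for j, run in enumerate(run_ids)
    }
    run_offsets = dict(
        zip(run_ids, rng.uniform(*cfg.run_offset_range, size=cfg.n_runs))
    )
    runs_by_exp: dict[str, list[str]] = {}
    for run, exp in run_experiment.items():
        runs_by_exp.setdefault(exp, []).append(run)
    experiments = sorted(runs_by_exp)

    psms: list[PsmRecord] = []
    truth: list[TruthRecord] = []
    proteins: dict[str, str] = {}
    protein_map: dict[str, set[str]] = {}
    annotation_rows = []
    scan_counters: dict[str, int] = {run: 0 for run in run_ids}
    seen_sequences: set[str] = set()

    for i, true_class in enumerate(classes):
        acc = f"SSP{i:04d}"
        n_y_needed = {"s": 1, "s/p": 1, "ss": 2, "ss/s/p": 2}.get(true_class, 0)
        need = "N" if true_class == "deam_artifact" else ""
        if true_class in ("p", "decoy_shift", "deam_artifact", "s", "s/p"):
            need += "S"  # guarantee a phospho-acceptor besides Y
        length = int(rng.integers(*cfg.peptide_length_range, endpoint=True))
        for _ in range(200):
            seq = _draw_sequence(rng, length, n_y_needed, need)
            if seq not in seen_sequences:
                break
        else:
            raise RuntimeError("could not draw a fresh peptide sequence")
        seen_sequences.add(seq)
        mods, sy_peptide = _plant_mods(rng, cfg, true_class, seq)
        pid = make_peptidoform_id(seq, mods)

        # protein context: flanks with acidity bias around true sY sites
        def flank(n: int, biased: bool) -> str:
            out = []
            for _ in range(n):
                if biased and rng.random() < cfg.acidic_flank_bias:
                    out.append(str(rng.choice(["D", "E"])))
                else:
                    out.append(str(rng.choice(list(_RESIDUE_POOL))))
            return "".join(out)

        sulfated = len(sy_peptide) > 0
        nflank = flank(cfg.flank_length - 1, sulfated and min(sy_peptide) <= 7) + str(
            rng.choice(["K", "R"])
        )
        cflank = flank(
            cfg.flank_length, sulfated and max(sy_peptide, default=0) >= length - 7
        )
        # acidity bias inside the peptide flanks of the sY site as well
        if sulfated:
            seq_list = list(seq)
            for sy in sy_peptide:
                for j in range(max(0, sy - 8), min(length, sy + 7)):
                    if seq_list[j] in "AVLG" and rng.random() < cfg.acidic_flank_bias:
                        seq_list[j] = str(rng.choice(["D", "E"]))
            new_seq = "".join(seq_list)
            if new_seq != seq and new_seq not in seen_sequences:
                seen_sequences.add(new_seq)
                seq = new_seq
                mods = [
                    Modification(m.position, seq[m.position - 1], m.name, m.mass_delta)
                    if m.position >= 1
                    else m
                    for m in mods
                ]
                pid = make_peptidoform_id(seq, mods)
        protein_seq = nflank + seq + cflank
        proteins[acc] = protein_seq
        protein_map.setdefault(seq, set()).add(acc)
        sy_protein = [cfg.flank_length + p for p in sy_peptide]

        # planted annotations
        planted_terms = []
        for term, p_enriched in cfg.annotation_probs.items():
            p_use = p_enriched if sulfated else cfg.annotation_background_rate
            if rng.random() < p_use:
                planted_terms.append(term)
        annotation_rows.append(
            {
                "accession": acc,
                "protein_name": (
                    f"Golgi-resident synthetic protein {i}"
                    if "Golgi" in planted_terms
                    else f"synthetic protein {i}"
                ),
                "subcellular_location": "Secreted." if "Secreted" in planted_terms else "",
                "transmembrane": "TRANSMEM 1..20" if "Transmembrane" in planted_terms else "",
                "known_sY": "1" if "known_sY" in planted_terms else "0",
            }
        )

        # PSM scatter: per-class mixture + per-run offset + q-values
        means = class_means(true_class)
        weights = list(cfg.mixture_weights.get(true_class, (1.0,) * len(means)))
        n_pass = int(rng.integers(*cfg.psm_count_range, endpoint=True))
        n_fail = int(round(n_pass * cfg.q_fail_fraction / (1 - cfg.q_fail_fraction)))
        n_total = n_pass + n_fail
        fail_flags = np.zeros(n_total, dtype=bool)
        fail_flags[:n_fail] = True
        rng.shuffle(fail_flags)

        n_exp = int(rng.integers(3, min(6, cfg.n_experiments), endpoint=True))
        exp_choice = rng.choice(experiments, size=n_exp, replace=False)
        available_runs = [r for e in exp_choice for r in runs_by_exp[e]]

        comp = rng.choice(len(means), size=n_total, p=np.array(weights) / sum(weights))
        draws = rng.normal(np.array(means)[comp], cfg.error_sd)
        for j in range(n_total):
            run = str(rng.choice(available_runs))
            scan_counters[run] += 1
            q = (
                float(rng.uniform(0.011, 0.5))
                if fail_flags[j]
                else float(rng.uniform(0.0, 0.0099))
            )
            psms.append(
                PsmRecord(
                    collection_id="PXDSYN001",
                    dataset_id="DS01",
                    experiment_id=run_experiment[run],
                    run_id=run,
                    scan_number=scan_counters[run],
                    peptide_sequence=seq,
                    modifications=list(mods),
                    charge=int(rng.integers(2, 4, endpoint=True)),
                    mass_error_raw=float(draws[j] + run_offsets[run]),
                    q_value=q,
                    instrument="SyntheticOrbitrap",
                )
            )
        truth.append(
            TruthRecord(
                peptidoform_id=pid,
                true_class=true_class,
                component_means=means,
                component_weights=[w / sum(weights) for w in weights],
                sy_peptide_positions=sy_peptide,
                sy_protein_positions=sy_protein,
                protein_accession=acc,
                planted_terms=planted_terms,
                n_psms_planted=n_pass,
            )
        )

    # GO-style terms: random memberships for interface plumbing
    go_terms = {}
    accs = sorted(proteins)
    for g in range(cfg.n_go_terms):
        size = int(rng.integers(5, max(6, len(accs) // 4), endpoint=True))
        members = set(rng.choice(accs, size=min(size, len(accs)), replace=False))
        go_terms[f"GO:{7000000 + g}"] = (f"synthetic process {g}", members)

    rng.shuffle(psms)
    return SyntheticBuild(
        config=cfg,
        psms=psms,
        proteins=proteins,
        protein_map=protein_map,
        annotation_table=pd.DataFrame(annotation_rows),
        go_terms=go_terms,
        truth=truth,
    )


def generate_spectrum(
    interpretation: SpectrumInterpretation,
    hypothesis: str = "full-neutral-loss",
    noise_fraction: float = 0.0,
    noise_rel_intensity: float = 0.2,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Synthetic MS2 peak list for an interpretation under a hypothesis.

    ``hypothesis="full-neutral-loss"`` places peaks at the fragment m/z of
    the labile (curly-brace) reading; ``"retained"`` places them at the
    mass-retaining reading (every modification kept on fragments).  True
    peaks get log-normal intensities; ``noise_fraction`` adds that
    proportion of uniform random noise peaks.
    """
    if hypothesis not in ("full-neutral-loss", "retained"):
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if hypothesis == "retained":
        # reinterpret labile modifications as mass-retaining (same mass)
        from .spectra import LABILE_MODS

        frag_interp = SpectrumInterpretation(
            interpretation.sequence,
            tuple(
                Modification(
                    m.position,
                    m.residue,
                    f"{m.name}-retained",
                    MODIFICATION_MASSES.get(m.name, m.mass_delta),
                )
                if m.name in LABILE_MODS
                else m
                for m in interpretation.modifications
            ),
            interpretation.charge,
        )
    else:
        frag_interp = interpretation
    rng = np.random.default_rng(seed)
    theo = theoretical_fragments(frag_interp)
    peaks = [(mz, float(rng.lognormal(mean=3.0, sigma=0.5))) for _, _, _, mz in theo]
    n_noise = int(round(noise_fraction * len(peaks)))
    if n_noise:
        lo = min(mz for mz, _ in peaks) - 50.0
        hi = max(mz for mz, _ in peaks) + 50.0
        for _ in range(n_noise):
            peaks.append(
                (
                    float(rng.uniform(lo, hi)),
                    float(rng.lognormal(mean=3.0, sigma=0.5)) * noise_rel_intensity,
                )
            )
    return sorted(peaks)


def write_mgf(
    spectra: Sequence[tuple[str, SpectrumInterpretation, Sequence[tuple[float, float]]]],
    path: str | Path,
) -> None:
    """Write (title, interpretation, peaks) triples as an MGF peak list."""
    from pyteomics import mgf as _pmgf

    entries = []
    for title, interp, peaks in spectra:
        mzs = np.array([p[0] for p in peaks])
        intens = np.array([p[1] for p in peaks])
        entries.append(
            {
                "m/z array": mzs,
                "intensity array": intens,
                "params": {
                    "title": title,
                    "pepmass": interp.precursor_mz(),
                    "charge": interp.charge,
                },
            }
        )
    _pmgf.write(entries, str(path), file_mode="w")
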