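"""End-to-end pipeline: ingest -> recalibrate -> aggregate -> GMM -> bins
-> composition -> calling -> enrichment -> flank composition.

Each stage reads from / writes to plain TSVs so stages can be re-run and
inspected independently; ``run_pipeline`` chains them and logs the
peptidoform counts surviving each filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calling as _calling
from . import context as _context
from . import enrichment as _enrichment
from . import gmm as _gmm
from . import ingest as _ingest
from . import peptidoform as _peptidoform

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds with their standard defaults, plus IO paths."""

    psm_table: str = ""
    protein_map: str = ""
    fasta: str = ""
    annotations: str = ""
    gmt: str = ""
    outdir: str = "results"
    seed: int = 0

    q_threshold: float = 0.01
    min_experiments: int = 3
    min_psms: int = 90
    delta_bic: float = 10.0
    auc_threshold: float = 0.15
    ora_q_cutoff: float = 0.1
    ora_min_set_size: int = 1
    match_tolerance: float = 0.05
    flank_w: int = 7
    center_tolerance: float = 0.002
    p_tolerance: float = 0.004
    undetermined_range: tuple[float, float] = (-0.006, -0.004)
    require_context: bool = True

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "undetermined_range" in data:
            data["undetermined_range"] = tuple(data["undetermined_range"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineReport:
    """Artifacts and bookkeeping from one pipeline run."""

    config: PipelineConfig
    stage_counts: dict[str, int]
    peptidoforms: dict[str, _peptidoform.Peptidoform]
    models: dict[str, _gmm.GmmModel]
    assignments: list[_gmm.BinAssignment]
    calls: list[_calling.HistogramCall]
    composition: pd.DataFrame
    candidates: pd.DataFrame
    enrichment: dict[str, pd.DataFrame]  # bin group -> results table
    flank_composition: pd.DataFrame | None


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage on the configured inputs and write the reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    records = _ingest.read_psm_table(config.psm_table)
    counts["psms_read"] = len(records)
    records = _ingest.filter_fdr(records, config.q_threshold)
    counts["psms_fdr"] = len(records)
    records = _ingest.recalibrate(records)
    records = _ingest.filter_phospho(records)
    counts["psms_phospho"] = len(records)

    protein_map: dict[str, set[str]] = {}
    if config.protein_map:
        pm = pd.read_csv(config.protein_map, sep="\t", dtype=str)
        protein_map = {
            row.sequence: set(str(row.accessions).split(";"))
            for row in pm.itertuples()
        }
    forms = _peptidoform.aggregate(records, protein_map)
    counts["peptidoforms"] = len(forms)
    robust = _peptidoform.filter_robust(
        forms, config.min_experiments, config.min_psms
    )
    counts["peptidoforms_robust"] = len(robust)
    _peptidoform.write_summary(robust, outdir / "peptidoforms.tsv")

    thresholds = _calling.CallingThresholds(
        center_tolerance=config.center_tolerance,
        p_tolerance=config.p_tolerance,
        undetermined_range=config.undetermined_range,
    )
    bins = _gmm.standard_bins()
    models: dict[str, _gmm.GmmModel] = {}
    assignments: list[_gmm.BinAssignment] = []
    for pf in robust:
        model = _gmm.fit_peptidoform(
            pf.mass_errors, seed=config.seed, delta=config.delta_bic
        )
        models[pf.id] = model
        assignments.append(
            _gmm.assign_bins(model, bins, config.auc_threshold, peptidoform_id=pf.id)
        )
    counts["peptidoforms_boi"] = sum(
        1
        for a in assignments
        if any(b.startswith("BOI") for b in a.assigned_bins)
    )
    _write_model_report(models, assignments, outdir / "gmm_models.tsv")

    by_id = {pf.id: pf for pf in robust}
    composition = _calling.bin_composition(assignments, by_id)
    composition.to_csv(outdir / "bin_composition.tsv", sep="\t", index=False)

    # custom annotation terms + context labels
    term_members: dict[str, set[str]] = {}
    custom_terms: _enrichment.TermMap = {}
    if config.annotations:
        ann = pd.read_csv(config.annotations, sep="\t", dtype=str)
        custom_terms = _enrichment.build_custom_terms(ann)
        term_members = {t: term.members for t, term in custom_terms.items()}

    boi_assigned = {
        a.peptidoform_id
        for a in assignments
        if any(b.startswith("BOI") for b in a.assigned_bins)
    }
    calls = []
    for pid in sorted(boi_assigned):
        pf = by_id[pid]
        if not pf.contains_Y:
            continue
        calls.append(
            _calling.call_peptidoform(
                pf,
                models[pid],
                term_members,
                thresholds,
                require_context=config.require_context,
            )
        )
    counts["calls_convincing"] = sum(
        1 for c in calls if c.label == _calling.CONVINCING
    )
    candidates = _calling.shortlist_candidates(
        calls, by_id, require_context=config.require_context
    )
    counts["candidates"] = len(candidates)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    # per-bin-group enrichment against the fitted-model background
    terms: _enrichment.TermMap = dict(custom_terms)
    if config.gmt:
        terms.update(_enrichment.read_gmt(config.gmt))
    background = sorted(
        {acc for pf in robust for acc in pf.protein_accessions}
    )
    enrichment_tables: dict[str, pd.DataFrame] = {}
    if terms and background:
        for group in ("BOI", "DECOY"):
            fg = sorted(
                {
                    acc
                    for a in assignments
                    if any(b.startswith(group) for b in a.assigned_bins)
                    for acc in by_id[a.peptidoform_id].protein_accessions
                }
            )
            results = _enrichment.run_ora(
                fg,
                background,
                terms,
                q_cutoff=None,
                min_set_size=config.ora_min_set_size,
            )
            table = _enrichment.results_frame(results)
            enrichment_tables[group] = table
            table.to_csv(outdir / f"enrichment_{group}.tsv", sep="\t", index=False)

    # acidity of flanks around candidate Y sites vs all modelled Y sites
    flank_composition = None
    if config.fasta:
        flank_composition = _flank_stage(
            config, robust, by_id, calls, outdir
        )

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(
            {"config_hash": config.config_hash(), "stage_counts": counts}, fh, indent=2
        )
    logger.info("pipeline stage counts: %s", counts)
    return PipelineReport(
        config=config,
        stage_counts=counts,
        peptidoforms=by_id,
        models=models,
        assignments=assignments,
        calls=calls,
        composition=composition,
        candidates=candidates,
        enrichment=enrichment_tables,
        flank_composition=flank_composition,
    )


def _protein_y_sites(
    pf: _peptidoform.Peptidoform, proteins: dict[str, str]
) -> list[tuple[str, int]]:
    """(accession, 1-based Y position) for every Y of the peptide within
    each mapped protein."""
    sites = []
    for acc in sorted(pf.protein_accessions):
        seq = proteins.get(acc)
        if seq is None:
            continue
        start = seq.find(pf.sequence)
        if start < 0:
            continue
        for i, r in enumerate(pf.sequence):
            if r == "Y":
                sites.append((acc, start + i + 1))
    return sites


def _flank_stage(config, robust, by_id, calls, outdir) -> pd.DataFrame:
    proteins = _context.read_fasta(config.fasta)
    convincing_ids = {
        c.peptidoform_id for c in calls if c.label == _calling.CONVINCING
    }
    windows = []
    for pf in robust:
        if not pf.contains_Y:
            continue
        origin = "foreground" if pf.id in convincing_ids else None
        for acc, pos in _protein_y_sites(pf, proteins):
            windows.extend(
                _context.extract_flanks(
                    acc, proteins[acc], [pos], origin="background", w=config.flank_w
                )
            )
            if origin:
                windows.extend(
                    _context.extract_flanks(
                        acc, proteins[acc], [pos], origin="foreground", w=config.flank_w
                    )
                )
    if not windows:
        return pd.DataFrame()
    table = _context.class_composition(windows)
    table.to_csv(outdir / "flank_composition.tsv", sep="\t", index=False)
    return table


def _write_model_report(models, assignments, path) -> None:
    rows = []
    assign_by_id = {a.peptidoform_id: a for a in assignments}
    for pid, model in models.items():
        a = assign_by_id[pid]
        rows.append(
            {
                "peptidoform_id": pid,
                "selected_k": model.selected_k,
                "n_psms": model.n_samples,
                "components": ";".join(
                    f"{w:.4f}:{mu:.6f}:{sd:.6f}" for w, mu, sd in model.components
                ),
                "bic_1": model.bic_by_k[1],
                "bic_2": model.bic_by_k[2],
                "bic_3": model.bic_by_k[3],
                "assigned_bins": ";".join(sorted(a.assigned_bins)),
                **{f"auc_{name}": auc for name, auc in a.auc_by_bin.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_model_report(path: str | Path):
    """Inverse of the model report writer: reconstruct per-peptidoform
    GmmModel and BinAssignment objects from gmm_models.tsv."""
    df = pd.read_csv(path, sep="\t")
    models: dict[str, _gmm.GmmModel] = {}
    assignments: list[_gmm.BinAssignment] = []
    bin_names = [b.name for b in _gmm.standard_bins()]
    for row in df.itertuples(index=False):
        components = [
            tuple(float(v) for v in part.split(":"))
            for part in row.components.split(";")
        ]
        models[row.peptidoform_id] = _gmm.GmmModel(
            components=components,
            bic_by_k={1: row.bic_1, 2: row.bic_2, 3: row.bic_3},
            selected_k=int(row.selected_k),
            n_samples=int(row.n_psms),
            log_likelihood=float("nan"),
        )
        assigned = (
            set(str(row.assigned_bins).split(";"))
            if isinstance(row.assigned_bins, str) and row.assigned_bins
            else set()
        )
        assignments.append(
            _gmm.BinAssignment(
                peptidoform_id=row.peptidoform_id,
                auc_by_bin={name: getattr(row, f"auc_{name}") for name in bin_names},
                assigned_bins=assigned,
                auc_threshold=0.15,
            )
        )
    return models, assignments


def export_histogram(
    peptidoform: _peptidoform.Peptidoform,
    model: _gmm.GmmModel,
    path: str | Path,
    bin_width: float = 0.001,
    density_points: int = 200,
) -> None:
    """Export binned mass-error counts plus fitted density samples as TSV,
    for external plotting of per-peptidoform histogram panels."""
    import numpy as np

    x = np.asarray(peptidoform.mass_errors)
    lo, hi = -0.0225, 0.0225
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    grid = np.linspace(lo, hi, density_points)
    dens = model.pdf(grid)
    hist = pd.DataFrame(
        {"kind": "histogram", "x": edges[:-1], "value": counts.astype(float)}
    )
    curve = pd.DataFrame({"kind": "density", "x": grid, "value": dens})
    pd.concat([hist, curve]).to_csv(path, sep="\t", index=False)
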