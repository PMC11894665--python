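"""Shared fixtures: a default synthetic build run through the pipeline.

The full-scale build (200 peptidoforms, >=90 PSMs each) is expensive to
fit, so it is generated and modelled once per session and shared by every
test that checks recovery of the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from sulfoscan import (
    GeneratorConfig,
    aggregate,
    assign_bins,
    filter_fdr,
    filter_phospho,
    filter_robust,
    fit_peptidoform,
    generate_build,
    recalibrate,
)

BUILD_SEED = 1


@dataclass
class FittedBuild:
    build: object
    peptidoforms: list
    truth: dict
    models: dict
    assignments: dict

    def by_class(self, true_class: str) -> list:
        return [
            pf
            for pf in self.peptidoforms
            if self.truth[pf.id].true_class == true_class
        ]


@pytest.fixture(scope="session")
def default_build():
    """The default-condition synthetic build, before any modelling."""
    return generate_build(GeneratorConfig(seed=BUILD_SEED))


@pytest.fixture(scope="session")
def fitted_build(default_build) -> FittedBuild:
    """Default build taken through FDR -> recalibration -> aggregation ->
    robustness filter -> per-peptidoform GMM fits and bin assignment."""
    records = filter_phospho(recalibrate(filter_fdr(default_build.psms)))
    forms = filter_robust(aggregate(records, default_build.protein_map))
    truth = {t.peptidoform_id: t for t in default_build.truth}
    models = {pf.id: fit_peptidoform(pf.mass_errors, seed=0) for pf in forms}
    assignments = {
        pf.id: assign_bins(models[pf.id], peptidoform_id=pf.id) for pf in forms
    }
    return FittedBuild(
        build=default_build,
        peptidoforms=forms,
        truth=truth,
        models=models,
        assignments=assignments,
    )
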