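"""Shared fixtures: one synthetic genome bundle and one full pipeline run."""

from dataclasses import dataclass

import pytest

from circorf.pipeline import PipelineConfig, run_pipeline
from circorf.simulate import (
    FixtureConfig,
    PlantedTruth,
    make_genome,
    make_proteome,
    simulate_backsplice_reads,
    simulate_rpf_reads,
)

FIXTURE_SEED = 11


@dataclass
class Bundle:
    config: FixtureConfig
    genome_records: list
    models: list
    truth: PlantedTruth
    genome: dict


@pytest.fixture(scope="session")
def bundle() -> Bundle:
    cfg = FixtureConfig(seed=FIXTURE_SEED)
    records, models, truth = make_genome(cfg)
    return Bundle(cfg, records, models, truth, {r.id: r.seq for r in records})


@pytest.fixture(scope="session")
def bs_reads(bundle):
    return simulate_backsplice_reads(bundle.truth, bundle.config)


@pytest.fixture(scope="session")
def rpf_reads(bundle):
    return simulate_rpf_reads(bundle.truth, bundle.config)


@pytest.fixture(scope="session")
def proteome(bundle):
    return make_proteome(bundle.models, bundle.genome)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_run")
    cfg = PipelineConfig(seed=FIXTURE_SEED, outdir=str(outdir))
    summary = run_pipeline(cfg)
    return cfg, summary
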