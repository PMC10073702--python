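"""Shared fixtures: a small synthetic community for unit tests and the
default-scale community (10 target + 12 neighbor genomes, 20 samples) for
the end-to-end checks. Both are generated once per session."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from sigbin.pipeline import PipelineConfig, run_pipeline, simulate_inputs
from sigbin.simulate import SimConfig, simulate_genomes

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_CFG = SimConfig(
    seed=11,
    n_target_genomes=4,
    n_neighbor_genera=2,
    genomes_per_neighbor=2,
    genome_length=30_000,
    n_genes_per_genome=18,
    n_markers=8,
    n_samples=6,
)

DEFAULT_CFG = SimConfig(seed=101)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SMALL_CFG


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(genomes, proteomes, truth) for the small community."""
    return simulate_genomes(small_cfg)


@pytest.fixture(scope="session")
def small_inputs(small_cfg):
    """Full synthetic input bundle + truth for the small community."""
    return simulate_inputs(small_cfg)


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return DEFAULT_CFG


@pytest.fixture(scope="session")
def default_inputs(default_cfg):
    """Default-scale community: 10 target + 12 neighbor genomes, 20 samples."""
    return simulate_inputs(default_cfg)


@pytest.fixture(scope="session")
def default_run(default_inputs, tmp_path_factory):
    """One end-to-end pipeline run on the default community."""
    inputs, truth = default_inputs
    cfg = PipelineConfig(seed=DEFAULT_CFG.seed, n_bootstrap=100)
    outdir = tmp_path_factory.mktemp("default_run")
    result = run_pipeline(cfg, inputs, outdir)
    return result, truth, inputs
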