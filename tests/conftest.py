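"""Shared fixtures: one synthetic dataset and one full pipeline run per session.

All fixtures are generated programmatically from the synthetic-data module;
nothing is read from checked-in data files.  The pipeline run uses the
scaled-down operating point (gapped k-mers to span 5, 30-permutation
parallel analysis) so the whole suite stays fast; unit tests cover the
span-8 universe separately.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from kmerfact import synth
from kmerfact.pipeline import RunConfig, run_pipeline

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def sim_config():
    return synth.default_config(FIXTURE_SEED)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """Genome, planted-motif truth, replication domains, cells, labels."""
    genome, truth = synth.make_genome(sim_config)
    domains, signals = synth.make_repli_domains(sim_config, genome)
    cells, labels = synth.simulate_cells(sim_config, genome, truth, domains)
    return {
        "config": sim_config,
        "genome": genome,
        "truth": truth,
        "domains": domains,
        "signals": signals,
        "cells": cells,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    out = tmp_path_factory.mktemp("fixture")
    synth.write_fixture(sim_config, out)
    return out


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory, fixture_dir):
    """Full pipeline run on the default synthetic dataset (span-5 universe)."""
    out = tmp_path_factory.mktemp("run")
    config = RunConfig(
        reads=str(fixture_dir / "reads.bed"),
        genome=str(fixture_dir / "genome.fa"),
        labels=str(fixture_dir / "labels.tsv"),
        motifs_dir=str(fixture_dir / "motifs"),
        repli_dir=str(fixture_dir / "repli"),
        outdir=str(out),
        max_span=5,
        min_loci=300,
        pa_permutations=30,
        p_pwm=1e-20,
        seed=FIXTURE_SEED,
    )
    return run_pipeline(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
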