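"""Shared fixtures: small simulated genomes and prepared read pools."""

from __future__ import annotations

import numpy as np
import pytest

from minicircler.align import ReadStore
from minicircler.config import PipelineConfig
from minicircler.read_prep import prepare_pairs
from minicircler.simulate import SimParams, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    # simulated libraries are generated at the working depth, so the
    # whole pool is used (the 10% rule exists for production-size runs)
    return PipelineConfig(subsample_frac=1.0)


@pytest.fixture(scope="session")
def sim_k5():
    params = SimParams(n_circles=5, seed=1)
    truth = simulate_genome(params)
    pairs, table = simulate_reads(truth, params)
    return params, truth, pairs, table


@pytest.fixture(scope="session")
def store_k5(sim_k5, cfg) -> ReadStore:
    _params, _truth, pairs, _table = sim_k5
    survivors, _log = prepare_pairs(pairs, cfg)
    return ReadStore(survivors)


@pytest.fixture(scope="session")
def sim_k10():
    params = SimParams(n_circles=10, seed=3)
    truth = simulate_genome(params)
    pairs, table = simulate_reads(truth, params)
    return params, truth, pairs, table


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
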