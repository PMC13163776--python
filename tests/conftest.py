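"""Shared synthetic fixtures; everything is generated at test time."""

from __future__ import annotations

import warnings

import pytest

import gwgen


@pytest.fixture(scope="session")
def small_config() -> gwgen.SimulationConfig:
    """A compact benchmark: fast to fit, still exercises all node classes."""
    return gwgen.SimulationConfig(
        node_counts={"TF": 10, "lncRNA": 4, "miRNA": 5, "receptor": 6, "protein": 35},
        samples_per_stage={"quiet": 40, "exacerbation": 40},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return gwgen.generate_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_data(small_truth):
    return gwgen.simulate_expression(small_truth, 40, "quiet")


@pytest.fixture(scope="session")
def small_candidate(small_truth):
    return gwgen.corrupt_candidate(small_truth, 1.0, seed=99)


@pytest.fixture(scope="session")
def small_real(small_candidate, small_data):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gwgen.identify_gwgen(small_candidate, small_data, "quiet")


@pytest.fixture(scope="session")
def benchmark_setup():
    """The full-size benchmark: 200 nodes, N=118, noise 0.1, multiplier 2."""
    config = gwgen.SimulationConfig(seed=1)
    truth = gwgen.generate_ground_truth(config)
    data = gwgen.simulate_expression(truth, 118, "quiet")
    candidate = gwgen.corrupt_candidate(truth, config.spurious_multiplier, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        real = gwgen.identify_gwgen(candidate, data, "quiet")
    return {"config": config, "truth": truth, "data": data,
            "candidate": candidate, "real": real}
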