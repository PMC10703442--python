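"""Shared fixtures: simulated sessions reused across test modules."""

import numpy as np
import pytest

from seqprev.io import PipelineConfig
from seqprev.synthetic import (
    AgentConfig,
    NeuronConfig,
    TimingParams,
    simulate_behavior,
    simulate_session,
    simulate_timing,
)


@pytest.fixture(scope="session")
def sim_session():
    """A medium synthetic session with spikes under the default conditions."""
    agent = AgentConfig(n_trials=900, block_length_range=(250, 400), seed=11)
    bundle, gt = simulate_session(
        agent, TimingParams(seed=12), NeuronConfig(n_units=15, seed=13)
    )
    return bundle, gt


@pytest.fixture(scope="session")
def degenerate_trials():
    """Pure LLR concatenation: no exploration, no omission, no switch lag."""
    cfg = AgentConfig(
        sequence_set=("LLR",),
        block_length_range=(600, 600),
        switch_lag_mean=0,
        explore_rate_baseline=0.0,
        omission_prob=0.0,
        n_trials=600,
        seed=3,
    )
    return simulate_timing(simulate_behavior(cfg), TimingParams(seed=4))


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(session_min_instances=50, n_shuffles=200)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
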