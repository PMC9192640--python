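"""Shared fixtures: small simulated sessions reused across test modules."""

import numpy as np
import pytest

from featdecode import io_bids, synthetic_data as sd, task_design as td


@pytest.fixture(scope="session")
def small_schedule():
    """40 counterbalanced trials (2 blocks x 20): 5 per cell."""
    return td.build_trial_schedule(2, 20, seed=11)


@pytest.fixture(scope="session")
def noiseless_participant(small_schedule):
    cfg = sd.SimulationConfig(seed=5).noiseless()
    return sd.simulate_participant(cfg, small_schedule, rng=5)


@pytest.fixture(scope="session")
def noisy_participant(small_schedule):
    cfg = sd.SimulationConfig(seed=9)
    return sd.simulate_participant(cfg, small_schedule, rng=9)


def decode_participant(participant):
    events = io_bids.parse_trigger_channel(
        participant.recording.trig, participant.recording.fs
    )
    return io_bids.decode_trials(events, participant.trigger_map, participant.recording)


@pytest.fixture(scope="session")
def noiseless_trials(noiseless_participant):
    return decode_participant(noiseless_participant)


@pytest.fixture(scope="session")
def noisy_trials(noisy_participant):
    return decode_participant(noisy_participant)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
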