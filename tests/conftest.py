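import warnings

import numpy as np
import pytest
from hypothesis import settings

from rmtg_valence import psth, synthetic_data as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# scipy warns when the signed-rank exact method degrades on ties/zeros;
# that path is exercised deliberately throughout the suite
warnings.filterwarnings("ignore", module="scipy")
warnings.filterwarnings("ignore", message=".*[Ss]ample size too small.*")
warnings.filterwarnings("ignore", message=".*kurtosistest.*")


@pytest.fixture(scope="session")
def reward_schedule():
    """50 reward-cue trials, 4 s apart."""
    return psth.make_schedule([("reward_cue", 50, 2.0)], interval=4.0,
                              start=2.0)


@pytest.fixture(scope="session")
def phasic_schedule():
    """Reward block followed by interleaved phasic aversive stimuli."""
    reward = psth.make_schedule([("reward_cue", 50, 2.0)], interval=4.0,
                                start=2.0)
    aversive = psth.make_schedule(
        [("footshock", 30, 0.01), ("siren", 30, 1.0), ("bright_light", 30, 2.0)],
        interval=4.0, start=reward.end + 4.0, interleave=True, seed=0)
    return psth.EventSchedule(reward.events + aversive.events)


def session_length(schedule):
    return schedule.end + 5.0


@pytest.fixture(scope="session")
def null_train(reward_schedule):
    """Unmodulated 10 Hz Poisson unit aligned to the reward schedule."""
    config = sd.UnitGenConfig(unit_id="null0", baseline_rate=10.0)
    return sd.generate_spike_train(config, reward_schedule,
                                   session_length(reward_schedule), seed=42)


def poisson_train(rate, duration, seed, unit_id="poisson"):
    config = sd.UnitGenConfig(unit_id=unit_id, baseline_rate=rate)
    empty = psth.EventSchedule(())
    return sd.generate_spike_train(config, empty, duration, seed=seed)


def constructed_train(times, span=None, unit_id="fixed"):
    from rmtg_valence.qc import SpikeTrain

    times = np.asarray(times, dtype=float)
    if span is None:
        span = (0.0, float(times[-1]) + 1.0 if times.size else 1.0)
    return SpikeTrain(unit_id=unit_id, spike_times=times, session_span=span)
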