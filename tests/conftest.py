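import numpy as np
import pytest

from alphacond import EpochArray, SimParams, build_montage, generate_schedule
from alphacond.epochs import epoch_times


@pytest.fixture(scope="session")
def montage64():
    return build_montage(64)


@pytest.fixture(scope="session")
def times500():
    return epoch_times(500.0)


@pytest.fixture(scope="session")
def small_subject(montage64):
    """One seeded 64-channel recall subject with few trials."""
    params = SimParams(trials_retained=(6, 8))
    schedule = generate_schedule("recall", seed=11)
    from alphacond import simulate_subject

    return simulate_subject(schedule, params, montage64, seed=12)


def make_sine_epochs(times, freq=10.0, amp=1.0, env=None, n_trials=1,
                     labels=("CS+E",), ch_names=("ROI",)):
    """Noiseless oscillation epochs for analytic time-frequency checks."""
    t_s = times / 1000.0
    sig = amp * np.cos(2 * np.pi * freq * t_s)
    if env is not None:
        sig = sig * env
    data = np.tile(sig, (len(ch_names), 1))[:, :, None]
    data = np.repeat(data, n_trials, axis=2)
    lab = tuple(labels) * (n_trials // len(labels)) if n_trials > 1 else tuple(labels)
    return EpochArray(data, 500.0, times, ch_names, lab[:n_trials])
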