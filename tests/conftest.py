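import numpy as np
import pytest

import trialspike as ts


@pytest.fixture(scope="session")
def small_trials():
    """A 56-trial balanced session table."""
    return ts.generate_trials(56, seed=101)


@pytest.fixture(scope="session")
def null_unit_spikes(small_trials):
    """Homogeneous 3-Hz Poisson spike train on the small session."""
    unit = ts.UnitSpec(unit_id=0, baseline_rate=3.0)
    return ts.generate_unit_spikes(unit, small_trials, seed=77)


@pytest.fixture(scope="session")
def two_unit_trace():
    """Raw trace with one RS (0.8 ms) and one FS (0.3 ms) unit at SNR 10.

    Returns (trace, sampling_rate, truth) where truth maps unit index to
    embedded spike times.
    """
    units = [ts.UnitSpec(unit_id=0, cell_type="RS", baseline_rate=3.0,
                         peak_to_trough_ms=0.8),
             ts.UnitSpec(unit_id=1, cell_type="FS", baseline_rate=6.0,
                         peak_to_trough_ms=0.3)]
    ses = ts.generate_session(units=units, n_trials=8, seed=3)
    trace, truth = ts.generate_raw_trace(ses, noise_sd=0.1, seed=4)
    return trace, 10_000.0, truth


def nearest_distance(sorted_times: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Distance from each x to its nearest element of sorted_times."""
    t = np.asarray(sorted_times)
    i = np.clip(np.searchsorted(t, x), 1, t.size - 1)
    return np.minimum(np.abs(t[i - 1] - x), np.abs(t[i] - x))
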