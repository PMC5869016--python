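import numpy as np
import pytest

from pause_ephys.core import EpochSet, SpikeTrain, Trace


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def one_second_epochs():
    """Ten 1 s light pulses at a 50 s interval."""
    onsets = 10.0 + 50.0 * np.arange(10)
    return EpochSet(epochs=np.column_stack([onsets, onsets + 1.0]), label="light")


@pytest.fixture
def periodic_train():
    """Perfectly periodic unit: one spike every 0.2 s over 100 s."""
    times = np.arange(0.1, 100.0, 0.2)
    return SpikeTrain(times=times, t_start=0.0, t_stop=100.0)


def square_wave_trace(
    fs: float = 1000.0,
    down: float = 0.5,
    up: float = 0.4,
    n_cycles: int = 20,
    v_down: float = -75.0,
    v_up: float = -55.0,
) -> tuple[Trace, np.ndarray]:
    """Noiseless two-level trace plus the true UP-onset times."""
    cycle = np.concatenate(
        [np.full(int(down * fs), v_down), np.full(int(up * fs), v_up)]
    )
    samples = np.tile(cycle, n_cycles)
    onsets = down + (down + up) * np.arange(n_cycles)
    return Trace(samples=samples, fs=fs), onsets
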