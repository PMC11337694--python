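import numpy as np
import pytest

import psar
from psar.fiducials import Beat, FiducialPoints

FS = 500.0


@pytest.fixture(scope="session")
def sine_8s():
    """0.2 mV sinusoid with 800 ms period (the ideal single-beat stand-in)."""
    return psar.gen_sine(0.2, 400.0, 8.0, FS)


@pytest.fixture(scope="session")
def sine_20s():
    return psar.gen_sine(0.2, 400.0, 20.0, FS)


@pytest.fixture(scope="session")
def ecg_noiseless():
    """10 s metronomic 60 bpm synthetic ECG with exact truth."""
    return psar.gen_synthetic_ecg(duration_s=10.0, fs=FS, bpm=60.0, rr_cv=0.0, seed=1)


def periodic_fiducials(n_beats: int, period_s: float = 0.8, fs: float = FS,
                       t0_s: float = 0.0) -> FiducialPoints:
    """R-only fiducials at exact multiples of the period."""
    idx = [int(round((t0_s + k * period_s) * fs)) for k in range(n_beats)]
    return FiducialPoints([Beat(R=i) for i in idx], fs=fs)


def single_cycle_signal(T: int, amplitude: float = 0.2, fs: float = FS):
    """One exact sine cycle of T samples (plus one spare) as an ECGSignal."""
    y = amplitude * np.sin(2.0 * np.pi * np.arange(T) / T)
    return psar.ECGSignal(np.concatenate([y, [y[0]]]), fs=fs)
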