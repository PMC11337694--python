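"""Core container for a uniformly sampled single-lead ECG trace."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class ECGSignal:
    """A uniformly sampled voltage trace from one ECG lead.

    Parameters
    ----------
    samples
        Voltage samples in millivolt. Stored as a float64 array; must be
        finite and non-empty.
    fs
        Sampling rate in Hz, strictly positive.
    lead
        Lead label, e.g. ``"I"``. Informational only.
    t0
        Time of the first sample in seconds; sample ``k`` occurs at
        ``t0 + k / fs``.
    """

    samples: np.ndarray
    fs: float
    lead: str = "I"
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in milliseconds (the unit the ideal-signal formulas use)."""
        return self.times * 1000.0

    def with_samples(self, samples: np.ndarray) -> "ECGSignal":
        """Return a copy carrying new samples but the same fs/lead/t0."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))
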