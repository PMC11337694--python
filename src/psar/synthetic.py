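"""Synthetic test signals: ideal sinusoids and a PQRST wave-train generator.

Two families are provided.  The ideal signals — a single sinusoid
``y = A sin(pi x / half_period)`` (x in ms), a two-piece mixed sinusoid, and
their constant / linear drift variants — have closed-form values and drive
the symmetry and invariance analyses of the embedding.  The ECG emulator
sums five Gaussian bumps (P, Q, R, S, T) per beat on a lead-I-like amplitude
scale (R about 1 mV, P below 0.25 mV) with lognormally distributed RR
intervals, and returns exact ground-truth fiducials so detector accuracy can
be scored without any recorded data.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiducials import Beat, FiducialPoints
from .signal import ECGSignal

DEFAULT_FS = 500.0

#: Per-wave (offset from R in ms, amplitude in mV, Gaussian sigma in ms);
#: a plausible lead-I morphology, every entry overridable.
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (-160.0, 0.15, 25.0),
    "Q": (-35.0, -0.10, 8.0),
    "R": (0.0, 1.00, 12.0),
    "S": (35.0, -0.15, 8.0),
    "T": (250.0, 0.30, 45.0),
}


def gen_sine(
    amplitude: float = 0.2,
    half_period_ms: float = 400.0,
    duration_s: float = 8.0,
    fs: float = DEFAULT_FS,
) -> ECGSignal:
    """Ideal sinusoid ``y(x) = A sin(pi x / half_period)`` with x in ms.

    The default (A = 0.2 mV, half period 400 ms, i.e. a 1.25 Hz / 800 ms
    cycle) mimics the period and R-peak amplitude scale of a lead-I beat.
    """
    if half_period_ms <= 0:
        raise ValueError("half_period_ms must be positive")
    x = np.arange(int(round(duration_s * fs))) / fs * 1000.0
    return ECGSignal(amplitude * np.sin(np.pi * x / half_period_ms), fs=fs)


def gen_mixed_sine(
    a1: float = 0.1,
    a2: float = 0.4,
    d1_ms: float = 800.0,
    d2_ms: float = 1200.0,
    duration_s: float = 8.0,
    fs: float = DEFAULT_FS,
) -> ECGSignal:
    """Piecewise sinusoid alternating two full sine cycles of unequal length.

    Each composite period of ``d1 + d2`` ms holds one full sine cycle of
    amplitude ``a1`` over the first ``d1`` ms (half period d1/2) followed by
    one of amplitude ``a2`` over the remaining ``d2`` ms (half period d2/2),
    each piece phase-local so the waveform is continuous.  The defaults give
    a 2000 ms composite period with an 800 ms / 1200 ms split — a cartoon of
    a compact wave group followed by a longer, larger complex.
    """
    if d1_ms <= 0 or d2_ms <= 0:
        raise ValueError("piece durations must be positive")
    x = np.arange(int(round(duration_s * fs))) / fs * 1000.0
    period = d1_ms + d2_ms
    x_loc = np.mod(x, period)
    in_first = x_loc < d1_ms
    y = np.where(
        in_first,
        a1 * np.sin(2.0 * np.pi * x_loc / d1_ms),
        a2 * np.sin(2.0 * np.pi * (x_loc - d1_ms) / d2_ms),
    )
    return ECGSignal(y, fs=fs)


def gen_fm_sine(
    amplitude: float = 0.2,
    mean_period_ms: float = 800.0,
    cv: float = 0.05,
    duration_s: float = 20.0,
    fs: float = DEFAULT_FS,
    seed: int = 0,
):
    """Quasi-periodic sinusoid: one full sine cycle per lognormal period.

    Cycle lengths are drawn like RR intervals (mean ``mean_period_ms``,
    coefficient of variation ``cv``) and the phase advances exactly one turn
    per cycle, so each cycle is a time-rescaled copy of the same waveform —
    the idealisation of a heartbeat train with rhythm variability but fixed
    morphology.  Returns the signal together with the exact cycle-boundary
    indices packaged as R-only fiducials, ready for splitting.
    """
    rng = np.random.default_rng(seed)
    bounds = [0.0]
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    while bounds[-1] < duration_s:
        step = mean_period_ms / 1000.0
        if sigma > 0:
            step *= float(np.exp(rng.normal(-sigma**2 / 2.0, sigma)))
        bounds.append(bounds[-1] + step)
    b = np.asarray(bounds)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = np.interp(t, b, np.arange(b.size, dtype=np.float64))
    sig = ECGSignal(amplitude * np.sin(2.0 * np.pi * phase), fs=fs)
    idx = [int(round(x * fs)) for x in b if round(x * fs) < n]
    fids = FiducialPoints([Beat(R=i) for i in idx], fs=fs)
    return sig, fids


def add_drift(
    sig: ECGSignal, kind: str = "constant", value: float = 0.1
) -> ECGSignal:
    """Superimpose baseline drift.

    ``constant``: add ``value`` mV everywhere.  ``linear``: add
    ``value * t_ms`` (slope in mV per millisecond; 5e-5 doubles a 0.1 mV
    offset every 2 s).  ``none``: identity.
    """
    if kind == "none":
        return sig
    if kind == "constant":
        return sig.with_samples(sig.samples + value)
    if kind == "linear":
        return sig.with_samples(sig.samples + value * sig.times_ms)
    raise ValueError(f"unknown drift kind {kind!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise description: white Gaussian plus mains interference.

    Exactly one of ``white_sigma`` (mV) or ``snr_db`` (relative to the clean
    signal) selects the white-noise level; ``powerline_amplitude`` (mV) adds
    a sinusoid at ``powerline_hz``.
    """

    white_sigma: float = 0.0
    snr_db: float | None = None
    powerline_amplitude: float = 0.0
    powerline_hz: float = 50.0


def add_noise(sig: ECGSignal, spec: NoiseSpec, seed: int = 0) -> ECGSignal:
    """Add seeded white and/or powerline noise; identical seed, identical output."""
    rng = np.random.default_rng(seed)
    y = sig.samples.copy()
    sigma = spec.white_sigma
    if spec.snr_db is not None:
        p_sig = float(np.mean(sig.samples**2))
        sigma = np.sqrt(p_sig / 10.0 ** (spec.snr_db / 10.0))
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=y.size)
    if spec.powerline_amplitude > 0:
        y = y + spec.powerline_amplitude * np.sin(
            2.0 * np.pi * spec.powerline_hz * sig.times
        )
    return sig.with_samples(y)


@dataclass
class SyntheticECGTruth:
    """Ground truth emitted alongside a synthetic ECG."""

    fiducials: FiducialPoints
    rr_series_ms: np.ndarray
    waves: dict[str, tuple[float, float, float]]


def gen_synthetic_ecg(
    duration_s: float = 10.0,
    fs: float = DEFAULT_FS,
    bpm: float = 60.0,
    rr_cv: float = 0.0,
    waves: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> tuple[ECGSignal, SyntheticECGTruth]:
    """Quasi-periodic PQRST wave train with exact fiducial ground truth.

    Each beat is the sum of five Gaussian bumps placed at fixed offsets from
    its R peak (see ``DEFAULT_WAVES``).  RR intervals are drawn from a
    lognormal with mean ``60000 / bpm`` ms and coefficient of variation
    ``rr_cv`` (0 gives a metronomic rhythm; ~0.15 emulates an irregular
    one).  The first R peak sits half a mean RR into the record.

    Returns the noiseless signal and a truth object whose fiducial indices
    are the sample-rounded bump centres.

    Raises
    ------
    ValueError
        If a wave offset exceeds the mean RR (bumps would fall outside
        their own beat).
    """
    waves = dict(DEFAULT_WAVES if waves is None else waves)
    mean_rr = 60000.0 / bpm
    for name, (off, _, _) in waves.items():
        if abs(off) >= mean_rr:
            raise ValueError(
                f"wave {name} offset {off} ms exceeds the mean RR {mean_rr} ms"
            )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t_ms = np.arange(n) / fs * 1000.0

    r_times: list[float] = []
    rr_list: list[float] = []
    t_r = mean_rr / 2.0
    while t_r < duration_s * 1000.0:
        r_times.append(t_r)
        if rr_cv > 0:
            sigma2 = np.log1p(rr_cv**2)
            rr = float(
                np.exp(rng.normal(np.log(mean_rr) - sigma2 / 2.0, np.sqrt(sigma2)))
            )
        else:
            rr = mean_rr
        rr_list.append(rr)
        t_r += rr

    y = np.zeros(n)
    beats: list[Beat] = []
    for t_peak in r_times:
        beat_kwargs: dict[str, int] = {}
        for name, (off, amp, width) in waves.items():
            centre = t_peak + off
            if amp != 0.0:
                y += amp * np.exp(-0.5 * ((t_ms - centre) / width) ** 2)
            idx = int(round(centre / 1000.0 * fs))
            if 0 <= idx < n and amp != 0.0:
                beat_kwargs[name] = idx
        if "R" in beat_kwargs:
            beats.append(Beat(**beat_kwargs))
    fids = FiducialPoints(beats=beats, fs=fs)
    truth = SyntheticECGTruth(
        fiducials=fids,
        rr_series_ms=np.array(rr_list[: max(0, len(r_times) - 1)]),
        waves=waves,
    )
    return ECGSignal(y, fs=fs), truth
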