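"""PQRST fiducial detection on a preprocessed single-lead ECG.

R peaks are found by a sliding-window curvature transform with an adaptive
threshold, then Q/S/T/P are located per beat inside physiology-standard
search windows around each R.  All window lengths are exposed as arguments;
the defaults assume lead-I morphology at a few hundred Hz sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .signal import ECGSignal

logger = logging.getLogger(__name__)

WAVES = ("P", "Q", "R", "S", "T")


@dataclass
class Beat:
    """Per-beat fiducial sample indices; R is mandatory, the rest optional."""

    R: int
    P: int | None = None
    Q: int | None = None
    S: int | None = None
    T: int | None = None

    def get(self, wave: str) -> int | None:
        return getattr(self, wave)

    def present(self) -> dict[str, int]:
        return {w: getattr(self, w) for w in WAVES if getattr(self, w) is not None}


@dataclass
class FiducialPoints:
    """Ordered beats with their fiducial indices and the source sampling rate."""

    beats: list[Beat]
    fs: float

    def __post_init__(self) -> None:
        r = [b.R for b in self.beats]
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("R indices must be strictly increasing")
        for b in self.beats:
            idx = [b.get(w) for w in WAVES if b.get(w) is not None]
            if any(y <= x for x, y in zip(idx, idx[1:])):
                raise ValueError(f"beat fiducials out of order: {b}")

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def r_indices(self) -> np.ndarray:
        return np.array([b.R for b in self.beats], dtype=np.int64)

    def rr_intervals_ms(self) -> np.ndarray:
        """RR series in milliseconds from the detected R indices."""
        r = self.r_indices
        return np.diff(r) / self.fs * 1000.0


def _curvature_transform(x: np.ndarray) -> np.ndarray:
    """Squared second difference of a 5-point smoothed signal.

    Sharp transitions (the QRS complex) dominate this statistic regardless
    of signal polarity, while broad P/T waves contribute little.
    """
    sm = ndimage.uniform_filter1d(x, size=5, mode="nearest")
    d2 = np.zeros_like(sm)
    d2[1:-1] = sm[2:] - 2.0 * sm[1:-1] + sm[:-2]
    return d2 * d2


def detect_r_peaks(
    sig: ECGSignal,
    min_rr_s: float = 0.25,
    refine_ms: float = 40.0,
    threshold_frac: float = 0.4,
    floor_frac: float = 0.1,
    rolling_window_s: float = 2.0,
    gap_factor: float = 1.8,
) -> np.ndarray:
    """Detect R-peak sample indices.

    A candidate is a local maximum of the curvature transform exceeding an
    adaptive threshold (``threshold_frac`` of the rolling 2 s window maximum,
    floored at ``floor_frac`` of the global maximum), with candidates closer
    than ``min_rr_s`` suppressed.  Each candidate is refined to the raw-signal
    local maximum within +/- ``refine_ms``.  A second pass re-examines RR gaps
    larger than ``gap_factor`` x the median RR with a halved threshold.

    Returns a strictly increasing int array (possibly empty).  Detection is
    invariant to positive amplitude rescaling of the input.
    """
    x = sig.samples
    c = _curvature_transform(x)
    gmax = float(c.max())
    if gmax <= 0.0:
        return np.array([], dtype=np.int64)
    win = max(3, int(round(rolling_window_s * sig.fs)))
    rolling_max = ndimage.maximum_filter1d(c, size=win, mode="nearest")
    thr = np.maximum(threshold_frac * rolling_max, floor_frac * gmax)
    dist = max(1, int(round(min_rr_s * sig.fs)))
    cand, _ = find_peaks(c, distance=dist)
    cand = cand[c[cand] >= thr[cand]]
    peaks = _refine_and_dedupe(x, cand, sig.fs, refine_ms, min_rr_s)

    # Gap re-detection: look for beats the adaptive threshold missed.
    if len(peaks) >= 3:
        rr = np.diff(peaks)
        med = float(np.median(rr))
        extra: list[int] = []
        for i, gap in enumerate(rr):
            if gap > gap_factor * med:
                lo, hi = peaks[i] + dist, peaks[i + 1] - dist
                if hi <= lo:
                    continue
                seg = c[lo:hi]
                sub, _ = find_peaks(seg, distance=dist)
                sub = sub[seg[sub] >= 0.5 * thr[lo:hi][sub]]
                extra.extend((lo + sub).tolist())
        if extra:
            merged = np.sort(np.concatenate([peaks, np.array(extra, dtype=np.int64)]))
            peaks = _refine_and_dedupe(x, merged, sig.fs, refine_ms, min_rr_s)
    return peaks


def _refine_and_dedupe(
    x: np.ndarray,
    cand: np.ndarray,
    fs: float,
    refine_ms: float,
    min_rr_s: float,
) -> np.ndarray:
    """Snap candidates to the local raw-signal maximum and enforce min spacing.

    When two refined candidates collide within ``min_rr_s`` the larger
    amplitude wins; on a tie the earlier one is kept.
    """
    if cand.size == 0:
        return np.array([], dtype=np.int64)
    r = max(1, int(round(refine_ms / 1000.0 * fs)))
    refined = []
    for i in np.asarray(cand, dtype=np.int64):
        lo, hi = max(0, i - r), min(len(x), i + r + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.array(refined, dtype=np.int64))
    dist = max(1, int(round(min_rr_s * fs)))
    kept: list[int] = []
    for i in refined:
        if kept and i - kept[-1] < dist:
            if x[i] > x[kept[-1]]:
                kept[-1] = int(i)
            # tie or smaller: keep the earlier
        else:
            kept.append(int(i))
    return np.array(kept, dtype=np.int64)


def refine_fiducials(
    sig: ECGSignal,
    r_peaks: np.ndarray,
    q_window_ms: float = 80.0,
    s_window_ms: float = 80.0,
    t_window_ms: tuple[float, float] = (40.0, 400.0),
    p_window_ms: tuple[float, float] = (40.0, 250.0),
    prominence_floor_mv: float = 0.05,
) -> FiducialPoints:
    """Locate Q, S, T and P around each detected R peak.

    Search windows (defaults, all configurable): Q = signed minimum within
    80 ms before R; S = signed minimum within 80 ms after R; T = extremum of
    largest deviation in (S + 40 ms, S + 400 ms) clipped to the next beat;
    P = maximum in (Q - 250 ms, Q - 40 ms) clipped past the previous T.  A
    wave whose amplitude deviates from the local window median by less than
    ``prominence_floor_mv`` is marked missing.
    """
    x = sig.samples
    fs = sig.fs
    n = len(x)
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if r_peaks.size == 0:
        return FiducialPoints(beats=[], fs=fs)

    def ms(v: float) -> int:
        return max(1, int(round(v / 1000.0 * fs)))

    beats: list[Beat] = []
    for k, r in enumerate(r_peaks):
        beat = Beat(R=int(r))
        lo = max(0, r - ms(q_window_ms))
        if lo < r:
            seg = x[lo:r]
            idx = lo + int(np.argmin(seg))
            if np.median(seg) - x[idx] >= prominence_floor_mv:
                beat.Q = idx
        hi = min(n, r + ms(s_window_ms) + 1)
        if r + 1 < hi:
            seg = x[r + 1 : hi]
            idx = r + 1 + int(np.argmin(seg))
            if np.median(seg) - x[idx] >= prominence_floor_mv:
                beat.S = idx
        if beat.S is not None:
            t_lo = beat.S + ms(t_window_ms[0])
            t_hi = beat.S + ms(t_window_ms[1])
            if k + 1 < len(r_peaks):
                t_hi = min(t_hi, int(r_peaks[k + 1]) - ms(q_window_ms))
            t_hi = min(t_hi, n)
            if t_lo < t_hi:
                seg = x[t_lo:t_hi]
                idx = t_lo + int(np.argmax(np.abs(seg - np.median(seg))))
                if abs(x[idx] - np.median(seg)) >= prominence_floor_mv:
                    beat.T = idx
        if beat.Q is not None:
            p_lo = beat.Q - ms(p_window_ms[1])
            p_hi = beat.Q - ms(p_window_ms[0])
            if k > 0 and beats[k - 1].T is not None:
                p_lo = max(p_lo, beats[k - 1].T + 1)
            p_lo = max(p_lo, 0)
            if p_lo < p_hi:
                seg = x[p_lo:p_hi]
                idx = p_lo + int(np.argmax(seg))
                if x[idx] - np.median(seg) >= prominence_floor_mv:
                    beat.P = idx
        _enforce_order(beat)
        beats.append(beat)
    return FiducialPoints(beats=beats, fs=fs)


def _enforce_order(beat: Beat) -> None:
    """Drop any wave that violates P < Q < R < S < T."""
    if beat.Q is not None and beat.Q >= beat.R:
        beat.Q = None
    if beat.S is not None and beat.S <= beat.R:
        beat.S = None
    if beat.T is not None and (beat.S is None or beat.T <= beat.S):
        beat.T = None
    if beat.P is not None and (beat.Q is None or beat.P >= beat.Q):
        beat.P = None


#: Fiducials each split scheme needs on a beat to be usable.
REQUIRED_WAVES = {"RR": ("R",), "QRS": ("Q", "R", "S"), "STPQ": ("Q", "R", "S")}


def validate_beats(fids: FiducialPoints, method: str) -> FiducialPoints:
    """Drop beats lacking the fiducials the chosen split scheme requires.

    ``RR`` needs only R; ``QRS`` needs Q and S; ``STPQ`` segments run from one
    beat's S to the next beat's Q, so both waves are required on every
    retained beat.  Drop counts are logged.
    """
    if method not in REQUIRED_WAVES:
        raise ValueError(f"unknown split method {method!r}")
    need = REQUIRED_WAVES[method]
    kept = [b for b in fids.beats if all(b.get(w) is not None for w in need)]
    dropped = len(fids.beats) - len(kept)
    if dropped:
        logger.info(
            "validate_beats(%s): dropped %d of %d beats lacking %s",
            method, dropped, len(fids.beats), need,
        )
    return FiducialPoints(beats=kept, fs=fids.fs)
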