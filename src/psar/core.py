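"""Periodic split attractor reconstruction (PSAR).

The signal is cut into cardiac-cycle segments by one of three schemes —
R-R (R peak to next R peak), QRS (Q to S of one beat) or STPQ (S of one
beat to Q of the next, covering the T and P waves) — and each segment is
delay-embedded in 3-D with its *own* delay tau = segment period / 3.  Tying
the delay to each cycle's period is what makes the reconstruction invariant
to heart-rate changes: a stretched beat and a compressed beat trace the same
orbit.  Per-cycle trajectories are re-spliced into one point cloud with
cycle provenance.

Two embedding modes are offered.  ``circular`` continues each cycle
periodically within itself (y index taken modulo the cycle length), which
preserves the exact three-fold rotational symmetry the tau = T/3 rule
induces for a periodic cycle; ``truncated`` stops 2*tau early and never
wraps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fiducials import FiducialPoints, validate_beats
from .signal import ECGSignal

logger = logging.getLogger(__name__)

SPLIT_METHODS = ("RR", "QRS", "STPQ")
EMBED_MODES = ("circular", "truncated")
EMBED_DIM = 3
#: Segments shorter than this are dropped so that tau >= 3 samples.
MIN_SEGMENT_SAMPLES = 9


def compute_tau(period_samples: int) -> int:
    """Delay for a split period: round(period / 3), half away from zero, min 1."""
    if period_samples < 3:
        raise ValueError(
            f"split period must be at least 3 samples, got {period_samples}"
        )
    return max(1, int(np.floor(period_samples / 3.0 + 0.5)))


@dataclass(frozen=True)
class CycleSegment:
    """One split interval, half-open ``[start, end)``, with its own delay."""

    start: int
    end: int
    method: str
    tau_samples: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.method not in SPLIT_METHODS:
            raise ValueError(f"unknown split method {self.method!r}")

    @property
    def period_samples(self) -> int:
        return self.end - self.start

    @classmethod
    def from_bounds(cls, start: int, end: int, method: str) -> "CycleSegment":
        return cls(start=start, end=end, method=method,
                   tau_samples=compute_tau(end - start))


def split_cycles(
    fids: FiducialPoints,
    method: str = "RR",
    min_segment_samples: int = MIN_SEGMENT_SAMPLES,
) -> list[CycleSegment]:
    """Cut the record into cycle segments according to the chosen scheme.

    ``RR``: consecutive R-peak pairs, contiguous by construction.
    ``QRS``: Q to S within each beat.
    ``STPQ``: S of beat i to Q of beat i+1 (T and P waves in between).
    Beats lacking required fiducials are dropped first; segments shorter
    than ``min_segment_samples`` are dropped and counted in the log.
    """
    fids = validate_beats(fids, method)
    beats = fids.beats
    bounds: list[tuple[int, int]] = []
    if method == "RR":
        r = [b.R for b in beats]
        bounds = list(zip(r[:-1], r[1:]))
    elif method == "QRS":
        bounds = [(b.Q, b.S) for b in beats]
    elif method == "STPQ":
        bounds = [(a.S, b.Q) for a, b in zip(beats[:-1], beats[1:])]
    segments = []
    short = 0
    for start, end in bounds:
        if end - start < min_segment_samples:
            short += 1
            continue
        segments.append(CycleSegment.from_bounds(int(start), int(end), method))
    if short:
        logger.info("split_cycles(%s): dropped %d segments shorter than %d samples",
                    method, short, min_segment_samples)
    return segments


@dataclass
class EmbeddedTrajectory:
    """Concatenated 3-D delay vectors with per-point cycle provenance."""

    points: np.ndarray  # shape (N, 3), mV
    cycle_ids: np.ndarray  # shape (N,), non-decreasing
    mode: str
    m: int = EMBED_DIM

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, EMBED_DIM)
        self.cycle_ids = np.asarray(self.cycle_ids, dtype=np.int64).reshape(-1)
        if self.points.shape[0] != self.cycle_ids.shape[0]:
            raise ValueError("points and cycle_ids length mismatch")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trajectory coordinates must be finite")
        if self.cycle_ids.size and np.any(np.diff(self.cycle_ids) < 0):
            raise ValueError("cycle_ids must be non-decreasing")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n_cycles(self) -> int:
        return int(np.unique(self.cycle_ids).size)

    @classmethod
    def empty(cls, mode: str) -> "EmbeddedTrajectory":
        return cls(points=np.empty((0, EMBED_DIM)),
                   cycle_ids=np.empty((0,), dtype=np.int64), mode=mode)


def embed_segment(
    sig: ECGSignal,
    seg: CycleSegment,
    mode: str = "circular",
    tau_override: int | None = None,
    cycle_id: int = 0,
) -> EmbeddedTrajectory:
    """Delay-embed one cycle segment in 3-D.

    ``circular``: for n in [0, T), the point is
    ``(y[n], y[(n + tau) mod T], y[(n + 2 tau) mod T])`` with indices local
    to the segment — the cycle is treated as one period of a periodic orbit.
    ``truncated``: n runs over [0, T - 2 tau) with no wrap; if T <= 2 tau the
    result is empty (logged).  ``tau_override`` (used by delay-sweep
    analyses) replaces the segment's own tau = T/3.
    """
    if mode not in EMBED_MODES:
        raise ValueError(f"unknown embedding mode {mode!r}")
    if seg.start < 0 or seg.end > len(sig):
        raise ValueError("segment exceeds signal bounds")
    y = sig.samples[seg.start : seg.end]
    T = len(y)
    tau = int(tau_override) if tau_override is not None else seg.tau_samples
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if mode == "circular":
        n = np.arange(T)
        pts = np.column_stack((y[n], y[(n + tau) % T], y[(n + 2 * tau) % T]))
    else:
        n_pts = T - 2 * tau
        if n_pts <= 0:
            logger.warning(
                "truncated embedding of a %d-sample segment with tau=%d is empty",
                T, tau,
            )
            return EmbeddedTrajectory.empty(mode)
        n = np.arange(n_pts)
        pts = np.column_stack((y[n], y[n + tau], y[n + 2 * tau]))
    ids = np.full(pts.shape[0], cycle_id, dtype=np.int64)
    return EmbeddedTrajectory(points=pts, cycle_ids=ids, mode=mode)


def reconstruct_attractor(
    sig: ECGSignal,
    fids: FiducialPoints,
    method: str = "RR",
    mode: str = "circular",
) -> EmbeddedTrajectory:
    """Split, embed each cycle with its own tau, and re-splice.

    Cycle ids are assigned in temporal order.  An input yielding no usable
    segments returns an empty trajectory (with a warning).
    """
    segments = split_cycles(fids, method)
    return embed_cycles(sig, segments, mode=mode)


def embed_cycles(
    sig: ECGSignal,
    segments: list[CycleSegment],
    mode: str = "circular",
) -> EmbeddedTrajectory:
    """Embed an explicit segment list and concatenate in order."""
    if not segments:
        logger.warning("no usable segments; returning empty trajectory")
        return EmbeddedTrajectory.empty(mode)
    parts = [
        embed_segment(sig, seg, mode=mode, cycle_id=i)
        for i, seg in enumerate(segments)
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return EmbeddedTrajectory.empty(mode)
    return EmbeddedTrajectory(
        points=np.concatenate([p.points for p in parts]),
        cycle_ids=np.concatenate([p.cycle_ids for p in parts]),
        mode=mode,
    )
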