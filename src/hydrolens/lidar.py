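"""Transparency-signal processing for LiDAR hydration traces.

A time-of-flight sensor mounted above a hydrating gel records the
apparent distance to the sample once per second.  As the gel hydrates
the trace shows three phases: an initial *growth* dip (the swelling
sample rises toward the sensor), a *transparency* rise (light starts
passing through the increasingly clear gel so the apparent distance
grows past baseline), and an *equilibrium* plateau.  This module
normalises a trace to its early baseline, removes sensor jitter with a
zero-phase low-pass filter, and segments the three phases.

The normalised distance is a relative indicator of transparency change,
not an absolute transmittance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig

__all__ = [
    "LidarTrace",
    "PhaseSegmentation",
    "StructureNotFoundError",
    "normalize_trace",
    "zero_phase_lowpass",
    "segment_phases",
]

DEFAULT_CUTOFF_HZ = 1.0 / (2.0 * 3600.0)  # preserve >= 30-min features


class StructureNotFoundError(ValueError):
    """Raised when a trace lacks the dip-then-peak hydration structure."""


@dataclass(frozen=True)
class LidarTrace:
    """Uniformly sampled distance trace (default 1 Hz)."""

    times: np.ndarray  # seconds
    distances: np.ndarray  # mm, or dimensionless once normalised

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "distances", d)
        if t.size != d.size or t.size < 2:
            raise ValueError("trace needs >= 2 equal-length samples")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances contain non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.max(dt) > 1.01 * np.min(dt):
            raise ValueError("sampling must be uniform to within 1%")

    @property
    def dt(self) -> float:
        """Sampling interval, seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def fs(self) -> float:
        """Sampling rate, Hz."""
        return 1.0 / self.dt


@dataclass(frozen=True)
class PhaseSegmentation:
    """Hydration phase boundaries, hours since trace start."""

    growth_end: float
    transparency_peak: float
    equilibrium_start: float

    def __post_init__(self) -> None:
        if not self.growth_end <= self.transparency_peak <= self.equilibrium_start:
            raise ValueError("phase boundaries must be ordered")


def normalize_trace(t: LidarTrace, baseline_window: float = 600.0) -> LidarTrace:
    """Divide a trace by its mean over the initial baseline window.

    ``baseline_window`` is in seconds (default: first 10 minutes).  The
    output is dimensionless with first-window mean 1, and is invariant
    to uniform rescaling of the raw distances.
    """
    mask = t.times <= t.times[0] + baseline_window
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    if baseline_window > t.times[-1] - t.times[0]:
        raise ValueError("baseline window longer than the trace")
    baseline = float(np.mean(t.distances[mask]))
    if baseline <= 0:
        raise ValueError("baseline mean must be positive")
    return LidarTrace(times=t.times.copy(), distances=t.distances / baseline)


def zero_phase_lowpass(
    t: LidarTrace, cutoff: float = DEFAULT_CUTOFF_HZ, order: int = 4
) -> LidarTrace:
    """Forward-backward Butterworth low-pass filter (zero phase shift).

    The filter runs once forward and once backward so features keep
    their position in time (the effective order doubles).  Endpoints are
    handled by reflective padding.  Implemented with second-order
    sections for numerical stability at the very low default cutoff
    (multi-hour features at 1 Hz sampling).
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    nyquist = t.fs / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    sos = spsig.butter(order, cutoff / nyquist, btype="low", output="sos")
    filtered = spsig.sosfiltfilt(sos, t.distances)
    return LidarTrace(times=t.times.copy(), distances=filtered)


def segment_phases(
    t: LidarTrace,
    slope_threshold: float = 0.01,
    slope_window_h: float = 1.0,
    min_amplitude: float = 0.01,
) -> PhaseSegmentation:
    """Segment a normalised, filtered trace into the three phases.

    * ``growth_end``: time of the global minimum of the early dip;
    * ``transparency_peak``: time of the global maximum after the dip;
    * ``equilibrium_start``: first time after the peak from which the
      trace's slope magnitude stays below ``slope_threshold`` (per hour)
      over a trailing window of ``slope_window_h`` hours.

    ``min_amplitude`` is the minimum dip depth and rise height (on the
    normalised scale) for the dip-then-peak structure to count; flat or
    monotone traces raise :class:`StructureNotFoundError`.
    """
    hours = (t.times - t.times[0]) / 3600.0
    y = t.distances
    i_min = int(np.argmin(y))
    dip_depth = float(y[0] - y[i_min])
    if i_min == 0 or i_min == y.size - 1 or dip_depth < min_amplitude:
        raise StructureNotFoundError(
            "no early dip found; trace is flat or monotone"
        )
    i_max = i_min + int(np.argmax(y[i_min:]))
    rise = float(y[i_max] - y[i_min])
    if i_max == i_min or rise < min_amplitude:
        raise StructureNotFoundError("no transparency peak after the dip")

    # equilibrium: slope magnitude below threshold from i_eq onward,
    # measured over a trailing window
    win = max(2, int(round(slope_window_h * 3600.0 / t.dt)))
    slope = np.gradient(y, hours)  # per hour
    i_eq = None
    for i in range(i_max, y.size - win + 1):
        if np.all(np.abs(slope[i : i + win]) < slope_threshold):
            i_eq = i
            break
    if i_eq is None:
        i_eq = y.size - 1
    return PhaseSegmentation(
        growth_end=float(hours[i_min]),
        transparency_peak=float(hours[i_max]),
        equilibrium_start=float(max(hours[i_eq], hours[i_max])),
    )
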