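"""Dimensional swelling analysis of hydrogel samples.

A hydrogel button swells when hydrated; its expansion is summarised by
dimensionless factors — the ratio of the wet dimension to the dry
reference dimension.  Measured edge-to-edge diameters give the linear
expansion factor (LEF), sagittal depths give the radial expansion factor
(REF).  This module converts raw dimension-versus-time series into
expansion-factor series, reads factors at arbitrary timepoints, computes
trapezoidal area under the curve (AUC) over a time window, and derives
gravimetric water content from dry/swollen mass pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Direction",
    "DimensionSeries",
    "ExpansionSeries",
    "MassPair",
    "GroupSummary",
    "expansion_factor",
    "expansion_series",
    "factor_at",
    "auc",
    "water_content",
    "mass_swelling",
    "group_summary",
]

Direction = Literal["lateral", "sagittal"]


def _as_float_array(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DimensionSeries:
    """Raw tracked dimension of one sample in one direction over time."""

    sample_id: str
    direction: Direction
    times: np.ndarray  # hours, strictly increasing
    values: np.ndarray  # mm, positive
    dry_reference: float  # mm, positive

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _as_float_array(self.times, "times"))
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if self.times.size == 0:
            raise ValueError("series must contain at least one sample")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("dimension values must be positive")
        if not self.dry_reference > 0:
            raise ValueError("dry reference dimension must be positive")


@dataclass(frozen=True)
class ExpansionSeries:
    """Dimensionless expansion factors (wet/dry) for one sample."""

    sample_id: str
    direction: Direction
    times: np.ndarray
    factors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _as_float_array(self.times, "times"))
        object.__setattr__(self, "factors", _as_float_array(self.factors, "factors"))
        if self.times.size == 0:
            raise ValueError("series must contain at least one sample")
        if self.times.size != self.factors.size:
            raise ValueError("times and factors must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.factors <= 0):
            raise ValueError("expansion factors must be positive")


@dataclass(frozen=True)
class MassPair:
    """Dry (M0) and swollen (M1) mass of one sample, grams."""

    m_dry: float
    m_swollen: float

    def __post_init__(self) -> None:
        if not self.m_dry > 0:
            raise ValueError("dry mass must be positive")
        if self.m_swollen < self.m_dry:
            raise ValueError("swollen mass must be >= dry mass")


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± sample sd of a quantity over the samples of one group."""

    group: str
    timepoint: float  # hours
    mean: float
    sd: float
    n: int


def expansion_factor(wet: float, dry: float) -> float:
    """Ratio of a swollen dimension to its dry reference (LEF or REF)."""
    if not dry > 0 or not wet > 0:
        raise ValueError("wet and dry dimensions must be positive")
    return wet / dry


def expansion_series(d: DimensionSeries) -> ExpansionSeries:
    """Convert a tracked dimension series into an expansion-factor series."""
    return ExpansionSeries(
        sample_id=d.sample_id,
        direction=d.direction,
        times=d.times.copy(),
        factors=d.values / d.dry_reference,
    )


def factor_at(s: ExpansionSeries, t: float) -> float:
    """Expansion factor at time ``t`` (hours), linearly interpolated.

    Values are exact at recorded sample times; no extrapolation is
    performed outside the recorded range.
    """
    if t < s.times[0] or t > s.times[-1]:
        raise ValueError(
            f"t={t} h outside recorded range [{s.times[0]}, {s.times[-1]}] h"
        )
    return float(np.interp(t, s.times, s.factors))


def auc(s: ExpansionSeries, t0: float, t1: float) -> float:
    """Trapezoidal integral of the expansion factor over [t0, t1] hours.

    Endpoints off the sampling grid are linearly interpolated, so AUC is
    additive over adjacent windows.
    """
    if t0 >= t1:
        raise ValueError(f"need t0 < t1, got [{t0}, {t1}]")
    for t in (t0, t1):
        if t < s.times[0] or t > s.times[-1]:
            raise ValueError(f"t={t} h outside recorded range")
    inside = (s.times > t0) & (s.times < t1)
    ts = np.concatenate(([t0], s.times[inside], [t1]))
    fs = np.interp(ts, s.times, s.factors)
    return float(np.trapezoid(fs, ts))


def water_content(m: MassPair) -> float:
    """Gravimetric water content, percent: 100*(M1 - M0)/M1."""
    return 100.0 * (m.m_swollen - m.m_dry) / m.m_swollen


def mass_swelling(m: MassPair) -> float:
    """Mass-swelling ratio (M1 - M0)/M1, the water content as a fraction.

    Alias of :func:`water_content` on the fractional scale; reported
    group means such as 0.637 for C77 are on this scale.
    """
    return water_content(m) / 100.0


def group_summary(
    values: Sequence[float], group: str, timepoint: float
) -> GroupSummary:
    """Mean and sample standard deviation (n-1 denominator) of a group."""
    arr = _as_float_array(values, "values")
    if arr.size == 0:
        raise ValueError("cannot summarise an empty group")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(
        group=group,
        timepoint=timepoint,
        mean=float(np.mean(arr)),
        sd=sd,
        n=int(arr.size),
    )
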