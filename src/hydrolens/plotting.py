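"""Optional matplotlib views of swelling curves, power errors and traces.

matplotlib is imported lazily so the core package has no hard plotting
dependency (install the ``plot`` extra).
"""

from __future__ import annotations

from typing import Sequence

from .lidar import LidarTrace
from .optics import PowerErrorCurve
from .swelling import ExpansionSeries

__all__ = ["plot_expansion_series", "plot_power_error", "plot_lidar_trace"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_expansion_series(series: Sequence[ExpansionSeries], ax=None):
    """Expansion factor vs time, one line per sample."""
    ax = _axes(ax)
    for s in series:
        ax.plot(s.times, s.factors, label=f"{s.sample_id} ({s.direction})", lw=0.8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("expansion factor (wet/dry)")
    ax.legend(fontsize="x-small")
    return ax


def plot_power_error(curves: Sequence[PowerErrorCurve], ax=None):
    """Power error vs target power with the ISO tolerance band."""
    ax = _axes(ax)
    for c in curves:
        ax.plot(c.targets, c.errors, label=c.material)
    ref = curves[0]
    ax.fill_between(
        ref.targets, -ref.iso_tol, ref.iso_tol, alpha=0.2, color="grey",
        label="ISO tolerance",
    )
    ax.set_xlabel("target power (D)")
    ax.set_ylabel("power error (D)")
    ax.legend(fontsize="small")
    return ax


def plot_lidar_trace(trace: LidarTrace, ax=None, max_hours: float = 15.0):
    """Normalised distance vs time (first ``max_hours`` hours)."""
    ax = _axes(ax)
    hours = (trace.times - trace.times[0]) / 3600.0
    mask = hours <= max_hours
    ax.plot(hours[mask], trace.distances[mask], lw=0.6)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalised distance")
    return ax
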