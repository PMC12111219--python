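"""Synthetic cohort generator with the study's statistical structure.

Stands in for the laboratory rigs (tracking cameras, balance, laser
bench, LiDAR sensor): it produces dimension-versus-time series, mass
pairs, refraction-angle observations and LiDAR distance traces for a
5-group × 5-sample cohort, so the whole analysis chain is testable
without any instrument data.

Swelling kinetics are modelled as a saturating exponential plus a slow
linear creep,

    factor(t) = 1 + (plateau - 1 - creep*H) * (1 - exp(-t/tau)) + creep*t,

with H = 24 h, which reproduces the observed rapid rise within the first
~8 h followed by ongoing slow expansion.  For the Contaflex preset the
plateau and creep of each group/direction are solved so the *noiseless*
factor passes exactly through the published 17 h and 24 h group means;
the published standard deviations set the measurement noise.

Every random draw comes from a dedicated stream keyed by
(seed, group index, sample index, channel), so each sub-generator is
independently reproducible and a fixed seed yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .lidar import LidarTrace, PhaseSegmentation
from .materials import MaterialSpec, load_registry
from .optics import RefractionObservation, snell_refraction_angle
from .swelling import DimensionSeries, MassPair

__all__ = [
    "SwellKineticsParams",
    "CohortConfig",
    "CohortSample",
    "Cohort",
    "swelling_factor_curve",
    "solve_kinetics_from_anchors",
    "gen_swelling_series",
    "contaflex_preset",
    "gen_lidar_trace",
    "gen_masses",
    "gen_refraction_obs",
    "gen_cohort",
]

_HORIZON_H = 24.0
_CHANNELS = {"lateral": 0, "sagittal": 1, "mass": 2, "refraction": 3, "lidar": 4}


def _rng(seed: int, group_idx: int, sample_idx: int, channel: str) -> np.random.Generator:
    return np.random.default_rng(
        [int(seed), int(group_idx), int(sample_idx), _CHANNELS[channel]]
    )


@dataclass(frozen=True)
class SwellKineticsParams:
    """Generative kinetics for one group/direction.

    ``plateau`` is the asymptotic expansion factor of the saturating
    term, ``tau`` the saturation time constant (hours), ``creep`` the
    late-phase linear slope (per hour) and ``noise_sd`` the i.i.d.
    Gaussian measurement noise on the factor scale.
    """

    plateau: float
    tau: float
    creep: float
    noise_sd: float
    dry_reference: float  # mm

    def __post_init__(self) -> None:
        if self.plateau < 1:
            raise ValueError("plateau factor must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.dry_reference <= 0:
            raise ValueError("dry reference must be positive")


def swelling_factor_curve(p: SwellKineticsParams, t: np.ndarray) -> np.ndarray:
    """Noiseless expansion factor at times ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    amp = p.plateau - 1.0 - p.creep * _HORIZON_H
    return 1.0 + amp * (1.0 - np.exp(-t / p.tau)) + p.creep * t


def solve_kinetics_from_anchors(
    m17: float, m24: float, tau: float, noise_sd: float, dry_reference: float
) -> SwellKineticsParams:
    """Kinetics whose noiseless factor hits ``m17`` at 17 h and ``m24`` at 24 h.

    With tau fixed the factor model is linear in the saturating
    amplitude and the creep slope, so the two anchors determine both
    exactly (a 2×2 linear solve).
    """
    if m24 <= m17:
        raise ValueError(
            f"anchor means must increase in time, got {m17} at 17 h, {m24} at 24 h"
        )
    e17 = 1.0 - np.exp(-17.0 / tau)
    e24 = 1.0 - np.exp(-24.0 / tau)
    a_mat = np.array([[e17, 17.0], [e24, 24.0]])
    rhs = np.array([m17 - 1.0, m24 - 1.0])
    amp, creep = np.linalg.solve(a_mat, rhs)
    plateau = 1.0 + amp + creep * _HORIZON_H
    return SwellKineticsParams(
        plateau=float(plateau),
        tau=tau,
        creep=float(creep),
        noise_sd=noise_sd,
        dry_reference=dry_reference,
    )


def gen_swelling_series(
    p: SwellKineticsParams,
    direction: str,
    rng: np.random.Generator | int,
    sample_id: str = "s1",
    times: np.ndarray | None = None,
) -> DimensionSeries:
    """One tracked dimension series: kinetic curve × dry reference + noise."""
    if direction not in ("lateral", "sagittal"):
        raise ValueError(f"unknown direction {direction!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if times is None:
        times = np.arange(0.0, _HORIZON_H + 1e-9, 1.0 / 60.0)  # 1-min grid
    factors = swelling_factor_curve(p, times)
    if p.noise_sd > 0:
        factors = factors + rng.normal(0.0, p.noise_sd, size=times.shape)
    return DimensionSeries(
        sample_id=sample_id,
        direction=direction,  # type: ignore[arg-type]
        times=np.asarray(times, dtype=float),
        values=factors * p.dry_reference,
        dry_reference=p.dry_reference,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Layout and ground-truth parameters of a synthetic cohort."""

    groups: tuple[MaterialSpec, ...]
    kinetics: Mapping[tuple[str, str], SwellKineticsParams]  # (group, direction)
    samples_per_group: int = 5
    seed: int = 0
    times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, _HORIZON_H + 1e-9, 1.0 / 60.0)
    )
    mass_dry_g: float = 0.3
    mass_noise_sd: Mapping[str, float] | None = None  # g, per group
    theta_air_deg: float = 60.0
    angle_noise_deg: float = 0.5
    lidar_group: str = "C58"
    lidar_samples: int = 3
    lidar_fs_hz: float = 1.0
    lidar_duration_h: float = 15.0
    lidar_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")


def contaflex_preset(
    registry: Mapping[str, MaterialSpec] | None = None,
    tau: float = 2.5,
    seed: int = 0,
    noiseless: bool = False,
    dry_lateral_mm: float = 10.0,
    dry_sagittal_mm: float = 4.0,
) -> CohortConfig:
    """Cohort configuration anchored to the published Contaflex tables.

    Per group and direction, plateau and creep are solved so the
    noiseless factor curve passes exactly through the published 17 h and
    24 h means; noise is set from the published 24 h standard
    deviations (zeroed when ``noiseless``).
    """
    reg = load_registry() if registry is None else dict(registry)
    kinetics: dict[tuple[str, str], SwellKineticsParams] = {}
    mass_noise: dict[str, float] = {}
    for name, spec in reg.items():
        anchors = {
            "lateral": (spec.lef_17h, spec.lef_24h, dry_lateral_mm),
            "sagittal": (spec.ref_17h, spec.ref_24h, dry_sagittal_mm),
        }
        for direction, (a17, a24, dry) in anchors.items():
            kinetics[(name, direction)] = solve_kinetics_from_anchors(
                a17.mean,
                a24.mean,
                tau=tau,
                noise_sd=0.0 if noiseless else a24.sd,
                dry_reference=dry,
            )
        # propagate the published water-content sd to the swollen mass:
        # m1 = m0/(1 - wc), dm1/dwc = m0/(1 - wc)^2 per unit fraction
        wc = spec.lab_water_content.mean / 100.0
        dm_dwc = 0.3 / (1.0 - wc) ** 2
        mass_noise[name] = 0.0 if noiseless else dm_dwc * spec.lab_water_content.sd / 100.0
    return CohortConfig(
        groups=tuple(reg[n] for n in sorted(reg)),
        kinetics=kinetics,
        seed=seed,
        mass_noise_sd=mass_noise,
        angle_noise_deg=0.0 if noiseless else 0.5,
        lidar_noise_sd=0.0 if noiseless else 0.005,
    )


def gen_lidar_trace(
    dip_time: float = 2.0,
    peak_time: float = 9.0,
    plateau_time: float = 12.5,
    depth: float = 0.15,
    height: float = 0.08,
    plateau_value: float = 1.02,
    noise_sd: float = 0.005,
    duration_h: float = 15.0,
    fs_hz: float = 1.0,
    rng: np.random.Generator | int = 0,
) -> tuple[LidarTrace, PhaseSegmentation]:
    """Dip–rise–plateau transparency trace plus its ground-truth phases.

    The noiseless template is a C1 piecewise-cubic curve through the
    knots (0, 1), (dip_time, 1-depth), (peak_time, 1+height),
    (plateau_time, plateau_value) with zero slope at every knot, so the
    global minimum and maximum sit exactly at ``dip_time`` and
    ``peak_time`` and the curve is flat from ``plateau_time`` on.
    i.i.d. Gaussian sensor noise is added on the normalised scale.
    """
    if not dip_time < peak_time < plateau_time:
        raise ValueError("need dip_time < peak_time < plateau_time")
    if plateau_time >= duration_h:
        raise ValueError("trace must extend beyond the plateau onset")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    knots_h = np.array([0.0, dip_time, peak_time, plateau_time, duration_h])
    knot_vals = np.array([1.0, 1.0 - depth, 1.0 + height, plateau_value, plateau_value])
    spline = CubicHermiteSpline(knots_h, knot_vals, np.zeros_like(knot_vals))
    times_s = np.arange(0.0, duration_h * 3600.0, 1.0 / fs_hz)
    values = spline(times_s / 3600.0)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=times_s.shape)
    truth = PhaseSegmentation(
        growth_end=dip_time,
        transparency_peak=peak_time,
        equilibrium_start=plateau_time,
    )
    return LidarTrace(times=times_s, distances=values), truth


def gen_masses(
    water_content_pct: float,
    m_dry: float = 0.3,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> tuple[MassPair, bool]:
    """Mass pair whose water content recovers the anchor in expectation.

    m_swollen = m_dry / (1 - wc/100) + Gaussian noise.  A noise draw
    pushing the swollen mass below the dry mass is clipped to the dry
    mass (water content 0); the returned flag marks clipped pairs.
    """
    if not 0 < water_content_pct < 100:
        raise ValueError("water content must be in (0, 100) percent")
    if m_dry <= 0:
        raise ValueError("dry mass must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    m_swollen = m_dry / (1.0 - water_content_pct / 100.0)
    if noise_sd > 0:
        m_swollen += float(rng.normal(0.0, noise_sd))
    clipped = m_swollen < m_dry
    if clipped:
        m_swollen = m_dry
    return MassPair(m_dry=m_dry, m_swollen=m_swollen), bool(clipped)


def gen_refraction_obs(
    n_true: float,
    theta_air: float = 60.0,
    angle_noise_deg: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> RefractionObservation:
    """Laser-bench observation: forward Snell refraction plus angle noise."""
    if n_true < 1:
        raise ValueError("refractive index must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    theta_gel = snell_refraction_angle(n_true, theta_air)
    if angle_noise_deg > 0:
        theta_gel += float(rng.normal(0.0, angle_noise_deg))
        theta_gel = float(np.clip(theta_gel, 1e-6, theta_air))
    return RefractionObservation(theta_air=theta_air, theta_gel=theta_gel)


@dataclass(frozen=True)
class CohortSample:
    """All synthetic measurements for one physical sample."""

    group: str
    sample_id: str
    lateral: DimensionSeries
    sagittal: DimensionSeries
    mass: MassPair | None = None
    mass_clipped: bool = False
    refraction: RefractionObservation | None = None


@dataclass(frozen=True)
class Cohort:
    """A full synthetic dataset plus its generating ground truth."""

    config: CohortConfig
    samples: tuple[CohortSample, ...]
    lidar: tuple[LidarTrace, ...]
    lidar_truth: PhaseSegmentation
    truth: dict


def gen_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort described by ``config``.

    Deterministic for a fixed seed: per-sample RNG streams are derived
    from (seed, group index, sample index, channel).
    """
    samples: list[CohortSample] = []
    truth: dict = {"kinetics": {}, "water_content_pct": {}, "n_17h": {}}
    for gi, spec in enumerate(config.groups):
        truth["water_content_pct"][spec.name] = spec.lab_water_content.mean
        truth["n_17h"][spec.name] = spec.n_17h.mean
        for direction in ("lateral", "sagittal"):
            p = config.kinetics[(spec.name, direction)]
            truth["kinetics"][f"{spec.name}/{direction}"] = {
                "plateau": p.plateau,
                "tau": p.tau,
                "creep": p.creep,
                "noise_sd": p.noise_sd,
                "factor_17h": float(swelling_factor_curve(p, np.array([17.0]))[0]),
                "factor_24h": float(swelling_factor_curve(p, np.array([24.0]))[0]),
            }
        mass_sd = (config.mass_noise_sd or {}).get(spec.name, 0.0)
        for si in range(config.samples_per_group):
            sid = f"{spec.name}-{si + 1}"
            lateral = gen_swelling_series(
                config.kinetics[(spec.name, "lateral")],
                "lateral",
                _rng(config.seed, gi, si, "lateral"),
                sample_id=sid,
                times=config.times,
            )
            sagittal = gen_swelling_series(
                config.kinetics[(spec.name, "sagittal")],
                "sagittal",
                _rng(config.seed, gi, si, "sagittal"),
                sample_id=sid,
                times=config.times,
            )
            mass, clipped = gen_masses(
                spec.lab_water_content.mean,
                m_dry=config.mass_dry_g,
                noise_sd=mass_sd,
                rng=_rng(config.seed, gi, si, "mass"),
            )
            refraction = gen_refraction_obs(
                spec.n_17h.mean,
                theta_air=config.theta_air_deg,
                angle_noise_deg=config.angle_noise_deg,
                rng=_rng(config.seed, gi, si, "refraction"),
            )
            samples.append(
                CohortSample(
                    group=spec.name,
                    sample_id=sid,
                    lateral=lateral,
                    sagittal=sagittal,
                    mass=mass,
                    mass_clipped=clipped,
                    refraction=refraction,
                )
            )
    lidar_traces: list[LidarTrace] = []
    lidar_truth = PhaseSegmentation(2.0, 9.0, 12.5)
    gi_lidar = next(
        (i for i, g in enumerate(config.groups) if g.name == config.lidar_group), 0
    )
    for si in range(config.lidar_samples):
        trace, lidar_truth = gen_lidar_trace(
            noise_sd=config.lidar_noise_sd,
            duration_h=config.lidar_duration_h,
            fs_hz=config.lidar_fs_hz,
            rng=_rng(config.seed, gi_lidar, si, "lidar"),
        )
        lidar_traces.append(trace)
    return Cohort(
        config=config,
        samples=tuple(samples),
        lidar=tuple(lidar_traces),
        lidar_truth=lidar_truth,
        truth=truth,
    )
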