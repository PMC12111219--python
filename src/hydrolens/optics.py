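"""Lens optics: refractometry, optic-zone geometry and power-error simulation.

The simulation answers a manufacturing question: a soft contact lens is
lathed dry using the manufacturer's single isotropic swell factor, but
the material actually re-hydrates anisotropically (lateral LEF versus
axial REF) and to a refractive index that differs from the published
one.  What optical power does the swollen lens really deliver?

Pipeline per target power:

1. design the wet optic zone (back apex radius 8.6 mm by convention,
   front radius solved from the thick-lens equation with the
   manufacturer index);
2. shrink the design isotropically by 1/swell-factor to its dry state;
3. re-swell laterally by the measured LEF and axially by the measured
   REF (centre thickness scales axially);
4. fit axis-centred circles to the swollen front and back surface
   profiles to obtain effective central curvatures;
5. recompute the thick-lens power with the fitted radii, the scaled
   thickness and the measured refractive index.

The difference between this expected power and the target power is the
power error, compared against the ISO power-tolerance bands
(±0.25 D up to ±10 D, ±0.5 D up to ±20 D, ±1.0 D beyond).

Sign convention: the optical axis is z, the apex sits at the origin and
sag is non-negative; both surfaces are convex toward the incoming light
(a meniscus lens), so both apex radii are stored positive and the back
surface power is negative.  Radii live in millimetres and are converted
to metres only inside the power formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .materials import MaterialSpec

__all__ = [
    "RefractionObservation",
    "LensGeometry",
    "SurfaceProfile",
    "SwellTransform",
    "PowerErrorCurve",
    "SimulationConfig",
    "InfeasibleDesignError",
    "refractive_index_from_angles",
    "snell_refraction_angle",
    "thick_lens_power",
    "solve_front_radius",
    "build_profiles",
    "swell_transform",
    "fit_circle_radius",
    "iso_tolerance",
    "expected_power",
    "power_error_curve",
]


class InfeasibleDesignError(ValueError):
    """Raised when no physically valid lens realises the requested power."""


@dataclass(frozen=True)
class RefractionObservation:
    """One laser-bench measurement: incident and refracted angles.

    Angles are measured from the surface normal, in degrees.  The ray
    travels from air (n = 1) into the hydrogel, so it bends toward the
    normal: 0 < theta_gel <= theta_air < 90.
    """

    theta_air: float
    theta_gel: float

    def __post_init__(self) -> None:
        if not 0 < self.theta_gel <= self.theta_air < 90:
            raise ValueError(
                "need 0 < theta_gel <= theta_air < 90 degrees, got "
                f"({self.theta_air}, {self.theta_gel})"
            )


def refractive_index_from_angles(obs: RefractionObservation) -> float:
    """Snell's-law index recovery: n = sin(theta_air)/sin(theta_gel)."""
    return float(
        np.sin(np.deg2rad(obs.theta_air)) / np.sin(np.deg2rad(obs.theta_gel))
    )


def snell_refraction_angle(n_gel: float, theta_air: float) -> float:
    """Forward Snell model: refraction angle (degrees) inside the gel.

    Inverse of :func:`refractive_index_from_angles`; used by the
    synthetic bench generator.
    """
    if n_gel < 1:
        raise ValueError("hydrogel index must be >= 1 (denser than air)")
    if not 0 < theta_air < 90:
        raise ValueError("incident angle must be in (0, 90) degrees")
    return float(np.rad2deg(np.arcsin(np.sin(np.deg2rad(theta_air)) / n_gel)))


@dataclass(frozen=True)
class LensGeometry:
    """Optic-zone description of a meniscus contact lens."""

    r_front: float  # mm, front apex radius
    r_back: float  # mm, back apex radius (classic base curve 8.6)
    center_thickness: float  # mm
    zone_diameter: float  # mm
    n: float  # refractive index of the lens material

    def __post_init__(self) -> None:
        if self.r_front <= 0 or self.r_back <= 0:
            raise ValueError("apex radii must be positive")
        if self.center_thickness <= 0:
            raise ValueError("centre thickness must be positive")
        if self.zone_diameter <= 0:
            raise ValueError("zone diameter must be positive")
        if self.zone_diameter / 2 >= min(self.r_front, self.r_back):
            raise InfeasibleDesignError(
                "optic-zone half-chord must be smaller than both apex radii "
                f"(zone {self.zone_diameter} mm vs radii "
                f"{self.r_front:.3f}/{self.r_back:.3f} mm)"
            )
        if not 1 < self.n < 2:
            raise ValueError("refractive index must lie in (1, 2)")


@dataclass(frozen=True)
class SurfaceProfile:
    """Meridional sag profile of one axisymmetric surface.

    ``x`` are lateral offsets from the axis (mm, symmetric about 0) and
    ``z`` the sag relative to the apex (mm, z(0) = 0, non-negative).
    """

    x: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        if x.size != z.size or x.size < 1:
            raise ValueError("x and z must be equal-length, non-empty")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
            raise ValueError("profile contains non-finite values")
        if np.any(z < -1e-12):
            raise ValueError("sag must be non-negative")


@dataclass(frozen=True)
class SwellTransform:
    """Anisotropic similarity: lateral scale ``a`` (LEF), axial ``b`` (REF)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("swell scales must be positive")


def _surface_powers(g: LensGeometry) -> tuple[float, float]:
    f1 = (g.n - 1.0) / (g.r_front * 1e-3)
    f2 = -(g.n - 1.0) / (g.r_back * 1e-3)
    return f1, f2


def thick_lens_power(g: LensGeometry) -> float:
    """Paraxial power (dioptres) of the lens in air.

    P = F1 + F2 - (t/n) F1 F2 with surface powers
    F1 = (n-1)/r_front, F2 = -(n-1)/r_back (meniscus convention,
    radii in metres).
    """
    f1, f2 = _surface_powers(g)
    t = g.center_thickness * 1e-3
    return float(f1 + f2 - (t / g.n) * f1 * f2)


def solve_front_radius(
    target: float, r_back: float, t: float, n: float
) -> float:
    """Front apex radius (mm) delivering ``target`` dioptres.

    Closed-form inversion of the thick-lens equation, which is linear in
    the front surface power F1:
    F1 = (P - F2) / (1 - (t/n) F2).
    """
    if r_back <= 0:
        raise ValueError("back radius must be positive")
    if t < 0:
        raise ValueError("thickness must be non-negative")
    f2 = -(n - 1.0) / (r_back * 1e-3)
    f1 = (target - f2) / (1.0 - (t * 1e-3 / n) * f2)
    if f1 <= 0:
        raise InfeasibleDesignError(
            f"target {target} D needs non-positive front power F1={f1:.3f}; "
            "not representable as a meniscus with this base curve"
        )
    return float((n - 1.0) / f1 * 1e3)


def _spherical_sag(r: float, x: np.ndarray) -> np.ndarray:
    if np.max(np.abs(x)) >= r:
        raise InfeasibleDesignError(
            f"half-chord {np.max(np.abs(x)):.3f} mm >= apex radius {r:.3f} mm; "
            "spherical cap does not exist"
        )
    return r - np.sqrt(r**2 - x**2)


def build_profiles(
    g: LensGeometry, n_points: int = 201
) -> tuple[SurfaceProfile, SurfaceProfile]:
    """Sample front and back spherical-cap sag profiles over the zone.

    Both profiles use z(x) = R - sqrt(R^2 - x^2) relative to their own
    apex on a symmetric grid spanning the optic-zone diameter.
    """
    if n_points < 3:
        raise ValueError("need at least 3 sample points")
    x = np.linspace(-g.zone_diameter / 2, g.zone_diameter / 2, n_points)
    return (
        SurfaceProfile(x=x, z=_spherical_sag(g.r_front, x)),
        SurfaceProfile(x=x, z=_spherical_sag(g.r_back, x)),
    )


def swell_transform(p: SurfaceProfile, s: SwellTransform) -> SurfaceProfile:
    """Scale a profile laterally by ``a`` and axially by ``b``.

    The uniform dry conversion is the special case
    a = b = 1/(manufacturer swell factor).
    """
    return SurfaceProfile(x=p.x * s.a, z=p.z * s.b)


def fit_circle_radius(p: SurfaceProfile) -> float:
    """Effective central radius (mm) by axis-centred least-squares fit.

    Algebraic (Kåsa) circle fit reduced to one free centre coordinate:
    for an axisymmetric surface the centre lies on the z axis at
    (0, z0), giving the linear model x^2 + z^2 = 2 z z0 + (R^2 - z0^2).
    """
    pts = np.unique(np.column_stack([p.x, p.z]).round(12), axis=0)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 distinct points for a circle fit")
    x, z = pts[:, 0], pts[:, 1]
    design = np.column_stack([2.0 * z, np.ones_like(z)])
    rhs = x**2 + z**2
    sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 2:
        raise ValueError("points are collinear; circle radius undefined")
    z0, c = sol
    r2 = c + z0**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    return float(np.sqrt(r2))


def iso_tolerance(power: float) -> float:
    """ISO back-vertex power tolerance band (dioptres) for a labelled power."""
    if not np.isfinite(power):
        raise ValueError("power must be finite")
    p = abs(power)
    if p <= 10.0:
        return 0.25
    if p <= 20.0:
        return 0.5
    return 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the wet→dry→re-wet power simulation.

    ``fit_zone_diameter`` is the chord over which circles are fitted to
    the swollen surfaces (clipped to the available swollen zone).  The
    effective curvature of an anisotropically swollen sphere depends on
    this width, so it is exposed prominently rather than buried.
    """

    back_radius: float = 8.6  # mm, classic base curve
    center_thickness: float = 0.5  # mm, wet design value
    zone_diameter: float = 8.0  # mm, wet optic zone
    fit_zone_diameter: float = 8.0  # mm, chord used for circle fitting
    n_points: int = 201
    timepoint: str = "24h"


@dataclass(frozen=True)
class PowerErrorCurve:
    """Expected-vs-target power over a grid, with ISO tolerance flags."""

    material: str
    targets: np.ndarray  # D
    expected: np.ndarray  # D (NaN where infeasible)
    errors: np.ndarray  # D, expected - target
    iso_tol: np.ndarray  # D
    within_iso: np.ndarray  # bool
    infeasible: tuple[float, ...]  # targets with no valid design

    def max_abs_error(self) -> float:
        return float(np.nanmax(np.abs(self.errors)))

    def iso_compliant_fraction(self) -> float:
        ok = ~np.isnan(self.errors)
        return float(np.mean(self.within_iso[ok])) if ok.any() else float("nan")


def _clip_to_fit_zone(p: SurfaceProfile, half_chord: float) -> SurfaceProfile:
    mask = np.abs(p.x) <= half_chord + 1e-12
    return SurfaceProfile(x=p.x[mask], z=p.z[mask])


def expected_power(
    design: LensGeometry,
    material: MaterialSpec,
    timepoint: str = "24h",
    fit_zone_diameter: float = 8.0,
    n_points: int = 201,
) -> float:
    """Power (D) actually delivered by a lens lathed for this design.

    Runs the wet→dry→re-wet chain: the wet ``design`` (built with the
    manufacturer index) is shrunk isotropically by the manufacturer
    swell factor, re-swollen with the measured LEF (lateral) and REF
    (axial) group means at ``timepoint``, circle-fitted, and evaluated
    with the measured refractive index.
    """
    lef, ref = material.expansion(timepoint)
    n_lab = material.refractive_index(timepoint)
    sf = material.manufacturer_swell_factor

    front, back = build_profiles(design, n_points=n_points)
    net = SwellTransform(a=lef / sf, b=ref / sf)
    front_sw = swell_transform(front, net)
    back_sw = swell_transform(back, net)

    half = min(fit_zone_diameter / 2.0, float(np.max(np.abs(front_sw.x))))
    r_front = fit_circle_radius(_clip_to_fit_zone(front_sw, half))
    r_back = fit_circle_radius(_clip_to_fit_zone(back_sw, half))

    swollen = LensGeometry(
        r_front=r_front,
        r_back=r_back,
        center_thickness=design.center_thickness * net.b,
        zone_diameter=2.0 * half,
        n=n_lab,
    )
    return thick_lens_power(swollen)


def power_error_curve(
    material: MaterialSpec,
    grid: Sequence[float] | None = None,
    config: SimulationConfig | None = None,
) -> PowerErrorCurve:
    """Expected power, error and ISO compliance over a target-power grid.

    Infeasible targets (no meniscus design exists) are kept in the grid
    with NaN expected power and listed in ``infeasible`` rather than
    silently dropped.
    """
    cfg = config or SimulationConfig()
    targets = (
        np.arange(-20.0, 20.0 + 1e-9, 0.25)
        if grid is None
        else np.asarray(grid, dtype=float)
    )
    expected = np.full(targets.shape, np.nan)
    infeasible: list[float] = []
    for i, target in enumerate(targets):
        try:
            r_front = solve_front_radius(
                target, cfg.back_radius, cfg.center_thickness, material.manufacturer_n
            )
            design = LensGeometry(
                r_front=r_front,
                r_back=cfg.back_radius,
                center_thickness=cfg.center_thickness,
                zone_diameter=cfg.zone_diameter,
                n=material.manufacturer_n,
            )
            expected[i] = expected_power(
                design,
                material,
                timepoint=cfg.timepoint,
                fit_zone_diameter=cfg.fit_zone_diameter,
                n_points=cfg.n_points,
            )
        except InfeasibleDesignError:
            infeasible.append(float(target))
    errors = expected - targets
    iso = np.array([iso_tolerance(t) for t in targets])
    within = np.abs(errors) <= iso
    return PowerErrorCurve(
        material=material.name,
        targets=targets,
        expected=expected,
        errors=errors,
        iso_tol=iso,
        within_iso=within,
        infeasible=tuple(infeasible),
    )
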