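"""Registry of Contaflex hydrogel material constants.

The five material groups (C38, C55, C58, C67, C77) are group-I
polymacon-based hydrogels named after their manufacturer-stated nominal
water content (percent).  For each group the registry stores the
manufacturer's published swell factor and refractive index together with
laboratory-measured linear and radial expansion factors (LEF, REF),
refractive indices at the 17 h and 24 h hydration timepoints, and the
gravimetric water content.  All downstream modules (swelling analysis,
optics simulation, synthetic cohorts) resolve their constants through
this registry, so alternative material tables can be substituted by
pointing :func:`load_registry` at a different CSV file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "Measured",
    "MaterialSpec",
    "MaterialNotFoundError",
    "MATERIAL_NAMES",
    "load_registry",
    "save_registry",
    "get_material",
]

MATERIAL_NAMES = ("C38", "C55", "C58", "C67", "C77")


class MaterialNotFoundError(KeyError):
    """Raised when a material label is not present in the registry."""


@dataclass(frozen=True)
class Measured:
    """A laboratory quantity reported as mean ± sample standard deviation."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"standard deviation must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class MaterialSpec:
    """Constants for one hydrogel material group.

    Attributes
    ----------
    name:
        Group label, e.g. ``"C77"``.
    nominal_water_content:
        Manufacturer-stated equilibrium water content, percent.
    manufacturer_swell_factor:
        Single isotropic wet/dry scale published by the manufacturer,
        used to derive dry lathing dimensions from wet targets.
    manufacturer_n:
        Manufacturer-published refractive index of the hydrated material.
    lef_17h, lef_24h:
        Measured linear (diameter) expansion factors at 17 h and 24 h.
    ref_17h, ref_24h:
        Measured radial (sagittal-depth) expansion factors.
    n_17h, n_24h:
        Laser-refractometry refractive indices at the two timepoints.
    lab_water_content:
        Gravimetric water content 100*(M1-M0)/M1, percent.
    """

    name: str
    nominal_water_content: float
    manufacturer_swell_factor: float
    manufacturer_n: float
    lef_17h: Measured
    lef_24h: Measured
    ref_17h: Measured
    ref_24h: Measured
    n_17h: Measured
    n_24h: Measured
    lab_water_content: Measured

    def __post_init__(self) -> None:
        if self.manufacturer_swell_factor < 1:
            raise ValueError(f"{self.name}: swell factor must be >= 1")
        for attr in ("lef_17h", "lef_24h", "ref_17h", "ref_24h"):
            if getattr(self, attr).mean < 1:
                raise ValueError(f"{self.name}: {attr} mean must be >= 1")
        for attr in ("manufacturer_n",):
            n = getattr(self, attr)
            if not 1 < n < 2:
                raise ValueError(f"{self.name}: {attr}={n} outside (1, 2)")
        for attr in ("n_17h", "n_24h"):
            n = getattr(self, attr).mean
            if not 1 < n < 2:
                raise ValueError(f"{self.name}: {attr} mean={n} outside (1, 2)")
        for attr in ("nominal_water_content",):
            wc = getattr(self, attr)
            if not 0 < wc < 100:
                raise ValueError(f"{self.name}: {attr}={wc} outside (0, 100)")
        if not 0 < self.lab_water_content.mean < 100:
            raise ValueError(f"{self.name}: lab water content outside (0, 100)")

    def expansion(self, timepoint: str) -> tuple[float, float]:
        """Return the (LEF, REF) group means at ``"17h"`` or ``"24h"``."""
        if timepoint == "17h":
            return self.lef_17h.mean, self.ref_17h.mean
        if timepoint == "24h":
            return self.lef_24h.mean, self.ref_24h.mean
        raise ValueError(f"unknown timepoint {timepoint!r}; use '17h' or '24h'")

    def refractive_index(self, timepoint: str) -> float:
        """Measured group-mean refractive index at ``"17h"`` or ``"24h"``."""
        if timepoint == "17h":
            return self.n_17h.mean
        if timepoint == "24h":
            return self.n_24h.mean
        raise ValueError(f"unknown timepoint {timepoint!r}; use '17h' or '24h'")


# CSV columns <-> MaterialSpec fields.  Measured fields expand to _mean/_sd.
_SCALAR_FIELDS = (
    "nominal_water_content",
    "manufacturer_swell_factor",
    "manufacturer_n",
)
_MEASURED_FIELDS = (
    "lef_17h",
    "lef_24h",
    "ref_17h",
    "ref_24h",
    "n_17h",
    "n_24h",
    "lab_water_content",
)


def _columns() -> list[str]:
    cols = ["name", *_SCALAR_FIELDS]
    for f in _MEASURED_FIELDS:
        cols += [f"{f}_mean", f"{f}_sd"]
    return cols


def load_registry(path: str | Path | None = None) -> dict[str, MaterialSpec]:
    """Load a material table into a name-keyed registry.

    With no argument the table bundled with the package (the five
    Contaflex groups) is loaded.  The CSV must carry one row per
    material with columns named after :class:`MaterialSpec` fields,
    mean/sd quantities split into ``<field>_mean`` / ``<field>_sd``.
    """
    if path is None:
        with resources.files("hydrolens.data").joinpath("materials.csv").open() as fh:
            table = pd.read_csv(fh, float_precision="round_trip")
    else:
        table = pd.read_csv(path, float_precision="round_trip")
    missing = set(_columns()) - set(table.columns)
    if missing:
        raise ValueError(f"material table is missing columns: {sorted(missing)}")
    registry: dict[str, MaterialSpec] = {}
    for _, row in table.iterrows():
        kwargs: dict[str, object] = {"name": str(row["name"])}
        for f in _SCALAR_FIELDS:
            kwargs[f] = float(row[f])
        for f in _MEASURED_FIELDS:
            kwargs[f] = Measured(float(row[f"{f}_mean"]), float(row[f"{f}_sd"]))
        registry[str(row["name"])] = MaterialSpec(**kwargs)  # type: ignore[arg-type]
    return registry


def save_registry(registry: Mapping[str, MaterialSpec], path: str | Path) -> None:
    """Write a registry back to the documented CSV layout.

    Floats are serialised with ``repr`` so a save/load round trip
    reproduces every constant bit-exactly.
    """
    rows = []
    for spec in registry.values():
        row: dict[str, object] = {"name": spec.name}
        for f in _SCALAR_FIELDS:
            row[f] = repr(getattr(spec, f))
        for f in _MEASURED_FIELDS:
            m: Measured = getattr(spec, f)
            row[f"{f}_mean"] = repr(m.mean)
            row[f"{f}_sd"] = repr(m.sd)
        rows.append(row)
    pd.DataFrame(rows, columns=_columns()).to_csv(path, index=False)


def get_material(
    name: str, registry: Mapping[str, MaterialSpec] | None = None
) -> MaterialSpec:
    """Look up one material by its group label.

    Raises
    ------
    MaterialNotFoundError
        If the label is unknown; the error message lists valid labels.
    """
    reg = load_registry() if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        raise MaterialNotFoundError(
            f"unknown material {name!r}; valid labels: {sorted(reg)}"
        ) from None
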