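"""Surface-area estimation from linear morphometrics.

Region surface areas are estimated from caliper measurements using simple
solids of revolution: the bill as the lateral surface of a nearly circular
elliptical cone (measured either from the anterior edge of the nares, the
"cone", or from the base of the bill, the full bill), the two tarsi as
elliptical cylinders, and the body from the classic mass allometry
A = 8.11 m^0.67 (A in cm^2, m in g).  Toes are excluded from the leg area
and the feathered tibia is counted as body surface.

Units: linear measurements are millimetres, masses grams; all areas returned
here are mm^2 and body volume cm^3.  Conversion to SI happens at exactly one
point, inside the heat-budget module, so that mm^2 values can never silently
enter a wattage formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "LinearMeasurements",
    "RegionAreas",
    "PhysicalConstants",
    "bill_cone_area",
    "bill_total_area",
    "legs_area",
    "body_area",
    "body_volume",
    "derive_region_areas",
    "relative_areas",
    "percent_increase",
    "read_morphometrics",
    "write_morphometrics",
    "table1_summary",
]

#: mm^2 per cm^2, the single area conversion used by the body allometry.
_MM2_PER_CM2 = 100.0


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class LinearMeasurements:
    """Caliper measurements for one bird (mm) plus mass (g).

    Bill dimensions are taken both at the anterior edge of the nares
    (``*_nares``, defining the exposed bill cone) and at the base of the
    bill (``*_base``, defining the full bill).
    """

    bill_length_nares: float
    bill_width_nares: float
    bill_depth_nares: float
    bill_length_base: float
    bill_width_base: float
    bill_depth_base: float
    tarsus_length: float
    tarsus_width: float
    tarsus_depth: float
    wing_chord: float
    mass: float

    def __post_init__(self) -> None:
        _require_positive(**{f.name: getattr(self, f.name) for f in fields(self)})
        for dim in ("length", "width", "depth"):
            base = getattr(self, f"bill_{dim}_base")
            nares = getattr(self, f"bill_{dim}_nares")
            if base < nares:
                raise ValueError(
                    f"bill_{dim}_base ({base}) must be >= bill_{dim}_nares ({nares})"
                )


@dataclass(frozen=True)
class RegionAreas:
    """Per-region surface areas (mm^2) and body volume (cm^3) for one bird."""

    bill_cone_area: float
    bill_total_area: float
    legs_area: float
    body_area: float
    body_volume: float

    @property
    def total_area(self) -> float:
        """Whole-bird area: full bill + both tarsi + body (mm^2)."""
        return self.bill_total_area + self.legs_area + self.body_area


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the heat-budget model.

    emissivity
        Long-wave emissivity of biological surfaces (0.96).
    stefan_boltzmann
        W m^-2 K^-4.
    air_velocity
        Bulk air speed in the chamber, m/s; forced convection assumes 0.1.
    bird_density
        Whole-body density of a sparrow, g/cm^3, used for volume from mass.
    latent_heat_vaporization
        J per g of water, used to convert heat savings into water savings.
    """

    emissivity: float = 0.96
    stefan_boltzmann: float = 5.6703e-8
    air_velocity: float = 0.1
    bird_density: float = 0.913
    latent_heat_vaporization: float = 2418.0

    def __post_init__(self) -> None:
        if not 0 < self.emissivity <= 1:
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")
        _require_positive(
            stefan_boltzmann=self.stefan_boltzmann,
            air_velocity=self.air_velocity,
            bird_density=self.bird_density,
            latent_heat_vaporization=self.latent_heat_vaporization,
        )


def bill_cone_area(width: float, depth: float, length: float) -> float:
    """Lateral surface of the bill cone, ((W+D)/4)·L·π, in mm^2.

    W, D and L are bill width, depth and length at the anterior edge of the
    nares.  The printed length is used directly, without slant-height
    correction.
    """
    _require_positive(width=width, depth=depth, length=length)
    return (width + depth) / 4.0 * length * math.pi


def bill_total_area(width_base: float, depth_base: float, length_base: float) -> float:
    """Lateral surface of the full bill: same cone formula, base measurements."""
    _require_positive(
        width_base=width_base, depth_base=depth_base, length_base=length_base
    )
    return (width_base + depth_base) / 4.0 * length_base * math.pi


def legs_area(width: float, depth: float, length: float) -> float:
    """Lateral surface of both tarsi modelled as elliptical cylinders, mm^2.

    Perimeter approximation π·sqrt(2((w/2)^2+(d/2)^2) − 0.5(w−d)^2), times
    tarsus length, times two legs.  Toes and the feathered tibia are not
    part of this area.
    """
    _require_positive(width=width, depth=depth, length=length)
    radicand = 2.0 * ((width / 2.0) ** 2 + (depth / 2.0) ** 2) - 0.5 * (width - depth) ** 2
    if radicand <= 0:
        raise ValueError(
            f"elliptical-cylinder radicand must be positive, got {radicand} "
            f"for width={width}, depth={depth}"
        )
    return math.pi * math.sqrt(radicand) * length * 2.0


def body_area(mass: float) -> float:
    """Body surface from mass allometry A = 8.11 m^0.67 (cm^2), returned in mm^2."""
    _require_positive(mass=mass)
    return 8.11 * mass**0.67 * _MM2_PER_CM2


def body_volume(mass: float, density: float = PhysicalConstants().bird_density) -> float:
    """Body volume m/ρ in cm^3 for mass in g and density in g/cm^3."""
    _require_positive(mass=mass, density=density)
    return mass / density


def derive_region_areas(
    m: LinearMeasurements, constants: PhysicalConstants | None = None
) -> RegionAreas:
    """All region areas and body volume for one bird's measurements."""
    constants = constants or PhysicalConstants()
    return RegionAreas(
        bill_cone_area=bill_cone_area(
            m.bill_width_nares, m.bill_depth_nares, m.bill_length_nares
        ),
        bill_total_area=bill_total_area(
            m.bill_width_base, m.bill_depth_base, m.bill_length_base
        ),
        legs_area=legs_area(m.tarsus_width, m.tarsus_depth, m.tarsus_length),
        body_area=body_area(m.mass),
        body_volume=body_volume(m.mass, constants.bird_density),
    )


def relative_areas(areas: RegionAreas) -> tuple[float, float, float]:
    """(bill, legs, body) as percentages of total surface area; sums to 100."""
    total = areas.total_area
    if not total > 0:
        raise ValueError(f"total_area must be positive, got {total}")
    return (
        100.0 * areas.bill_total_area / total,
        100.0 * areas.legs_area / total,
        100.0 * areas.body_area / total,
    )


def percent_increase(larger_mean: float, smaller_mean: float) -> float:
    """Percent by which ``larger_mean`` exceeds ``smaller_mean``."""
    if not smaller_mean > 0:
        raise ValueError(f"smaller_mean must be positive, got {smaller_mean}")
    return 100.0 * (larger_mean - smaller_mean) / smaller_mean


# ---------------------------------------------------------------------------
# Tabular I/O

MORPHOMETRICS_COLUMNS = [
    "bird_id",
    "subspecies",
    *[f.name for f in fields(LinearMeasurements)],
]


def read_morphometrics(path) -> pd.DataFrame:
    """Read a per-bird morphometrics CSV; validates the documented header."""
    df = pd.read_csv(path)
    missing = set(MORPHOMETRICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"morphometrics file missing columns: {sorted(missing)}")
    return df


def write_morphometrics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def table1_summary(
    birds: pd.DataFrame,
    group_col: str = "subspecies",
    groups: tuple[str, str] = ("melodia", "atlantica"),
) -> pd.DataFrame:
    """Morphometric comparison table between two cohorts.

    One row per measurement with the group means and SDs, the
    equal-variance two-sample t-test P (Bonferroni-corrected across the
    rows) and the percent increase of the larger over the smaller mean.
    Values are carried at full precision; round only for display.
    """
    from .model_selection import pooled_t_bonferroni

    rows = []
    measures = [
        ("wing_chord", "Wing chord (mm)"),
        ("mass", "Mass (g)"),
        ("tarsus_length", "Tarsus (mm)"),
        ("bill_cone_area", "Bill cone area (mm2)"),
        ("bill_total_area", "Total bill area (mm2)"),
        ("legs_area", "Leg area (mm2)"),
        ("body_area", "Body area (mm2)"),
        ("bill_pct", "Total bill area as a percent of entire area"),
        ("legs_pct", "Leg area as a percent of entire area"),
        ("body_pct", "Body area as a percent of entire area"),
    ]
    birds = birds.copy()
    total = birds["bill_total_area"] + birds["legs_area"] + birds["body_area"]
    birds["bill_pct"] = 100.0 * birds["bill_total_area"] / total
    birds["legs_pct"] = 100.0 * birds["legs_area"] / total
    birds["body_pct"] = 100.0 * birds["body_area"] / total

    available = [(c, label) for c, label in measures if c in birds.columns]
    n_tests = len(available)
    for col, label in available:
        a = birds.loc[birds[group_col] == groups[0], col].to_numpy(float)
        b = birds.loc[birds[group_col] == groups[1], col].to_numpy(float)
        p_adj = pooled_t_bonferroni(a, b, n_tests=n_tests)
        lo, hi = sorted([a.mean(), b.mean()])
        rows.append(
            {
                "measurement": label,
                f"{groups[0]}_mean": a.mean(),
                f"{groups[0]}_sd": a.std(ddof=1),
                f"{groups[1]}_mean": b.mean(),
                f"{groups[1]}_sd": b.std(ddof=1),
                "p_bonferroni": p_adj,
                "percent_increase": percent_increase(hi, lo) if lo > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
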