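"""Radiative + forced-convective dry heat loss per body region.

For each region (full bill, both tarsi, body) the dry heat flux is

    Q = Q_r + Q_c
    Q_r = eps * sigma * A * (Ts_K^4 - Ta_K^4)
    Q_c = h_c * A * (Ts - Ta),   h_c = Nu * k / D,
    Nu  = c * Re^n,              Re  = V * D / nu

with region-specific convection constants (c, n) = (0.174, 0.618) for bill
and legs and (0.34, 0.6) for the body, and characteristic dimension D equal
to half the bill depth, the tarsus length, and the cube root of body volume
respectively.  Air conductivity k and kinematic viscosity nu come from
:mod:`billheat.air`.  No free convection, solar gain, or evaporative or
respiratory exchange is modelled: the chamber had neither radiative load
nor wind.

Surface areas enter the public interface only as :class:`RegionAreas`
(mm^2); the mm^2 -> m^2 conversion happens here, once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .air import AirPropertyConfig
from .morphometrics import PhysicalConstants, RegionAreas

__all__ = [
    "RegionConvectionParams",
    "RegionTemperatures",
    "RegionHeat",
    "HeatBudget",
    "BILL_CONVECTION",
    "LEGS_CONVECTION",
    "BODY_CONVECTION",
    "radiative_heat",
    "reynolds",
    "nusselt",
    "convective_coefficient",
    "convective_heat",
    "region_heat_loss",
    "full_budget",
    "water_savings",
    "budget_table",
]

_KELVIN = 273.15
_M2_PER_MM2 = 1e-6  # single mm^2 -> m^2 conversion point
_M_PER_MM = 1e-3
_M_PER_CM = 1e-2


@dataclass(frozen=True)
class RegionConvectionParams:
    """Forced-convection constants and characteristic dimension for a region."""

    region: str
    c: float
    n: float
    characteristic_dimension_m: float

    def __post_init__(self) -> None:
        if not self.characteristic_dimension_m > 0:
            raise ValueError(
                f"characteristic dimension for {self.region} must be positive, "
                f"got {self.characteristic_dimension_m}"
            )


def BILL_CONVECTION(bill_depth_base_mm: float) -> RegionConvectionParams:
    """Bill: cylinder-in-crossflow constants, D = half the bill depth at the base."""
    return RegionConvectionParams("bill", 0.174, 0.618, bill_depth_base_mm / 2.0 * _M_PER_MM)


def LEGS_CONVECTION(tarsus_length_mm: float) -> RegionConvectionParams:
    """Legs: same constants as the bill, D = tarsus length."""
    return RegionConvectionParams("legs", 0.174, 0.618, tarsus_length_mm * _M_PER_MM)


def BODY_CONVECTION(body_volume_cm3: float) -> RegionConvectionParams:
    """Body: blunt-body constants, D = cube root of body volume."""
    return RegionConvectionParams("body", 0.34, 0.6, body_volume_cm3 ** (1.0 / 3.0) * _M_PER_CM)


@dataclass(frozen=True)
class RegionTemperatures:
    """Mean surface temperatures (degC) of the thermography regions of interest."""

    bill: float
    bill_base: float
    bill_cone: float
    legs: float
    body: float

    def check_plausible(self, ta: float) -> None:
        """Warn (not fail) when a surface leaves the [Ta-5, 45] degC band."""
        for name in ("bill", "bill_base", "bill_cone", "legs", "body"):
            t = getattr(self, name)
            if not (ta - 5.0 <= t <= 45.0):
                warnings.warn(
                    f"surface temperature {name}={t} degC outside plausibility "
                    f"band [{ta - 5.0}, 45.0] at Ta={ta}",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class RegionHeat:
    """Radiative / convective split for one region (W)."""

    q_radiative: float
    q_convective: float

    @property
    def q(self) -> float:
        return self.q_radiative + self.q_convective


@dataclass(frozen=True)
class HeatBudget:
    """Per-region and total dry heat loss for one observation (W)."""

    bill: RegionHeat
    legs: RegionHeat
    body: RegionHeat

    @property
    def q_bill(self) -> float:
        return self.bill.q

    @property
    def q_legs(self) -> float:
        return self.legs.q

    @property
    def q_body(self) -> float:
        return self.body.q

    @property
    def q_total(self) -> float:
        return self.bill.q + self.legs.q + self.body.q

    @property
    def percent_q_bill(self) -> float:
        """Bill share of total heat loss, %; NaN when the total is not positive."""
        total = self.q_total
        if total <= 0:
            return float("nan")
        return 100.0 * self.q_bill / total


def radiative_heat(Ts: float, Ta: float, area_m2: float, emissivity: float) -> float:
    """Net long-wave exchange eps*sigma*A*(Ts_K^4 - Ta_K^4), W; positive when Ts > Ta."""
    if not area_m2 > 0:
        raise ValueError(f"area_m2 must be positive, got {area_m2}")
    sigma = PhysicalConstants().stefan_boltzmann
    return emissivity * sigma * area_m2 * ((Ts + _KELVIN) ** 4 - (Ta + _KELVIN) ** 4)


def reynolds(velocity: float, D: float, nu: float) -> float:
    """Reynolds number V*D/nu."""
    return velocity * D / nu


def nusselt(Re: float, c: float, n: float) -> float:
    """Forced-convection Nusselt number c*Re^n."""
    return c * Re**n


def convective_coefficient(Nu: float, k: float, D: float) -> float:
    """Heat transfer coefficient h_c = Nu*k/D, W m^-2 K^-1."""
    if not D > 0:
        raise ValueError(f"characteristic dimension D must be positive, got {D}")
    return Nu * k / D


def convective_heat(hc: float, area_m2: float, Ts: float, Ta: float) -> float:
    """Convective flux h_c*A*(Ts - Ta), W."""
    return hc * area_m2 * (Ts - Ta)


def region_heat_loss(
    Ts: float,
    Ta: float,
    area_mm2: float,
    params: RegionConvectionParams,
    constants: PhysicalConstants | None = None,
    air_config: AirPropertyConfig | None = None,
) -> RegionHeat:
    """Radiative and convective heat loss of one region, W.

    ``area_mm2`` is in mm^2 as produced by the morphometrics module;
    a surface colder than the air yields negative heat loss (no clamping).
    """
    constants = constants or PhysicalConstants()
    air_config = air_config or AirPropertyConfig()
    area_m2 = area_mm2 * _M2_PER_MM2
    q_r = radiative_heat(Ts, Ta, area_m2, constants.emissivity)
    k = air_config.conductivity(Ts, Ta)
    nu = air_config.viscosity(Ts, Ta)
    Re = reynolds(constants.air_velocity, params.characteristic_dimension_m, nu)
    Nu = nusselt(Re, params.c, params.n)
    hc = convective_coefficient(Nu, k, params.characteristic_dimension_m)
    q_c = convective_heat(hc, area_m2, Ts, Ta)
    return RegionHeat(q_radiative=q_r, q_convective=q_c)


def full_budget(
    areas: RegionAreas,
    temps: RegionTemperatures,
    ta: float,
    bill_depth_base_mm: float,
    tarsus_length_mm: float,
    constants: PhysicalConstants | None = None,
    air_config: AirPropertyConfig | None = None,
) -> HeatBudget:
    """Whole-bird dry heat budget for one observation.

    The bill term uses the full bill area with the whole-bill mean surface
    temperature; legs use both tarsi; body uses the mass-allometric area.
    """
    constants = constants or PhysicalConstants()
    return HeatBudget(
        bill=region_heat_loss(
            temps.bill, ta, areas.bill_total_area,
            BILL_CONVECTION(bill_depth_base_mm), constants, air_config,
        ),
        legs=region_heat_loss(
            temps.legs, ta, areas.legs_area,
            LEGS_CONVECTION(tarsus_length_mm), constants, air_config,
        ),
        body=region_heat_loss(
            temps.body, ta, areas.body_area,
            BODY_CONVECTION(areas.body_volume), constants, air_config,
        ),
    )


def water_savings(delta_q: float, latent_heat: float = 2418.0) -> float:
    """Water-evaporation equivalent of a heat-loss difference, mg/h.

    A sustained dry heat loss of ``delta_q`` watts spares the water that
    evaporating at latent heat ``latent_heat`` (J/g) would have consumed:
    delta_q * 3600 / L * 1000 mg per hour.
    """
    if not latent_heat > 0:
        raise ValueError(f"latent_heat must be positive, got {latent_heat}")
    return delta_q * 3600.0 / latent_heat * 1000.0


def budget_table(
    observations: pd.DataFrame,
    birds: pd.DataFrame,
    constants: PhysicalConstants | None = None,
    air_config: AirPropertyConfig | None = None,
) -> pd.DataFrame:
    """Per-observation heat budgets for a whole experiment.

    ``observations`` carries one row per analysed frame (columns ``bird_id``,
    ``ta``, ``t_bill``, ``t_legs``, ``t_body`` at minimum); ``birds`` carries
    per-bird areas and the characteristic dimensions (``bill_total_area``,
    ``legs_area``, ``body_area``, ``body_volume``, ``bill_depth_base``,
    ``tarsus_length``).  Returns the observations augmented with q_* columns
    in watts plus ``percent_q_bill``.
    """
    bird_info = birds.set_index("bird_id")
    rows = []
    for rec in observations.itertuples(index=False):
        b = bird_info.loc[rec.bird_id]
        areas = RegionAreas(
            bill_cone_area=float(b["bill_cone_area"]),
            bill_total_area=float(b["bill_total_area"]),
            legs_area=float(b["legs_area"]),
            body_area=float(b["body_area"]),
            body_volume=float(b["body_volume"]),
        )
        temps = RegionTemperatures(
            bill=rec.t_bill,
            bill_base=getattr(rec, "t_base", rec.t_bill),
            bill_cone=getattr(rec, "t_cone", rec.t_bill),
            legs=rec.t_legs,
            body=rec.t_body,
        )
        hb = full_budget(
            areas, temps, rec.ta,
            bill_depth_base_mm=float(b["bill_depth_base"]),
            tarsus_length_mm=float(b["tarsus_length"]),
            constants=constants, air_config=air_config,
        )
        rows.append(
            {
                "q_bill": hb.q_bill,
                "q_legs": hb.q_legs,
                "q_body": hb.q_body,
                "q_total": hb.q_total,
                "percent_q_bill": hb.percent_q_bill,
            }
        )
    return pd.concat([observations.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
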