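"""Temperature-dependent physical properties of dry air at 1 atm.

Thermal conductivity follows the power-law correlation
k(T) = 0.02624 (T/300 K)^0.8646 W m^-1 K^-1 (Kadoya-type fit to standard
dry-air tables).  Kinematic viscosity combines Sutherland's dynamic
viscosity, mu(T) = 1.458e-6 T^1.5 / (T + 110.4) Pa s, with ideal-gas
density at 101325 Pa.  Both agree with published property tables to well
within 2% over 0-50 degC (see the shipped reference table
``data/dry_air_properties.csv``).

Humidity and pressure dependence are ignored: over the 15-37 degC chamber
protocol their effect on k and nu is below the accuracy of the convection
correlations themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "AirState",
    "AirPropertyConfig",
    "thermal_conductivity",
    "kinematic_viscosity",
    "film_temperature",
    "air_state",
]

_T_MIN_C = -20.0
_T_MAX_C = 60.0
_KELVIN = 273.15

# Sutherland constants for dry air
_SUTHERLAND_C1 = 1.458e-6  # kg m^-1 s^-1 K^-0.5
_SUTHERLAND_S = 110.4  # K
_R_SPECIFIC = 287.05  # J kg^-1 K^-1
_P_ATM = 101325.0  # Pa


def _check_range(T: float, allow_extrapolation: bool) -> None:
    if not allow_extrapolation and not (_T_MIN_C <= T <= _T_MAX_C):
        raise ValueError(
            f"air temperature {T} degC outside the validated range "
            f"[{_T_MIN_C}, {_T_MAX_C}] degC; pass allow_extrapolation=True to override"
        )


def thermal_conductivity(T: float, *, allow_extrapolation: bool = False) -> float:
    """Thermal conductivity of dry air (W m^-1 K^-1) at temperature T (degC)."""
    _check_range(T, allow_extrapolation)
    TK = T + _KELVIN
    return 0.02624 * (TK / 300.0) ** 0.8646


def kinematic_viscosity(T: float, *, allow_extrapolation: bool = False) -> float:
    """Kinematic viscosity of dry air (m^2/s) at temperature T (degC), 1 atm."""
    _check_range(T, allow_extrapolation)
    TK = T + _KELVIN
    mu = _SUTHERLAND_C1 * TK**1.5 / (TK + _SUTHERLAND_S)
    rho = _P_ATM / (_R_SPECIFIC * TK)
    return mu / rho


def film_temperature(Ts: float, Ta: float) -> float:
    """Arithmetic mean of surface and ambient temperature (degC)."""
    return (Ts + Ta) / 2.0


@dataclass(frozen=True)
class AirState:
    """Air properties evaluated at one temperature."""

    temperature: float
    thermal_conductivity: float
    kinematic_viscosity: float


@dataclass(frozen=True)
class AirPropertyConfig:
    """Where to evaluate k and nu in the convection chain.

    The chamber measurements pin nu to the ambient temperature; the
    evaluation point for k is not similarly pinned, so it defaults to the
    film temperature (Ts+Ta)/2 — the standard choice for boundary-layer
    properties — and can be switched to ambient for sensitivity checks.
    """

    conductivity_at: Literal["film", "ambient"] = "film"
    viscosity_at: Literal["film", "ambient"] = "ambient"

    def conductivity(self, Ts: float, Ta: float) -> float:
        T = film_temperature(Ts, Ta) if self.conductivity_at == "film" else Ta
        return thermal_conductivity(T)

    def viscosity(self, Ts: float, Ta: float) -> float:
        T = film_temperature(Ts, Ta) if self.viscosity_at == "film" else Ta
        return kinematic_viscosity(T)


def air_state(T: float) -> AirState:
    """Bundle k and nu at one temperature."""
    return AirState(T, thermal_conductivity(T), kinematic_viscosity(T))
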