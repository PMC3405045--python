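"""Seeded synthetic cohorts and step-wise thermography experiments.

Emulates the chamber protocol — 18 male song sparrows (9 Atlantic
*M. m. atlantica*, 9 eastern *M. m. melodia*), 2 degC ambient steps from 15
to 37 degC, 15 min per step with five analysed frames from the final five
minutes — together with the statistical structure of the measured
responses:

* whole-bill surface temperature runs 9.8 degC above ambient at 15 degC,
  declining close to linearly to 4.7 degC above ambient at 37 degC, with a
  small (weakly supported) Atlantic elevation;
* bill-base temperature is higher still and carries a subspecies x ambient
  interaction: Atlantic bases are hotter particularly at low ambient;
* body surface runs 4.4 -> 2.6 degC above ambient with no subspecies term;
* tarsus temperature rises non-linearly, modelled as a logistic
  vasodilation threshold near 29 degC;
* activity (hops/min) is quadratic in ambient temperature, identical in
  both subspecies; relative humidity declines linearly with ambient.

Every bird carries an individual random intercept per response and each
frame adds independent Gaussian noise.  All randomness flows from one seed.

Morphometric cohorts are drawn from per-subspecies truncated normals
(+-3 SD) at the means/SDs of the chamber birds; linear bill and tarsus
dimensions are back-derived from the sampled areas by uniformly scaling a
nominal shape, so the derived areas reproduce the draws exactly and the
base >= nares invariant holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphometrics import (
    LinearMeasurements,
    PhysicalConstants,
    RegionAreas,
    derive_region_areas,
)

__all__ = [
    "SubspeciesMorphometrics",
    "CohortConfig",
    "ProtocolConfig",
    "ResponseModelConfig",
    "SyntheticBird",
    "generate_cohort",
    "generate_experiment",
    "cohort_table",
    "roi_mean_temperature",
    "select_frames",
    "EASTERN_MORPHOMETRICS",
    "ATLANTIC_MORPHOMETRICS",
]


@dataclass(frozen=True)
class SubspeciesMorphometrics:
    """Means and SDs of the sampled morphometrics for one subspecies.

    Areas in mm^2, lengths in mm, mass in g.  Bill depth at the base is not
    part of the published comparison table; its default is a stated
    assumption (a song sparrow bill is ~6 mm deep at the base) and only
    matters as the convective characteristic dimension.
    """

    wing_chord: tuple[float, float]
    mass: tuple[float, float]
    tarsus_length: tuple[float, float]
    bill_cone_area: tuple[float, float]
    bill_total_area: tuple[float, float]
    legs_area: tuple[float, float]
    bill_depth_base: tuple[float, float] = (6.0, 0.3)


EASTERN_MORPHOMETRICS = SubspeciesMorphometrics(
    wing_chord=(65.89, 1.19),
    mass=(18.89, 1.27),
    tarsus_length=(20.01, 0.74),
    bill_cone_area=(88.19, 4.21),
    bill_total_area=(127.46, 10.41),
    legs_area=(240.07, 20.87),
)

ATLANTIC_MORPHOMETRICS = SubspeciesMorphometrics(
    wing_chord=(63.92, 1.44),
    mass=(19.97, 1.05),
    tarsus_length=(19.85, 0.89),
    bill_cone_area=(99.89, 19.81),
    bill_total_area=(148.70, 12.12),
    legs_area=(241.94, 20.61),
)

# Nominal bill/tarsus shapes used to back out linear dimensions from areas.
# (width, depth, length) in mm; only their ratios matter.
_BILL_BASE_SHAPE = (5.5, 6.0, 14.1)
_BILL_NARES_SHAPE = (4.0, 4.8, 12.75)
_TARSUS_SECTION_SHAPE = (2.0, 1.8)  # (width, depth)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and morphometric distributions."""

    n_per_subspecies: int = 9
    eastern: SubspeciesMorphometrics = EASTERN_MORPHOMETRICS
    atlantic: SubspeciesMorphometrics = ATLANTIC_MORPHOMETRICS
    truncation_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_subspecies < 2:
            raise ValueError("n_per_subspecies must be at least 2")
        for ssp in (self.eastern, self.atlantic):
            for name, (_, sd) in ssp.__dict__.items():
                if sd < 0:
                    raise ValueError(f"{name} SD must be non-negative, got {sd}")


@dataclass(frozen=True)
class ProtocolConfig:
    """Ambient-temperature step protocol of the chamber experiment."""

    ta_start: float = 15.0
    ta_end: float = 37.0
    ta_step: float = 2.0
    frames_per_step: int = 5
    step_duration_min: float = 15.0

    def __post_init__(self) -> None:
        if not self.ta_end > self.ta_start:
            raise ValueError("ta_end must exceed ta_start")
        n = (self.ta_end - self.ta_start) / self.ta_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("ta_step must divide the ambient range evenly")
        if self.frames_per_step < 1:
            raise ValueError("frames_per_step must be >= 1")

    @property
    def ta_levels(self) -> np.ndarray:
        return np.arange(
            self.ta_start, self.ta_end + self.ta_step / 2.0, self.ta_step
        )


@dataclass(frozen=True)
class ResponseModelConfig:
    """Generating model for the surface-temperature and covariate responses.

    Elevation endpoints are degC above ambient at (ta_start, ta_end) and
    interpolate linearly in between.  The bill-base interaction pair
    ``(level, slope)`` adds ``level + slope*(Ta - ta_start)`` degC for
    Atlantic birds; the default declines from +1.5 degC at 15 degC to 0 at
    37 degC.  Variance components (individual intercept SD, frame noise SD)
    are stated assumptions, not published values.
    """

    bill_elevation_endpoints: tuple[float, float] = (9.8, 4.7)
    bill_subspecies_offset: float = 0.3
    base_elevation_endpoints: tuple[float, float] = (10.5, 5.0)
    base_interaction: tuple[float, float] = (1.5, -1.5 / 22.0)
    body_elevation_endpoints: tuple[float, float] = (4.4, 2.6)
    legs_threshold_c: float = 29.0
    legs_elevation_pre: float = 1.0
    legs_elevation_post: float = 5.0
    legs_threshold_width_c: float = 2.0
    random_intercept_sd: float = 0.5
    frame_noise_sd: float = 0.4
    activity_vertex: tuple[float, float] = (26.0, 5.0)  # (Ta at minimum, hops/min)
    activity_curvature: float = 0.165  # hops/min per degC^2
    activity_noise_sd: float = 2.0
    humidity_at_start: float = 70.0
    humidity_slope: float = -40.0 / 22.0  # % per degC
    humidity_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("random_intercept_sd", "frame_noise_sd",
                     "activity_noise_sd", "humidity_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("bill_elevation_endpoints", "body_elevation_endpoints"):
            if min(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SyntheticBird:
    """One simulated bird: identity, measurements, and derived areas."""

    bird_id: str
    subspecies: str
    measurements: LinearMeasurements
    areas: RegionAreas


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n_sd: float) -> float:
    if sd == 0:
        return mean
    return float(
        stats.truncnorm.rvs(-n_sd, n_sd, loc=mean, scale=sd, random_state=rng)
    )


def _bill_dims_from_area(area: float, shape: tuple[float, float, float]):
    """Scale the nominal (W, D, L) shape so the cone formula returns ``area``."""
    w0, d0, l0 = shape
    area0 = (w0 + d0) / 4.0 * l0 * np.pi
    s = float(np.sqrt(area / area0))
    return w0 * s, d0 * s, l0 * s


def _tarsus_section_from_area(area: float, length: float):
    """Scale the nominal tarsus cross-section so both tarsi give ``area``."""
    w0, d0 = _TARSUS_SECTION_SHAPE
    rad0 = 2.0 * ((w0 / 2) ** 2 + (d0 / 2) ** 2) - 0.5 * (w0 - d0) ** 2
    target = area / (2.0 * np.pi * length)  # = sqrt(radicand)
    s = float(target / np.sqrt(rad0))
    return w0 * s, d0 * s


def generate_cohort(
    config: CohortConfig | None = None,
    constants: PhysicalConstants | None = None,
) -> list[SyntheticBird]:
    """Draw a seeded cohort of birds with consistent measurements and areas."""
    config = config or CohortConfig()
    constants = constants or PhysicalConstants()
    rng = np.random.default_rng(config.seed)
    birds: list[SyntheticBird] = []
    for subspecies, morph in (
        ("melodia", config.eastern),
        ("atlantica", config.atlantic),
    ):
        for i in range(config.n_per_subspecies):
            t = config.truncation_sd
            mass = _truncnorm(rng, *morph.mass, t)
            wing = _truncnorm(rng, *morph.wing_chord, t)
            tarsus_l = _truncnorm(rng, *morph.tarsus_length, t)
            a_total = _truncnorm(rng, *morph.bill_total_area, t)
            a_cone = _truncnorm(rng, *morph.bill_cone_area, t)
            a_legs = _truncnorm(rng, *morph.legs_area, t)

            wb, db, lb = _bill_dims_from_area(a_total, _BILL_BASE_SHAPE)
            wn, dn, ln_ = _bill_dims_from_area(a_cone, _BILL_NARES_SHAPE)
            # keep every nares dimension within the base dimensions
            s_cap = min(wb / wn, db / dn, lb / ln_)
            if s_cap < 1.0:
                wn, dn, ln_ = min(wn * s_cap, wb), min(dn * s_cap, db), min(ln_ * s_cap, lb)
            # pin base depth to its own (weakly varying) distribution by
            # rescaling width/length to preserve the sampled area
            depth_target = max(_truncnorm(rng, *morph.bill_depth_base, t), dn)
            width_adj = 4.0 * a_total / (np.pi * lb) - depth_target
            if width_adj >= wn:
                wb, db = width_adj, depth_target

            tw, td = _tarsus_section_from_area(a_legs, tarsus_l)
            m = LinearMeasurements(
                bill_length_nares=ln_,
                bill_width_nares=wn,
                bill_depth_nares=dn,
                bill_length_base=lb,
                bill_width_base=wb,
                bill_depth_base=db,
                tarsus_length=tarsus_l,
                tarsus_width=tw,
                tarsus_depth=td,
                wing_chord=wing,
                mass=mass,
            )
            birds.append(
                SyntheticBird(
                    bird_id=f"{subspecies[:3]}_{i + 1:02d}",
                    subspecies=subspecies,
                    measurements=m,
                    areas=derive_region_areas(m, constants),
                )
            )
    return birds


def cohort_table(birds: list[SyntheticBird]) -> pd.DataFrame:
    """Flatten a cohort to the per-bird morphometrics table."""
    rows = []
    for b in birds:
        row = {"bird_id": b.bird_id, "subspecies": b.subspecies}
        row.update(b.measurements.__dict__)
        row.update(
            {
                "bill_cone_area": b.areas.bill_cone_area,
                "bill_total_area": b.areas.bill_total_area,
                "legs_area": b.areas.legs_area,
                "body_area": b.areas.body_area,
                "body_volume": b.areas.body_volume,
                "total_area": b.areas.total_area,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _interp(ta, start, end, endpoints):
    lo, hi = endpoints
    return lo + (hi - lo) * (ta - start) / (end - start)


def generate_experiment(
    birds: list[SyntheticBird],
    protocol: ProtocolConfig | None = None,
    response: ResponseModelConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the step protocol for a cohort; one row per analysed frame.

    Columns: bird_id, subspecies, ta (nominal step temperature), frame_index,
    t_bill, t_base, t_cone, t_legs, t_body (degC), activity (hops/min),
    rh (percent relative humidity).
    """
    protocol = protocol or ProtocolConfig()
    response = response or ResponseModelConfig()
    rng = np.random.default_rng(seed)
    start, end = protocol.ta_start, protocol.ta_end
    levels = protocol.ta_levels

    rows = []
    for b in birds:
        is_atlantic = b.subspecies == "atlantica"
        # independent per-response individual intercepts
        u = {
            resp: rng.normal(0.0, response.random_intercept_sd)
            for resp in ("bill", "base", "body", "legs")
        }
        for ta in levels:
            bill_elev = _interp(ta, start, end, response.bill_elevation_endpoints)
            base_elev = _interp(ta, start, end, response.base_elevation_endpoints)
            body_elev = _interp(ta, start, end, response.body_elevation_endpoints)
            if is_atlantic:
                bill_elev += response.bill_subspecies_offset
                level, slope = response.base_interaction
                base_elev += level + slope * (ta - start)
            legs_elev = response.legs_elevation_pre + (
                response.legs_elevation_post - response.legs_elevation_pre
            ) / (1.0 + np.exp(-(ta - response.legs_threshold_c) / response.legs_threshold_width_c))
            cone_elev = 2.0 * bill_elev - base_elev

            ta_v, act_min = response.activity_vertex
            activity_mean = act_min + response.activity_curvature * (ta - ta_v) ** 2
            rh_mean = response.humidity_at_start + response.humidity_slope * (ta - start)

            for frame in range(1, protocol.frames_per_step + 1):
                eps = rng.normal(0.0, response.frame_noise_sd, size=4)
                t_bill = ta + bill_elev + u["bill"] + eps[0]
                t_base = ta + base_elev + u["base"] + eps[1]
                t_body = ta + body_elev + u["body"] + eps[2]
                t_legs = ta + legs_elev + u["legs"] + eps[3]
                activity = max(
                    0.0, activity_mean + rng.normal(0.0, response.activity_noise_sd)
                )
                rh = float(
                    np.clip(rh_mean + rng.normal(0.0, response.humidity_noise_sd), 2.0, 100.0)
                )
                rows.append(
                    {
                        "bird_id": b.bird_id,
                        "subspecies": b.subspecies,
                        "ta": float(ta),
                        "frame_index": frame,
                        "t_bill": t_bill,
                        "t_base": t_base,
                        "t_cone": ta + cone_elev + u["bill"] + eps[0],
                        "t_legs": t_legs,
                        "t_body": t_body,
                        "activity": activity,
                        "rh": rh,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minimal thermography ROI plumbing


def roi_mean_temperature(grid: np.ndarray, mask: np.ndarray) -> float:
    """Mean of a radiometric temperature grid under a boolean region mask."""
    grid = np.asarray(grid, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if grid.shape != mask.shape:
        raise ValueError(f"grid shape {grid.shape} != mask shape {mask.shape}")
    if not mask.any():
        raise ValueError("ROI mask selects no pixels")
    return float(grid[mask].mean())


def select_frames(
    frame_times_min: np.ndarray,
    quality_flags: np.ndarray | None = None,
    n_minutes: int = 5,
) -> list[int | None]:
    """Pick one analysis frame per minute of a recording.

    The default frame is the last one within each minute; if it is flagged
    bad, the temporally closest good frame within that minute is used
    (earlier frame on a tie).  A minute with no good frame yields ``None``.
    """
    times = np.asarray(frame_times_min, dtype=float)
    good = (
        np.ones_like(times, dtype=bool)
        if quality_flags is None
        else np.asarray(quality_flags, dtype=bool)
    )
    if times.max() < n_minutes:
        raise ValueError(
            f"recording spans {times.max():.2f} min; need at least {n_minutes}"
        )
    chosen: list[int | None] = []
    for minute in range(1, n_minutes + 1):
        in_minute = np.flatnonzero((times > minute - 1) & (times <= minute))
        if in_minute.size == 0:
            chosen.append(None)
            continue
        target = in_minute[np.argmax(times[in_minute])]
        if good[target]:
            chosen.append(int(target))
            continue
        candidates = in_minute[good[in_minute]]
        if candidates.size == 0:
            chosen.append(None)
            continue
        dist = np.abs(times[candidates] - times[target])
        # stable argmin -> earlier frame wins ties
        chosen.append(int(candidates[np.argmin(dist)]))
    return chosen
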