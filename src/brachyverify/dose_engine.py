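"""TG-43U1 dose engine: source-strength decay and dose summation.

The dose rate at a point (r, theta) relative to one dwell is

    Ddot(r, theta) = S_k · Lambda · G_L(r, theta)/G_L(r0, theta0)
                     · g_L(r) · F(r, theta)           [cGy/h]

with S_k the air-kerma strength on the treatment day (U = cGy·cm²·h⁻¹)
and Lambda the dose-rate constant (cGy·h⁻¹·U⁻¹). The plan dose at a
verification point is the sum over dwells of rate × dwell time, with
dwell times held in seconds and converted to hours at the multiply.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np

from . import geometry as geo
from .errors import DateError, DomainError, NearSourceError, NumericError, PlanError
from .source_model import SourceSpec, anisotropy_with_flag, radial_dose

__all__ = [
    "DwellPosition",
    "KermaCalibration",
    "DwellContribution",
    "PlanDose",
    "decay_air_kerma_strength",
    "dwell_dose_rate",
    "plan_dose",
]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class DwellPosition:
    """One dwell of the stepping source: geometry plus dwell time (s)."""

    index: int
    geometry: geo.DwellGeometry
    dwell_time: float
    channel: str = "1"

    def __post_init__(self):
        if self.dwell_time < 0:
            raise PlanError(f"dwell {self.index}: dwell_time must be >= 0, "
                            f"got {self.dwell_time!r}")


@dataclass(frozen=True)
class KermaCalibration:
    """Calibrated air-kerma strength and the two midnight-anchored dates."""

    Sk_calibration: float
    calibration_date: _dt.date
    treatment_date: _dt.date

    def __post_init__(self):
        if not (self.Sk_calibration > 0):
            raise DomainError(
                f"Sk_calibration must be > 0 U, got {self.Sk_calibration!r}")
        if self.treatment_date < self.calibration_date:
            raise DateError(
                f"treatment date {self.treatment_date} precedes calibration "
                f"date {self.calibration_date}")


def decay_air_kerma_strength(cal: KermaCalibration, half_life: float) -> float:
    """Air-kerma strength on the treatment day (U).

    Both dates are taken at midnight, so the elapsed time is a whole-day
    count and Sk(t) = Sk_cal · 2^(−Δt/half_life). Sub-day decay is below
    the resolution of the acceptance band for Ir-192.
    """
    if not (half_life > 0):
        raise DomainError(f"half_life must be > 0 days, got {half_life!r}")
    delta_days = (cal.treatment_date - cal.calibration_date).days
    return cal.Sk_calibration * 2.0 ** (-delta_days / half_life)


@dataclass(frozen=True)
class DwellContribution:
    """Per-dwell bookkeeping returned with a plan dose."""

    index: int
    channel: str
    dose_rate_cgy_per_h: float
    dwell_time_s: float
    dose_cgy: float
    r_cm: float
    theta_deg: float
    theta_clamped: bool


@dataclass(frozen=True)
class PlanDose:
    """Total dose (cGy) with per-dwell contributions and range flags."""

    dose_cgy: float
    contributions: tuple[DwellContribution, ...]
    any_below_r_min: bool = False
    any_above_r_max: bool = False
    any_theta_clamped: bool = False


def dwell_dose_rate(spec: SourceSpec, Sk: float, geom: geo.DwellGeometry,
                    point, *, capsule_radius: float = geo.DEFAULT_CAPSULE_RADIUS_CM,
                    _detail: list | None = None) -> float:
    """Dose rate (cGy/h) at ``point`` from a single dwell.

    Raises :class:`NearSourceError` when the point is inside the guard
    capsule around the active segment, where the line-source formalism
    has no meaningful value.
    """
    if not (Sk > 0):
        raise DomainError(f"air-kerma strength must be > 0 U, got {Sk!r}")
    L = spec.active_length_L
    dist = geo.perpendicular_distance_to_segment(geom, point, L)
    if dist < capsule_radius:
        raise NearSourceError(
            f"point at {dist:.4f} cm from the active segment is inside the "
            f"{capsule_radius:.3f} cm guard capsule", distance_cm=dist)
    coords = geo.polar_coords(geom, point, L)
    g_ratio = geo.geometry_function(coords, L) / geo.reference_geometry_value(L)
    g_r = radial_dose(spec, coords.r)
    f_val, clamped = anisotropy_with_flag(spec, coords.r, coords.theta)
    rate = Sk * spec.dose_rate_constant_Lambda * g_ratio * g_r * f_val
    if not math.isfinite(rate):
        raise NumericError(
            f"non-finite dose rate at r={coords.r!r} cm, theta={coords.theta!r} deg")
    if _detail is not None:
        _detail.append((coords, clamped))
    return rate


def plan_dose(spec: SourceSpec, Sk: float, dwells, point, *,
              capsule_radius: float = geo.DEFAULT_CAPSULE_RADIUS_CM) -> PlanDose:
    """Total dose (cGy) at ``point`` summed over all dwells of a plan.

    A near-source condition at any dwell aborts the sum with a
    :class:`NearSourceError` naming the offending dwell index; the
    verification layer converts that into a failed-with-diagnosis result.
    """
    dwells = list(dwells)
    if not dwells:
        raise PlanError("plan has no dwell positions")
    contributions = []
    below = above = clamped_any = False
    total = 0.0
    for dwell in dwells:
        detail: list = []
        try:
            rate = dwell_dose_rate(spec, Sk, dwell.geometry, point,
                                   capsule_radius=capsule_radius, _detail=detail)
        except NearSourceError as err:
            raise NearSourceError(
                f"dwell {dwell.index}: {err}", dwell_index=dwell.index,
                distance_cm=err.distance_cm) from err
        coords, clamped = detail[0]
        dose = rate * dwell.dwell_time / SECONDS_PER_HOUR
        total += dose
        below = below or coords.r < spec.r_min
        above = above or coords.r > spec.r_max
        clamped_any = clamped_any or clamped
        contributions.append(DwellContribution(
            index=dwell.index, channel=dwell.channel,
            dose_rate_cgy_per_h=rate, dwell_time_s=dwell.dwell_time,
            dose_cgy=dose, r_cm=coords.r, theta_deg=coords.theta,
            theta_clamped=clamped))
    return PlanDose(dose_cgy=total, contributions=tuple(contributions),
                    any_below_r_min=below, any_above_r_max=above,
                    any_theta_clamped=clamped_any)
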