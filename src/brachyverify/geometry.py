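"""Line-source geometry: dwell extraction, polar coordinates, G_L.

All lengths here are centimetres; unit conversion from millimetre plan
files happens at the I/O boundary, never in this module.

The geometry function of a line source of active length L is

    G_L(r, theta) = beta / (L r sin theta)        off the long axis,
    G_L(r, 0)     = (r^2 - L^2/4)^(-1)            on the long axis,

where beta is the angle subtended at the evaluation point by the two
tips of the hypothetical line source. The on-axis closed form is applied
at both poles (theta = 0 and theta = 180), by symmetry of the segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError, NearSourceError

__all__ = [
    "DwellGeometry",
    "PolarCoordinates",
    "dwell_from_transform",
    "source_tips",
    "polar_coords",
    "geometry_function",
    "R0_CM",
    "THETA0_DEG",
    "SIN_COLLINEAR_TOL",
    "DEFAULT_CAPSULE_RADIUS_CM",
]

#: TG-43 reference point: 1 cm on the transverse axis.
R0_CM = 1.0
THETA0_DEG = 90.0

#: sin(theta) below this is treated as collinear with the source axis.
SIN_COLLINEAR_TOL = 1e-6

#: Default radius of the near-source guard capsule around the active
#: segment (cm); points closer than this are not evaluable.
DEFAULT_CAPSULE_RADIUS_CM = 0.05


@dataclass(frozen=True)
class DwellGeometry:
    """Center position (cm) and unit orientation of one dwell."""

    center: np.ndarray
    orientation: np.ndarray

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float).reshape(3)
        orientation = np.asarray(self.orientation, dtype=float).reshape(3)
        if not np.all(np.isfinite(center)) or not np.all(np.isfinite(orientation)):
            raise GeometryError("dwell geometry contains non-finite coordinates")
        norm = float(np.linalg.norm(orientation))
        if abs(norm - 1.0) > 1e-9:
            raise GeometryError(f"orientation must be unit norm, |v| = {norm!r}")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "orientation", orientation)


@dataclass(frozen=True)
class PolarCoordinates:
    """(r, theta, beta) of a point relative to a line source.

    ``r`` in cm, ``theta`` in degrees within [0, 180], ``beta`` in
    radians (the tip-subtended angle), beta >= 0.
    """

    r: float
    theta: float
    beta: float


def dwell_from_transform(matrix, *, scale: float = 1.0) -> DwellGeometry:
    """Build a dwell from a 4x4 transform matrix.

    The third column carries the source orientation (normalized here)
    and the fourth column the center position, multiplied by ``scale``
    (e.g. 0.1 to convert a millimetre matrix to cm).
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4) or not np.all(np.isfinite(m)):
        raise GeometryError(f"expected a finite 4x4 transform matrix, got shape {m.shape}")
    axis = m[:3, 2]
    norm = float(np.linalg.norm(axis))
    if norm == 0.0:
        raise GeometryError("transform matrix third column (orientation) has zero norm")
    return DwellGeometry(center=m[:3, 3] * scale, orientation=axis / norm)


def source_tips(geom: DwellGeometry, L: float) -> tuple[np.ndarray, np.ndarray]:
    """Tip positions center ± (L/2)·orientation of the active segment."""
    if not (L > 0):
        raise DomainError(f"active length must be > 0, got {L!r}")
    half = 0.5 * L * geom.orientation
    return geom.center + half, geom.center - half


def polar_coords(geom: DwellGeometry, point, L: float) -> PolarCoordinates:
    """Polar coordinates (r, theta, beta) of ``point`` about a dwell.

    theta is the angle between the source orientation and the vector
    from the center to the point. beta is computed as the absolute
    difference of the two tip angles taken with a two-argument
    arctangent in the axial plane (z along the source axis, rho the
    perpendicular distance), which is quadrant-safe near the poles.
    """
    if not (L > 0):
        raise DomainError(f"active length must be > 0, got {L!r}")
    p = np.asarray(point, dtype=float).reshape(3)
    d = p - geom.center
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise NearSourceError("evaluation point coincides with the dwell center",
                              distance_cm=0.0)
    # axial/perpendicular decomposition relative to the source axis
    z = float(np.dot(d, geom.orientation))
    rho = float(np.linalg.norm(d - z * geom.orientation))
    theta = math.degrees(math.atan2(rho, z))  # in [0, 180]
    half = 0.5 * L
    beta = abs(math.atan2(rho, z - half) - math.atan2(rho, z + half))
    return PolarCoordinates(r=r, theta=theta, beta=beta)


def geometry_function(coords: PolarCoordinates, L: float) -> float:
    """Line-source geometry function G_L(r, theta) in cm^-2.

    The reference normalization G_L(r0, theta0) of the dose equation is
    obtained from this same function at r = 1 cm, theta = 90°.
    """
    if not (L > 0):
        raise DomainError(f"active length must be > 0, got {L!r}")
    sin_theta = math.sin(math.radians(coords.theta))
    if sin_theta < SIN_COLLINEAR_TOL:
        # On the long axis (theta ~ 0 or ~ 180): closed form, valid only
        # outside the active segment.
        if coords.r <= 0.5 * L:
            raise NearSourceError(
                f"collinear point at r={coords.r:.4f} cm lies inside the "
                f"active segment (L/2 = {0.5 * L:.4f} cm)",
                distance_cm=coords.r)
        return 1.0 / (coords.r * coords.r - L * L / 4.0)
    value = coords.beta / (L * coords.r * sin_theta)
    if not math.isfinite(value) or value <= 0.0:
        raise NearSourceError(
            f"geometry function not evaluable at r={coords.r!r} cm, "
            f"theta={coords.theta!r} deg", distance_cm=coords.r)
    return value


def reference_geometry_value(L: float) -> float:
    """G_L(r0=1 cm, theta0=90°) for a source of active length L."""
    beta0 = 2.0 * math.atan(0.5 * L / R0_CM)
    return beta0 / (L * R0_CM)


def perpendicular_distance_to_segment(geom: DwellGeometry, point, L: float) -> float:
    """Shortest distance (cm) from ``point`` to the active segment."""
    p = np.asarray(point, dtype=float).reshape(3)
    d = p - geom.center
    z = float(np.clip(np.dot(d, geom.orientation), -0.5 * L, 0.5 * L))
    closest = geom.center + z * geom.orientation
    return float(np.linalg.norm(p - closest))
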