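"""Probe geometry and the polar/Cartesian coordinate conventions.

All positions are expressed relative to the centre of curvature of a convex
(curvilinear) ultrasound probe.  Scan lines fan out radially from this
origin, so the natural tracking coordinates are polar: range ``r`` along a
scan line and angle ``theta`` measured from the vertical (axial) axis,
positive towards positive lateral ``x``.  The Cartesian frame has ``x``
lateral and ``y`` axial, with ``y`` positive pointing away from the probe
face into the medium, so that depth, range and image row index all increase
together.

Angles are degrees at every public interface; lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbeGeometry",
    "PolarPoint",
    "CartesianPoint",
    "InvalidGeometryError",
    "UndefinedAngleError",
    "scan_line_angles",
    "polar_to_cartesian",
    "cartesian_to_polar",
]


class InvalidGeometryError(ValueError):
    """Raised when probe parameters violate their physical constraints."""


class UndefinedAngleError(ValueError):
    """Raised when an angle is requested for the coordinate origin."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Curvilinear probe and imaging-system parameters.

    Parameters
    ----------
    radius_of_curvature_mm:
        Distance from the centre of curvature to the probe face (mm).
        The default of 68 mm is a configurable surrogate for the
        (proprietary) clinical probe; it is chosen so that the canonical
        5 mm accuracy grid spanning depths 40-140 mm below the probe face
        contains exactly 356 in-fan positions.
    field_of_view_deg:
        Full angular extent of the scan-line fan (degrees).
    n_scan_lines:
        Number of transmit scan lines per B-mode frame.
    sound_speed_mps:
        Sound speed assumed by the imaging system (m/s).
    imaging_depth_mm:
        Maximum imaging depth below the probe face (mm).
    """

    radius_of_curvature_mm: float = 68.0
    field_of_view_deg: float = 55.0
    n_scan_lines: int = 128
    sound_speed_mps: float = 1540.0
    imaging_depth_mm: float = 300.0

    def __post_init__(self) -> None:
        if self.radius_of_curvature_mm <= 0:
            raise InvalidGeometryError("radius of curvature must be positive")
        if not (0.0 < self.field_of_view_deg < 180.0):
            raise InvalidGeometryError("field of view must lie in (0, 180) degrees")
        if self.n_scan_lines < 2:
            raise InvalidGeometryError("at least two scan lines are required")
        if self.sound_speed_mps <= 0:
            raise InvalidGeometryError("sound speed must be positive")
        if self.imaging_depth_mm <= 0:
            raise InvalidGeometryError("imaging depth must be positive")

    @property
    def max_range_mm(self) -> float:
        """Largest in-fan range from the centre of curvature (mm)."""
        return self.radius_of_curvature_mm + self.imaging_depth_mm

    def contains_polar(self, r_mm: float, theta_deg: float, *, angle_tol_deg: float = 0.0) -> bool:
        """True if (r, theta) lies within the imaging fan."""
        half = self.field_of_view_deg / 2.0 + angle_tol_deg
        return (0.0 <= r_mm <= self.max_range_mm) and (abs(theta_deg) <= half)


@dataclass(frozen=True)
class PolarPoint:
    """Point in probe polar coordinates: range (mm), angle from vertical (deg)."""

    r_mm: float
    theta_deg: float

    def __post_init__(self) -> None:
        if self.r_mm < 0:
            raise ValueError("range must be non-negative")


@dataclass(frozen=True)
class CartesianPoint:
    """Point in probe Cartesian coordinates: lateral x, axial y (mm, depth-positive)."""

    x_mm: float
    y_mm: float


def scan_line_angles(geometry: ProbeGeometry) -> np.ndarray:
    """Scan-line angles (deg), evenly spaced, spanning the field of view.

    The first line sits at -FOV/2, the last at +FOV/2 and the fan is
    symmetric about the vertical axis.  The true spacing of the clinical
    system is proprietary; an inclusive uniform fan is used throughout.
    """
    half = geometry.field_of_view_deg / 2.0
    return np.linspace(-half, half, geometry.n_scan_lines)


def polar_to_cartesian(p: PolarPoint) -> CartesianPoint:
    """Map (r, theta) to (x, y) with x = r sin(theta), y = r cos(theta)."""
    th = np.deg2rad(p.theta_deg)
    return CartesianPoint(x_mm=p.r_mm * np.sin(th), y_mm=p.r_mm * np.cos(th))


def cartesian_to_polar(p: CartesianPoint) -> PolarPoint:
    """Map (x, y) to (r, theta) with r = hypot(x, y), theta = sign(x) acos(y/r)."""
    r = float(np.hypot(p.x_mm, p.y_mm))
    if r == 0.0:
        raise UndefinedAngleError("angle undefined at the centre of curvature")
    theta = np.degrees(np.arccos(np.clip(p.y_mm / r, -1.0, 1.0)))
    if p.x_mm < 0:
        theta = -theta
    return PolarPoint(r_mm=r, theta_deg=float(theta))
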