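"""Polar-to-Cartesian scan conversion with uncertainty propagation.

A polar estimate (r, theta) with uncertainties (sigma_r, sigma_theta) is
mapped to image Cartesian coordinates.  The uncertainty is first expressed
as a diagonal covariance in local axes aligned with the scan line —
variance ``sigma_r^2`` along the radial direction and ``(r tan
sigma_theta)^2`` along the tangential direction — and then rotated into the
(x, y) frame.  With theta measured from the vertical axis and x = r sin
theta, y = r cos theta, the rotation angle is ``phi = theta - 90 deg``, so
that on the probe axis (theta = 0) the radial uncertainty maps entirely to
the axial axis.

The module also calibrates B-mode images (pixel size and apex position)
from the fan-shaped sector of a single frame, and maps estimates to pixel
coordinates for overlay rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import PolarPoint, polar_to_cartesian
from .localise import PolarEstimate

__all__ = [
    "CartesianEstimate",
    "ImageCalibration",
    "CalibrationError",
    "polar_covariance",
    "rotate_covariance",
    "to_cartesian",
    "calibrate_image",
    "to_pixel",
    "render_fan_mask",
    "draw_crosshair",
]


class CalibrationError(ValueError):
    """Raised when no usable fan sector is found in a B-mode image."""


@dataclass(frozen=True)
class CartesianEstimate:
    """Tracked tip position in Cartesian image coordinates with covariance."""

    x_mm: float
    y_mm: float
    cov_mm2: np.ndarray
    valid: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "cov_mm2", np.asarray(self.cov_mm2, dtype=float))

    @property
    def sigma_x_mm(self) -> float:
        return math.sqrt(max(self.cov_mm2[0, 0], 0.0))

    @property
    def sigma_y_mm(self) -> float:
        return math.sqrt(max(self.cov_mm2[1, 1], 0.0))

    @classmethod
    def invalid(cls) -> "CartesianEstimate":
        return cls(float("nan"), float("nan"), np.full((2, 2), float("nan")), valid=False)


@dataclass(frozen=True)
class ImageCalibration:
    """Isotropic pixel size and apex (centre-of-curvature) pixel of a B-mode image."""

    pixel_size_mm: float
    apex_row: float
    apex_col: float
    image_shape: tuple[int, int]
    edge_fit_rms_px: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")


def polar_covariance(sigma_r_mm: float, sigma_theta_deg: float, r_mm: float) -> np.ndarray:
    """Diagonal covariance in scan-line-aligned axes (radial, tangential).

    The tangential standard deviation is the arc subtended by the angular
    uncertainty at range r: ``r tan(sigma_theta)``.
    """
    if r_mm <= 0:
        raise ValueError("range must be positive")
    if not (0.0 <= sigma_theta_deg < 90.0):
        raise ValueError("angular uncertainty must lie in [0, 90) degrees")
    s_tan = r_mm * math.tan(math.radians(sigma_theta_deg))
    return np.diag([sigma_r_mm**2, s_tan**2])


def rotate_covariance(cov: np.ndarray, phi_deg: float) -> np.ndarray:
    """Rotate a 2x2 covariance matrix by ``phi_deg``: ``R K R^T``."""
    p = math.radians(phi_deg)
    rot = np.array([[math.cos(p), -math.sin(p)], [math.sin(p), math.cos(p)]])
    return rot @ np.asarray(cov, dtype=float) @ rot.T


def to_cartesian(est: PolarEstimate) -> CartesianEstimate:
    """Scan-convert a polar estimate, propagating its uncertainties."""
    if not est.valid:
        return CartesianEstimate.invalid()
    pt = polar_to_cartesian(PolarPoint(r_mm=est.r_mm, theta_deg=est.theta_deg))
    k_rs = polar_covariance(est.sigma_r_mm, est.sigma_theta_deg, est.r_mm)
    k_xy = rotate_covariance(k_rs, est.theta_deg - 90.0)
    return CartesianEstimate(x_mm=pt.x_mm, y_mm=pt.y_mm, cov_mm2=k_xy, valid=True)


# ---------------------------------------------------------------------------
# image calibration


def _tls_line(points_rc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through (row, col) points: (centroid, direction)."""
    centroid = points_rc.mean(axis=0)
    _, _, vt = np.linalg.svd(points_rc - centroid, full_matrices=False)
    return centroid, vt[0]


def _intersect(p0: np.ndarray, d0: np.ndarray, p1: np.ndarray, d1: np.ndarray) -> np.ndarray:
    a = np.column_stack([d0, -d1])
    t = np.linalg.solve(a, p1 - p0)
    return p0 + t[0] * d0


def calibrate_image(
    bmode: np.ndarray,
    imaging_depth_mm: float,
    *,
    intensity_fraction: float = 0.01,
    edge_rows_fraction: float = 0.6,
) -> ImageCalibration:
    """Recover pixel size and apex position from a fan-shaped B-mode sector.

    The sector is segmented by thresholding at ``intensity_fraction`` of
    the maximum intensity; total-least-squares lines are fitted to the left
    and right boundaries over the upper portion of the sector (where the
    boundaries are the straight fan edges), and their intersection gives
    the apex.  The pixel size follows from the difference between the outer
    and inner arc radii, which spans the imaging depth.
    """
    img = np.asarray(bmode, dtype=float)
    if img.ndim != 2:
        raise ValueError("a single-channel 2-D image is required")
    vmax = float(img.max())
    if vmax <= 0:
        raise CalibrationError("image is entirely black; no fan sector found")
    mask = img > intensity_fraction * vmax
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size < 10:
        raise CalibrationError("fan sector too small to calibrate")
    top, bottom = rows[0], rows[-1]
    straight_limit = top + int(edge_rows_fraction * (bottom - top))
    left_pts, right_pts = [], []
    for r in range(top, straight_limit + 1):
        cols = np.flatnonzero(mask[r])
        if cols.size == 0:
            continue
        left_pts.append((r, cols[0]))
        right_pts.append((r, cols[-1]))
    left_pts = np.asarray(left_pts, dtype=float)
    right_pts = np.asarray(right_pts, dtype=float)
    if len(left_pts) < 5:
        raise CalibrationError("too few fan edge points for a line fit")

    p_l, d_l = _tls_line(left_pts)
    p_r, d_r = _tls_line(right_pts)
    try:
        apex = _intersect(p_l, d_l, p_r, d_r)
    except np.linalg.LinAlgError as exc:
        raise CalibrationError("fan edges are parallel; no apex") from exc

    def _residual_rms(pts: np.ndarray, p0: np.ndarray, d: np.ndarray) -> float:
        rel = pts - p0
        perp = rel - np.outer(rel @ d, d)
        return float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))

    rms = max(_residual_rms(left_pts, p_l, d_l), _residual_rms(right_pts, p_r, d_r))

    rr, cc = np.nonzero(mask)
    dist = np.hypot(rr - apex[0], cc - apex[1])
    r_inner, r_outer = float(dist.min()), float(dist.max())
    if r_outer - r_inner < 1.0:
        raise CalibrationError("degenerate fan: inner and outer arcs coincide")
    pixel_size = imaging_depth_mm / (r_outer - r_inner)
    return ImageCalibration(
        pixel_size_mm=pixel_size,
        apex_row=float(apex[0]),
        apex_col=float(apex[1]),
        image_shape=img.shape,
        edge_fit_rms_px=rms,
    )


def to_pixel(
    est: CartesianEstimate, cal: ImageCalibration
) -> tuple[float, float, float, float]:
    """Map a Cartesian estimate to image pixels: (row, col, sigma_row, sigma_col)."""
    col = cal.apex_col + est.x_mm / cal.pixel_size_mm
    row = cal.apex_row + est.y_mm / cal.pixel_size_mm
    return row, col, est.sigma_y_mm / cal.pixel_size_mm, est.sigma_x_mm / cal.pixel_size_mm


def render_fan_mask(
    image_shape: tuple[int, int],
    apex_row: float,
    apex_col: float,
    pixel_size_mm: float,
    rho_mm: float,
    imaging_depth_mm: float,
    fov_deg: float,
    value: int = 200,
) -> np.ndarray:
    """Render a synthetic fan sector (8-bit grey) for calibration fixtures."""
    rows, cols = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    dr = rows - apex_row
    dc = cols - apex_col
    r_mm = np.hypot(dr, dc) * pixel_size_mm
    theta = np.degrees(np.arctan2(dc, dr))
    inside = (
        (r_mm >= rho_mm)
        & (r_mm <= rho_mm + imaging_depth_mm)
        & (np.abs(theta) <= fov_deg / 2.0)
    )
    return (inside * value).astype(np.uint8)


def draw_crosshair(
    image: np.ndarray,
    row: float,
    col: float,
    *,
    sigma_row_px: float = 0.0,
    sigma_col_px: float = 0.0,
    base_size_px: int = 6,
    value: int = 255,
):
    """Draw a cross-hair cursor at (row, col), arms scaled by the uncertainty.

    Returns a PIL image; the input array is not modified.
    """
    from PIL import Image, ImageDraw

    img = Image.fromarray(np.asarray(image, dtype=np.uint8))
    draw = ImageDraw.Draw(img)
    h = base_size_px + sigma_col_px
    v = base_size_px + sigma_row_px
    draw.line([(col - h, row), (col + h, row)], fill=value, width=1)
    draw.line([(col, row - v), (col, row + v)], fill=value, width=1)
    return img
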