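"""Accuracy, repeatability and SNR evaluation of tracked positions.

Implements the study-style metrics used throughout the package:

* **Tracking error** — the vector displacement between the mean of the
  repeated tracked positions at a location and the true position,
  reported componentwise (Cartesian or polar) with its Euclidean
  magnitude.
* **Repeatability** — the per-axis sample standard deviation (n-1
  denominator) of the repeated tracked positions; its magnitude is the
  norm of the per-axis standard deviations.
* **Spatial summaries** — mean, standard deviation and percentiles of the
  per-location magnitudes across the scanned area.

Also provided: per-elevation and per-angle sweep analyses, the
shaft-direction label-offset correction for manually annotated images, the
uncertainty-vs-repeatability correlation, and an optional constant-velocity
or constant-acceleration Kalman filter for smoothing tracked trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan_convert import CartesianEstimate

__all__ = [
    "LocationMetrics",
    "tracking_error",
    "error_magnitude",
    "repeatability",
    "repeat_average",
    "spatial_summary",
    "location_metrics",
    "grid_metrics",
    "elevation_analysis",
    "angle_analysis",
    "label_offset_correction",
    "uncertainty_correlation",
    "kalman_smooth",
]


@dataclass(frozen=True)
class LocationMetrics:
    """Error and repeatability at one true location."""

    error_xy_mm: tuple[float, float]
    error_polar: tuple[float, float]  # (mm, deg)
    repeatability_xy_mm: tuple[float, float]
    n_frames: int
    n_valid: int

    @property
    def error_magnitude_mm(self) -> float:
        return float(np.hypot(*self.error_xy_mm))

    @property
    def repeatability_magnitude_mm(self) -> float:
        return float(np.hypot(*self.repeatability_xy_mm))


def tracking_error(tracked: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Mean tracked position minus truth, componentwise.

    ``tracked`` is (n, d); ``truth`` is (d,).  Works identically for
    Cartesian (x, y) and polar (r, theta) coordinates.
    """
    tracked = np.asarray(tracked, dtype=float)
    if tracked.ndim != 2 or tracked.shape[0] < 1:
        raise ValueError("at least one tracked sample is required")
    return tracked.mean(axis=0) - np.asarray(truth, dtype=float)


def error_magnitude(error_vec: np.ndarray) -> float:
    """Euclidean norm of an error vector."""
    return float(np.linalg.norm(np.asarray(error_vec, dtype=float)))


def repeatability(tracked: np.ndarray) -> np.ndarray:
    """Per-axis sample standard deviation (ddof=1) of repeated positions."""
    tracked = np.asarray(tracked, dtype=float)
    if tracked.shape[0] < 2:
        return np.zeros(tracked.shape[1])
    return tracked.std(axis=0, ddof=1)


def repeat_average(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean over repeat measurements and its uncertainty std/sqrt(N)."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    mean = v.mean(axis=0)
    if n < 2:
        return mean, np.zeros_like(mean)
    return mean, v.std(axis=0, ddof=1) / math.sqrt(n)


def spatial_summary(magnitudes: np.ndarray, percentiles: tuple[float, ...] = (95.0,)) -> dict:
    """Mean, std and percentiles of per-location magnitudes across the area."""
    m = np.asarray(magnitudes, dtype=float)
    m = m[np.isfinite(m)]
    out = {
        "mean": float(m.mean()),
        "std": float(m.std(ddof=1)) if m.size > 1 else 0.0,
        "n": int(m.size),
    }
    for p in percentiles:
        out[f"p{p:g}"] = float(np.percentile(m, p))
    return out


def location_metrics(
    tracked_xy: np.ndarray,
    truth_xy: np.ndarray,
    tracked_polar: np.ndarray | None = None,
    truth_polar: np.ndarray | None = None,
    n_frames: int | None = None,
) -> LocationMetrics:
    """Per-location error and repeatability from valid tracked samples."""
    tracked_xy = np.asarray(tracked_xy, dtype=float)
    n_valid = tracked_xy.shape[0]
    e_xy = tracking_error(tracked_xy, truth_xy)
    if tracked_polar is not None and truth_polar is not None:
        e_pol = tracking_error(np.asarray(tracked_polar), truth_polar)
    else:
        e_pol = np.array([float("nan"), float("nan")])
    rep = repeatability(tracked_xy)
    return LocationMetrics(
        error_xy_mm=(float(e_xy[0]), float(e_xy[1])),
        error_polar=(float(e_pol[0]), float(e_pol[1])),
        repeatability_xy_mm=(float(rep[0]), float(rep[1])),
        n_frames=n_frames if n_frames is not None else n_valid,
        n_valid=n_valid,
    )


def grid_metrics(estimates: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-position metrics for a grid experiment.

    ``estimates`` must have columns position_id, frame, x_mm, y_mm, r_mm,
    theta_deg, valid; ``truth`` must have position_id, x_mm, y_mm.  Invalid
    frames are excluded (their count is reported via n_frames/n_valid).
    """
    from .geometry import CartesianPoint, cartesian_to_polar

    rows = []
    truth_idx = truth.set_index("position_id")
    for pid, grp in estimates.groupby("position_id"):
        t = truth_idx.loc[pid]
        valid = grp[grp["valid"].astype(bool)]
        n_frames = len(grp)
        if len(valid) == 0:
            rows.append(
                {
                    "position_id": pid,
                    "x_mm": t["x_mm"],
                    "y_mm": t["y_mm"],
                    "n_frames": n_frames,
                    "n_valid": 0,
                    "error_x_mm": np.nan,
                    "error_y_mm": np.nan,
                    "error_r_mm": np.nan,
                    "error_theta_deg": np.nan,
                    "error_mag_mm": np.nan,
                    "rep_x_mm": np.nan,
                    "rep_y_mm": np.nan,
                    "rep_mag_mm": np.nan,
                    "rep_r_mm": np.nan,
                    "rep_theta_deg": np.nan,
                    "rep_tangential_mm": np.nan,
                }
            )
            continue
        truth_pol = cartesian_to_polar(CartesianPoint(float(t["x_mm"]), float(t["y_mm"])))
        m = location_metrics(
            valid[["x_mm", "y_mm"]].to_numpy(),
            np.array([t["x_mm"], t["y_mm"]]),
            valid[["r_mm", "theta_deg"]].to_numpy(),
            np.array([truth_pol.r_mm, truth_pol.theta_deg]),
            n_frames=n_frames,
        )
        rep_pol = repeatability(valid[["r_mm", "theta_deg"]].to_numpy())
        rep_tang = float(np.deg2rad(rep_pol[1]) * valid["r_mm"].mean())
        rows.append(
            {
                "position_id": pid,
                "x_mm": t["x_mm"],
                "y_mm": t["y_mm"],
                "n_frames": m.n_frames,
                "n_valid": m.n_valid,
                "error_x_mm": m.error_xy_mm[0],
                "error_y_mm": m.error_xy_mm[1],
                "error_r_mm": m.error_polar[0],
                "error_theta_deg": m.error_polar[1],
                "error_mag_mm": m.error_magnitude_mm,
                "rep_x_mm": m.repeatability_xy_mm[0],
                "rep_y_mm": m.repeatability_xy_mm[1],
                "rep_mag_mm": m.repeatability_magnitude_mm,
                "rep_r_mm": float(rep_pol[0]),
                "rep_theta_deg": float(rep_pol[1]),
                "rep_tangential_mm": rep_tang,
            }
        )
    return pd.DataFrame(rows)


def elevation_analysis(estimates: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-elevation displacement, repeatability and SNR curves.

    ``truth`` must carry z_mm per position.  Displacements compare the mean
    tracked (x, y) at each elevational offset with the true in-plane
    position; the SNR column is averaged over frames.
    """
    rows = []
    truth_idx = truth.set_index("position_id")
    for pid, grp in estimates.groupby("position_id"):
        t = truth_idx.loc[pid]
        valid = grp[grp["valid"].astype(bool)]
        row = {
            "position_id": pid,
            "z_mm": t["z_mm"],
            "n_valid": len(valid),
            "snr_db": float(grp["snr_db"].mean()),
        }
        if len(valid) > 0:
            e = tracking_error(
                valid[["x_mm", "y_mm"]].to_numpy(), np.array([t["x_mm"], t["y_mm"]])
            )
            rep = repeatability(valid[["x_mm", "y_mm"]].to_numpy())
            row.update(
                lateral_displacement_mm=float(e[0]),
                axial_displacement_mm=float(e[1]),
                lateral_repeatability_mm=float(rep[0]),
                axial_repeatability_mm=float(rep[1]),
            )
        else:
            row.update(
                lateral_displacement_mm=np.nan,
                axial_displacement_mm=np.nan,
                lateral_repeatability_mm=np.nan,
                axial_repeatability_mm=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("z_mm").reset_index(drop=True)


def angle_analysis(dataset, template) -> pd.DataFrame:
    """Raw and processed waveform amplitude versus needle insertion angle.

    For each scene of an angle-sweep dataset, the peak amplitude of the
    frame is averaged over repeated frames before and after matched
    filtering and envelope detection.  Amplitudes are reported relative to
    the 0-degree scene (first scene) so the angular dependence is explicit.
    """
    from .preprocess import envelope, matched_filter

    rows = []
    for pid, scene in enumerate(dataset.scenes):
        raw_peaks, proc_peaks = [], []
        for fi in range(dataset.n_frames_per_position):
            frame = dataset.frame(pid, fi)
            raw_peaks.append(float(np.max(np.abs(frame.samples))))
            proc = envelope(matched_filter(frame, template))
            proc_peaks.append(float(np.max(proc.samples)))
        rows.append(
            {
                "angle_deg": scene.needle_angle_deg,
                "raw_amplitude": float(np.mean(raw_peaks)),
                "raw_amplitude_std": float(np.std(raw_peaks, ddof=1)) if len(raw_peaks) > 1 else 0.0,
                "processed_amplitude": float(np.mean(proc_peaks)),
                "processed_amplitude_std": float(np.std(proc_peaks, ddof=1))
                if len(proc_peaks) > 1
                else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    df["raw_relative"] = df["raw_amplitude"] / df["raw_amplitude"].iloc[0]
    df["processed_relative"] = df["processed_amplitude"] / df["processed_amplitude"].iloc[0]
    return df


def label_offset_correction(
    labels_xy: np.ndarray, offset_mm: float, shaft_angle_deg: float
) -> np.ndarray:
    """Correct manually labelled positions for the apparent tip extension.

    The visually apparent tip in a B-mode image is displaced along the
    needle shaft from the true sensor position; the correction subtracts a
    vector of length ``offset_mm`` directed along the shaft at
    ``shaft_angle_deg`` (relative to horizontal, depth-positive y).
    """
    a = math.radians(shaft_angle_deg)
    shift = offset_mm * np.array([math.cos(a), math.sin(a)])
    return np.asarray(labels_xy, dtype=float) - shift


def uncertainty_correlation(estimated_sigma: np.ndarray, measured_rep: np.ndarray) -> float:
    """Pearson correlation between estimated uncertainty magnitudes and
    measured repeatability magnitudes."""
    r, _ = stats.pearsonr(np.asarray(estimated_sigma, float), np.asarray(measured_rep, float))
    return float(r)


# ---------------------------------------------------------------------------
# Kalman smoothing


def _cv_model(dt: float, q: float) -> tuple[np.ndarray, np.ndarray]:
    f1 = np.array([[1.0, dt], [0.0, 1.0]])
    q1 = q * np.array([[dt**3 / 3.0, dt**2 / 2.0], [dt**2 / 2.0, dt]])
    return f1, q1


def _ca_model(dt: float, q: float) -> tuple[np.ndarray, np.ndarray]:
    f1 = np.array([[1.0, dt, dt**2 / 2.0], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
    q1 = q * np.array(
        [
            [dt**5 / 20.0, dt**4 / 8.0, dt**3 / 6.0],
            [dt**4 / 8.0, dt**3 / 3.0, dt**2 / 2.0],
            [dt**3 / 6.0, dt**2 / 2.0, dt],
        ]
    )
    return f1, q1


def kalman_smooth(
    track: list[CartesianEstimate],
    model: str = "constant_velocity",
    process_noise: float = 1.0,
    dt: float = 1.0 / 18.0,
) -> list[CartesianEstimate]:
    """Kalman-filter a time-ordered track of Cartesian estimates.

    ``model`` is "constant_velocity" or "constant_acceleration";
    ``process_noise`` is the white-noise (acceleration or jerk) spectral
    density in mm^2 per s^3 (or s^5).  Each estimate's 2x2 covariance is
    used as the measurement covariance; invalid estimates are treated as
    missing measurements (prediction only).  Returns one smoothed estimate
    per input frame.
    """
    if model == "constant_velocity":
        f1, q1 = _cv_model(dt, process_noise)
    elif model == "constant_acceleration":
        f1, q1 = _ca_model(dt, process_noise)
    else:
        raise ValueError(f"unknown model: {model!r}")
    k = f1.shape[0]
    f = np.kron(np.eye(2), f1)
    q = np.kron(np.eye(2), q1)
    h = np.zeros((2, 2 * k))
    h[0, 0] = 1.0
    h[1, k] = 1.0

    valid = [e for e in track if e.valid]
    if len(valid) < 2:
        raise ValueError("at least two valid estimates are required")

    first = valid[0]
    x = np.zeros(2 * k)
    x[0], x[k] = first.x_mm, first.y_mm
    p = np.eye(2 * k) * 1.0e4

    out: list[CartesianEstimate] = []
    for est in track:
        x = f @ x
        p = f @ p @ f.T + q
        if est.valid:
            r_meas = np.asarray(est.cov_mm2, dtype=float)
            # floor tiny/zero covariances for numerical stability
            r_meas = r_meas + np.eye(2) * 1.0e-12
            z = np.array([est.x_mm, est.y_mm])
            s = h @ p @ h.T + r_meas
            gain = p @ h.T @ np.linalg.inv(s)
            x = x + gain @ (z - h @ x)
            p = (np.eye(2 * k) - gain @ h) @ p
        out.append(
            CartesianEstimate(
                x_mm=float(x[0]),
                y_mm=float(x[k]),
                cov_mm2=(h @ p @ h.T),
                valid=True,
            )
        )
    return out
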