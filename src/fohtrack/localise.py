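"""Needle-tip localisation within a processed FOH frame.

The tip's polar coordinates are estimated in two nearly independent steps:

* **Angle** — the energy of each (matched-filtered, enveloped) column is
  computed, a -6 dB threshold is applied across columns to stop noisy
  scan lines biasing the result, and the centre of mass (energy-weighted
  mean) of the surviving angular energy distribution gives the tip angle
  ``theta_bar``.  The weighted standard deviation of the distribution is a
  measure of its angular width and serves as the uncertainty
  ``sigma_theta``.  When the frame lacks the dynamic range for a meaningful
  centre of mass, the angle of the maximum-amplitude pixel is used instead.

* **Range** — the pulse time of arrival ``t`` on the strongest scan line
  gives ``r = c (t - delay) + rho``.  The onset is found from the
  cumulative energy of the waveform: with ``t_0.1`` and ``t_0.9`` the times
  at which the time-integral of the squared waveform reaches 10% and 90% of
  its final value and ``delta_t = t_0.9 - t_0.1``, the pulse duration is
  ``1.25 delta_t`` and the pulse start is ``t_0.1 - 0.125 delta_t``.  The
  range uncertainty is the pulse length, ``sigma_r = 1.25 c delta_t``.

Because matched filtering and envelope detection reshape the pulse, the
onset measured on a processed column is offset from the raw arrival time by
a fixed, template-dependent amount; the localiser calibrates this offset
once per template by passing a synthetic copy of the template through the
same processing chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .framing import FOHFrame
from .geometry import ProbeGeometry
from .preprocess import (
    DEFAULT_SNR_GATE_DB,
    NoiseLevel,
    PulseTemplate,
    frame_snr,
    matched_filter_envelope,
)

__all__ = [
    "PolarEstimate",
    "ColumnEnergies",
    "TrackerOptions",
    "NoSignalError",
    "PreTransmitError",
    "column_energies",
    "weighted_mean_angle",
    "weighted_angle_spread",
    "time_of_arrival",
    "radial_position",
    "toa_template_offset",
    "localise_frame",
]


class NoSignalError(ValueError):
    """Raised when an operation requires nonzero signal energy."""


class PreTransmitError(ValueError):
    """Raised when a pulse apparently arrives before the transmission."""


@dataclass(frozen=True)
class PolarEstimate:
    """Tracked tip position in probe polar coordinates with uncertainties."""

    r_mm: float
    theta_deg: float
    sigma_r_mm: float
    sigma_theta_deg: float
    snr_db: float
    valid: bool
    method: str = "centre_of_mass"  # or "max_pixel"

    @classmethod
    def invalid(cls, snr_db: float = float("nan")) -> "PolarEstimate":
        return cls(
            r_mm=float("nan"),
            theta_deg=float("nan"),
            sigma_r_mm=float("nan"),
            sigma_theta_deg=float("nan"),
            snr_db=snr_db,
            valid=False,
            method="none",
        )


@dataclass(frozen=True)
class ColumnEnergies:
    """Per-column energies after thresholding, with their scan-line angles."""

    energies: np.ndarray
    angles_deg: np.ndarray
    n_total: int
    n_nonzero: int
    degenerate: bool = False


@dataclass(frozen=True)
class TrackerOptions:
    """Tunable thresholds of the localiser (dB values are relative levels)."""

    threshold_db: float = -6.0
    snr_gate_db: float = DEFAULT_SNR_GATE_DB
    dynamic_range_db: float = 6.0
    toa_gate_pulse_lengths: float = 8.0
    spread_variant: str = "corrected"  # or "printed"
    in_fan_tolerance_deg: float = 1.0


def column_energies(frame: FOHFrame, threshold_db: float = -6.0) -> ColumnEnergies:
    """Column energies with a relative threshold applied across columns.

    Columns whose energy falls below ``max(e) * 10^(threshold_db/10)`` are
    set to zero so that noise-dominated scan lines cannot bias the centre
    of mass in either angular direction.
    """
    e = np.sum(frame.samples**2, axis=0)
    emax = float(np.max(e)) if e.size else 0.0
    if emax == 0.0:
        return ColumnEnergies(
            energies=e,
            angles_deg=frame.line_angles_deg.copy(),
            n_total=frame.n_lines,
            n_nonzero=0,
            degenerate=True,
        )
    e = np.where(e >= emax * 10.0 ** (threshold_db / 10.0), e, 0.0)
    return ColumnEnergies(
        energies=e,
        angles_deg=frame.line_angles_deg.copy(),
        n_total=frame.n_lines,
        n_nonzero=int(np.count_nonzero(e)),
    )


def weighted_mean_angle(ce: ColumnEnergies) -> float:
    """Centre of mass of the thresholded angular energy distribution (deg)."""
    total = float(np.sum(ce.energies))
    if total <= 0.0:
        raise NoSignalError("all column energies are zero")
    return float(np.sum(ce.angles_deg * ce.energies) / total)


def weighted_angle_spread(
    ce: ColumnEnergies, theta_bar_deg: float, variant: str = "corrected"
) -> float:
    """Weighted standard deviation of the angular energy distribution (deg).

    The default ("corrected") form is the energy-weighted RMS deviation
    with a small-sample factor sqrt(N'/(N'-1)), where N' counts columns
    with nonzero energy.  The "printed" variant divides the weighted sum of
    squares by N'(N'-1) times the total energy instead; it is retained for
    comparison because the corrected form is an interpretation of an
    ambiguously typeset formula.  Both return 0 when a single column holds
    all the energy.
    """
    total = float(np.sum(ce.energies))
    if total <= 0.0:
        raise NoSignalError("all column energies are zero")
    nprime = ce.n_nonzero
    if nprime < 2:
        return 0.0
    wss = float(np.sum(ce.energies * (ce.angles_deg - theta_bar_deg) ** 2))
    if variant == "corrected":
        return math.sqrt(wss / total * nprime / (nprime - 1))
    if variant == "printed":
        return math.sqrt(wss / (nprime * (nprime - 1) * total))
    raise ValueError(f"unknown spread variant: {variant!r}")


def time_of_arrival(
    waveform: np.ndarray,
    sample_rate_hz: float,
    gate: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Pulse start time and 10-90% cumulative-energy interval (seconds).

    The cumulative integral of the squared waveform (restricted to the
    half-open sample gate, if given) is treated as a piecewise-linear
    function of time; the crossings of 10% and 90% of its final value are
    located by linear interpolation.  Returns
    ``(t_start, delta_t) = (t_0.1 - 0.125 delta_t, t_0.9 - t_0.1)``.
    """
    w = np.asarray(waveform, dtype=float)
    lo, hi = (0, len(w)) if gate is None else gate
    lo = max(0, int(lo))
    hi = min(len(w), int(hi))
    seg = w[lo:hi]
    e = seg * seg
    total = float(np.sum(e))
    if hi <= lo or total <= 0.0:
        raise NoSignalError("gated waveform has zero energy")
    cum = np.concatenate(([0.0], np.cumsum(e)))  # cum[k] = energy before sample lo+k

    def crossing(q: float) -> float:
        level = q * total
        k = int(np.searchsorted(cum, level, side="right")) - 1
        k = min(k, len(e) - 1)
        frac = (level - cum[k]) / e[k] if e[k] > 0 else 0.0
        return (lo + k + frac) / sample_rate_hz

    t01 = crossing(0.1)
    t09 = crossing(0.9)
    dt = t09 - t01
    return t01 - 0.125 * dt, dt


def radial_position(
    t_start_s: float,
    delta_t_s: float,
    geometry: ProbeGeometry,
    delay_s: float = 0.0,
) -> tuple[float, float]:
    """Range from the centre of curvature: ``r = c (t - delay) + rho`` (mm),
    with uncertainty equal to the pulse length ``sigma_r = 1.25 c delta_t``."""
    t = t_start_s - delay_s
    if t < 0.0:
        raise PreTransmitError("pulse start precedes the transmission")
    c_mm_per_s = geometry.sound_speed_mps * 1e3
    r = c_mm_per_s * t + geometry.radius_of_curvature_mm
    sigma_r = 1.25 * c_mm_per_s * delta_t_s
    return r, sigma_r


def toa_template_offset(template: PulseTemplate, options: TrackerOptions | None = None) -> float:
    """Time-of-arrival bias (s) introduced by the processing chain.

    Passes a clean copy of the template through matched filtering and
    envelope detection and measures how far the estimated onset moves from
    the raw pulse's cumulative-energy onset.  Subtracting this offset from
    onsets measured on processed columns makes the range estimate unbiased.
    """
    if options is None:
        options = TrackerOptions()
    fs = template.sample_rate_hz
    w = template.waveform
    L = len(w)
    raw_onset_s, _ = time_of_arrival(np.abs(w), fs)
    pos = 2 * L
    col = np.zeros(6 * L)
    col[pos : pos + L] = w
    frame = FOHFrame(samples=col[:, None], sample_rate_hz=fs, line_angles_deg=np.array([0.0]))
    proc = matched_filter_envelope(frame, template)
    g = int(round(options.toa_gate_pulse_lengths * L))
    peak = int(np.argmax(proc.samples[:, 0]))
    t_meas, _ = time_of_arrival(proc.samples[:, 0], fs, gate=(peak - g, peak + g + 1))
    return t_meas - (pos / fs + raw_onset_s)


def localise_frame(
    frame: FOHFrame,
    template: PulseTemplate,
    noise: NoiseLevel | None,
    geometry: ProbeGeometry,
    options: TrackerOptions | None = None,
) -> PolarEstimate:
    """Full single-frame tracking pipeline: raw FOH frame to polar estimate.

    Runs matched filter, envelope detection and the SNR gate; estimates the
    angle by thresholded centre of mass when the column-energy distribution
    has sufficient dynamic range (max at least ``dynamic_range_db`` above
    the median), falling back to the maximum pixel otherwise; estimates the
    range from the time of arrival on the maximum-energy surviving column.
    Content-related failures yield ``valid=False`` rather than raising.

    ``noise`` should be the noise level of *processed* (matched-filtered
    and enveloped) transmitter-off frames; pass ``None`` to skip gating.
    """
    if options is None:
        options = TrackerOptions()
    proc = matched_filter_envelope(frame, template)
    snr = frame_snr(proc, noise) if noise is not None else float("inf")
    if noise is not None and snr < options.snr_gate_db:
        return PolarEstimate.invalid(snr_db=snr)

    ce = column_energies(proc, options.threshold_db)
    if ce.degenerate or ce.n_nonzero == 0:
        return PolarEstimate.invalid(snr_db=snr)

    raw_e = np.sum(proc.samples**2, axis=0)
    med = float(np.median(raw_e))
    # zero median with nonzero max is unbounded dynamic range (noise-free)
    com_ok = med == 0.0 or float(np.max(raw_e)) >= med * 10.0 ** (
        options.dynamic_range_db / 10.0
    )
    try:
        theta_bar = weighted_mean_angle(ce)
        sigma_theta = weighted_angle_spread(ce, theta_bar, options.spread_variant)
    except NoSignalError:
        return PolarEstimate.invalid(snr_db=snr)
    if com_ok:
        method = "centre_of_mass"
    else:
        method = "max_pixel"
        flat_peak = np.unravel_index(int(np.argmax(proc.samples)), proc.samples.shape)
        theta_bar = float(frame.line_angles_deg[flat_peak[1]])

    col_idx = int(np.argmax(ce.energies))
    col = proc.samples[:, col_idx]
    g = int(round(options.toa_gate_pulse_lengths * len(template.waveform)))
    peak = int(np.argmax(col))
    try:
        t_meas, delta_t = time_of_arrival(
            col, frame.sample_rate_hz, gate=(peak - g, peak + g + 1)
        )
        t_start = t_meas - toa_template_offset(template, options)
        r, sigma_r = radial_position(
            t_start, delta_t, geometry, frame.trigger_to_transmit_delay_s
        )
    except (NoSignalError, PreTransmitError):
        return PolarEstimate.invalid(snr_db=snr)

    valid = geometry.contains_polar(r, theta_bar, angle_tol_deg=options.in_fan_tolerance_deg)
    return PolarEstimate(
        r_mm=r,
        theta_deg=theta_bar,
        sigma_r_mm=sigma_r,
        sigma_theta_deg=sigma_theta,
        snr_db=snr,
        valid=valid,
        method=method,
    )
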