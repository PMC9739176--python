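"""Segmentation of the continuous hydrophone stream into per-frame arrays.

The digitizer records one long voltage trace from the fibre-optic
hydrophone (FOH) together with two synchronisation signals from the imaging
system: a *line trigger* pulse at every ultrasound transmission and a
*frame gate* that is high for the duration of each B-mode frame.  Rising
edges of the line trigger mark transmissions; the frame gate groups them
into frames.  Each frame becomes a 2-D array (time samples x scan lines)
called an FOH frame, the input to the tracking algorithm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ProbeGeometry, scan_line_angles

__all__ = [
    "TriggerStream",
    "FOHFrame",
    "detect_line_triggers",
    "segment_frames",
    "default_window_samples",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TriggerStream:
    """Line-trigger and frame-gate voltage series sampled at ``sample_rate_hz``."""

    line_trigger: np.ndarray
    frame_gate: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if len(self.line_trigger) != len(self.frame_gate):
            raise ValueError("line trigger and frame gate must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")


@dataclass
class FOHFrame:
    """One frame of per-scan-line hydrophone waveforms.

    ``samples`` has shape (n_samples, n_lines); column ``n`` is the waveform
    received during the transmission along the scan line at angle
    ``line_angles_deg[n]``.  Columns are ordered by increasing angle.
    """

    samples: np.ndarray
    sample_rate_hz: float
    line_angles_deg: np.ndarray
    frame_index: int = 0
    trigger_to_transmit_delay_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.line_angles_deg = np.asarray(self.line_angles_deg, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D array (n_samples, n_lines)")
        if self.samples.shape[1] != len(self.line_angles_deg):
            raise ValueError("one line angle per column is required")
        if self.samples.shape[0] < 1:
            raise ValueError("frame must contain at least one sample per line")
        if np.any(np.diff(self.line_angles_deg) <= 0):
            raise ValueError("columns must be ordered by strictly increasing angle")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    def copy_with(self, samples: np.ndarray) -> "FOHFrame":
        """New frame sharing this frame's metadata but with different samples."""
        return FOHFrame(
            samples=samples,
            sample_rate_hz=self.sample_rate_hz,
            line_angles_deg=self.line_angles_deg.copy(),
            frame_index=self.frame_index,
            trigger_to_transmit_delay_s=self.trigger_to_transmit_delay_s,
        )


def default_window_samples(
    geometry: ProbeGeometry, sample_rate_hz: float, margin_samples: int = 200
) -> int:
    """Acquisition window per scan line: one-way travel time to the imaging
    depth plus a pulse-length margin.  The clinical acquisition window is
    unspecified; this is the package's engineering default."""
    t_oneway = geometry.imaging_depth_mm * 1e-3 / geometry.sound_speed_mps
    return int(math.ceil(t_oneway * sample_rate_hz)) + int(margin_samples)


def detect_line_triggers(
    stream: TriggerStream,
    threshold_v: float,
    min_gap_samples: int | None = None,
) -> np.ndarray:
    """Indices of rising edges of the line trigger.

    A rising edge is a sample where the trigger crosses ``threshold_v``
    upward.  Edges closer than ``min_gap_samples`` to the previous accepted
    edge are treated as glitches and discarded; the default gap is half the
    median inter-edge interval.
    """
    v = np.asarray(stream.line_trigger, dtype=float)
    above = v >= threshold_v
    raw = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        raw = np.concatenate(([0], raw))
    if raw.size == 0:
        return raw
    if min_gap_samples is None:
        if raw.size >= 2:
            min_gap_samples = max(1, int(0.5 * np.median(np.diff(raw))))
        else:
            min_gap_samples = 1
    kept = [int(raw[0])]
    for idx in raw[1:]:
        if idx - kept[-1] >= min_gap_samples:
            kept.append(int(idx))
    return np.asarray(kept, dtype=int)


def _gate_intervals(gate: np.ndarray, threshold_v: float) -> list[tuple[int, int]]:
    """Half-open [start, stop) index intervals where the gate is high."""
    high = np.asarray(gate, dtype=float) >= threshold_v
    edges = np.flatnonzero(np.diff(high.astype(np.int8)))
    starts = list(edges[~high[edges]] + 1)
    stops = list(edges[high[edges]] + 1)
    if high[0]:
        starts.insert(0, 0)
    if high[-1]:
        stops.append(len(high))
    return list(zip(starts, stops))


def segment_frames(
    foh_stream: np.ndarray,
    stream: TriggerStream,
    n_lines: int,
    window_samples: int,
    *,
    geometry: ProbeGeometry | None = None,
    line_angles_deg: np.ndarray | None = None,
    trigger_threshold_v: float = 0.5,
    gate_threshold_v: float = 0.5,
    trigger_to_transmit_delay_s: float = 0.0,
) -> list[FOHFrame]:
    """Split a raw hydrophone stream into FOH frames.

    Each frame-gate high interval is expected to contain exactly
    ``n_lines`` line triggers; its frame then consists of ``window_samples``
    samples of ``foh_stream`` starting at each trigger index.  Gate
    intervals with a different trigger count (dropped or spurious triggers)
    are skipped with a warning, matching the live system's tolerance for
    malformed frames.  Frames whose last column would run past the end of
    the stream are dropped.
    """
    foh = np.asarray(foh_stream, dtype=float)
    if line_angles_deg is None:
        if geometry is None:
            raise ValueError("either line_angles_deg or geometry is required")
        line_angles_deg = scan_line_angles(geometry)
    if len(line_angles_deg) != n_lines:
        raise ValueError("line_angles_deg length must equal n_lines")

    triggers = detect_line_triggers(stream, trigger_threshold_v)
    frames: list[FOHFrame] = []
    frame_index = 0
    for start, stop in _gate_intervals(stream.frame_gate, gate_threshold_v):
        in_gate = triggers[(triggers >= start) & (triggers < stop)]
        if len(in_gate) != n_lines:
            log.warning(
                "frame gate [%d, %d) contains %d triggers, expected %d; skipped",
                start, stop, len(in_gate), n_lines,
            )
            continue
        if in_gate[-1] + window_samples > len(foh):
            log.warning("frame at gate [%d, %d) truncated by stream end; dropped", start, stop)
            continue
        cols = np.stack([foh[t : t + window_samples] for t in in_gate], axis=1)
        frames.append(
            FOHFrame(
                samples=cols,
                sample_rate_hz=stream.sample_rate_hz,
                line_angles_deg=np.asarray(line_angles_deg, dtype=float),
                frame_index=frame_index,
                trigger_to_transmit_delay_s=trigger_to_transmit_delay_s,
            )
        )
        frame_index += 1
    return frames
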