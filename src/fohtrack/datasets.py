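"""HDF5 container for FOH frame datasets and raw streams.

Layout::

    /                       attrs: sample_rate_hz, config_json, version
    /line_angles            shared per-column scan-line angles (deg)
    /frames/<k>             one dataset per frame (n_samples x n_lines),
                            attrs: position_id, frame_index, delay_s
    /truth/<column>         optional ground-truth table columns
    /raw/foh, /raw/line_trigger, /raw/frame_gate   optional raw stream

Floating-point data round-trips bit-exactly.
"""

from __future__ import annotations

import json
from typing import Iterable, Iterator

import h5py
import numpy as np
import pandas as pd

from .framing import FOHFrame, TriggerStream

__all__ = [
    "save_frames",
    "iter_frames",
    "load_truth",
    "save_raw_stream",
    "load_raw_stream",
    "read_config_snapshot",
]


def save_frames(
    path: str,
    frames: Iterable[tuple[int, int, FOHFrame]],
    *,
    truth: pd.DataFrame | None = None,
    config: dict | None = None,
) -> int:
    """Write (position_id, frame_idx, frame) triples; returns frame count."""
    from . import __version__

    n = 0
    with h5py.File(path, "w") as f:
        f.attrs["version"] = __version__
        f.attrs["config_json"] = json.dumps(config or {})
        grp = f.create_group("frames")
        for position_id, frame_idx, frame in frames:
            if "line_angles" not in f:
                f.create_dataset("line_angles", data=frame.line_angles_deg)
                f.attrs["sample_rate_hz"] = frame.sample_rate_hz
            ds = grp.create_dataset(str(n), data=frame.samples)
            ds.attrs["position_id"] = position_id
            ds.attrs["frame_index"] = frame_idx
            ds.attrs["trigger_to_transmit_delay_s"] = frame.trigger_to_transmit_delay_s
            n += 1
        if truth is not None:
            tg = f.create_group("truth")
            for col in truth.columns:
                tg.create_dataset(col, data=truth[col].to_numpy())
    return n


def iter_frames(path: str) -> Iterator[tuple[int, int, FOHFrame]]:
    """Yield (position_id, frame_idx, frame) in stored order."""
    with h5py.File(path, "r") as f:
        angles = f["line_angles"][()]
        fs = float(f.attrs["sample_rate_hz"])
        keys = sorted(f["frames"].keys(), key=int)
        for k in keys:
            ds = f["frames"][k]
            yield (
                int(ds.attrs["position_id"]),
                int(ds.attrs["frame_index"]),
                FOHFrame(
                    samples=ds[()],
                    sample_rate_hz=fs,
                    line_angles_deg=angles,
                    frame_index=int(ds.attrs["frame_index"]),
                    trigger_to_transmit_delay_s=float(
                        ds.attrs["trigger_to_transmit_delay_s"]
                    ),
                ),
            )


def load_truth(path: str) -> pd.DataFrame | None:
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            return None
        return pd.DataFrame({col: f["truth"][col][()] for col in f["truth"].keys()})


def read_config_snapshot(path: str) -> dict:
    with h5py.File(path, "r") as f:
        return json.loads(f.attrs.get("config_json", "{}"))


def save_raw_stream(path: str, foh: np.ndarray, stream: TriggerStream, config: dict | None = None) -> None:
    from . import __version__

    with h5py.File(path, "w") as f:
        f.attrs["version"] = __version__
        f.attrs["config_json"] = json.dumps(config or {})
        g = f.create_group("raw")
        g.create_dataset("foh", data=np.asarray(foh, dtype=float))
        g.create_dataset("line_trigger", data=stream.line_trigger)
        g.create_dataset("frame_gate", data=stream.frame_gate)
        g.attrs["sample_rate_hz"] = stream.sample_rate_hz


def load_raw_stream(path: str) -> tuple[np.ndarray, TriggerStream]:
    with h5py.File(path, "r") as f:
        g = f["raw"]
        stream = TriggerStream(
            line_trigger=g["line_trigger"][()],
            frame_gate=g["frame_gate"][()],
            sample_rate_hz=float(g.attrs["sample_rate_hz"]),
        )
        return g["foh"][()], stream
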