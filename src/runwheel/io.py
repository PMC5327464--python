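"""File interfaces: trace CSV, encoder CSV, multi-page TIFF and JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quadrature import EncoderRecording, WheelSpec

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_encoder_csv",
    "write_encoder_csv",
    "read_movie_tiff",
    "write_movie_tiff",
    "dump_json",
]


def write_trace_csv(path: str | Path, values: np.ndarray, sample_rate: float) -> None:
    """Write a single-channel trace as ``time_s,value`` CSV."""
    t = np.arange(len(values)) / sample_rate
    pd.DataFrame({"time_s": t, "value": values}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a ``time_s,value`` CSV; returns (values, sample_rate)."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace CSV needs at least 2 samples")
    fs = float(1.0 / np.median(np.diff(t)))
    return df["value"].to_numpy(dtype=float), fs


def write_encoder_csv(path: str | Path, rec: EncoderRecording) -> None:
    t = np.arange(rec.n_samples) / rec.sample_rate
    pd.DataFrame(
        {
            "time_s": t,
            "channel_I": rec.channel_I,
            "channel_A": rec.channel_A,
            "channel_B": rec.channel_B,
        }
    ).to_csv(path, index=False)


def read_encoder_csv(path: str | Path, wheel: WheelSpec | None = None) -> EncoderRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = float(1.0 / np.median(np.diff(t)))
    return EncoderRecording(
        channel_I=df["channel_I"].to_numpy(dtype=float),
        channel_A=df["channel_A"].to_numpy(dtype=float),
        channel_B=df["channel_B"].to_numpy(dtype=float),
        sample_rate=fs,
        wheel=wheel or WheelSpec(sample_rate=fs),
    )


def write_movie_tiff(path: str | Path, frames: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_movie_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder))
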