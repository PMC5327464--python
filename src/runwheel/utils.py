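"""Shared helpers: rate conversion between the 10 kHz behaviour clock and
the imaging frame clock."""

from __future__ import annotations

import numpy as np

__all__ = ["frame_edges", "downsample_labels", "downsample_mean"]


def frame_edges(n_samples: int, sample_rate: float, frame_rate: float) -> np.ndarray:
    """Sample-index edges of each frame interval (half-open, last edge = n)."""
    n_frames = int(np.floor(n_samples * frame_rate / sample_rate))
    edges = np.round(np.arange(n_frames + 1) * sample_rate / frame_rate).astype(int)
    return np.clip(edges, 0, n_samples)


def downsample_labels(labels: np.ndarray, sample_rate: float, frame_rate: float) -> np.ndarray:
    """Down-sample per-sample state labels to the frame clock by majority vote."""
    labels = np.asarray(labels)
    edges = frame_edges(len(labels), sample_rate, frame_rate)
    n_frames = len(edges) - 1
    states = np.unique(labels)
    counts = np.zeros((len(states), n_frames), dtype=int)
    for i, s in enumerate(states):
        cum = np.concatenate(([0], np.cumsum(labels == s)))
        counts[i] = cum[edges[1:]] - cum[edges[:-1]]
    return states[np.argmax(counts, axis=0)].astype(labels.dtype)


def downsample_mean(values: np.ndarray, sample_rate: float, frame_rate: float) -> np.ndarray:
    """Down-sample a trace to the frame clock by averaging within each frame."""
    values = np.asarray(values, dtype=float)
    edges = frame_edges(len(values), sample_rate, frame_rate)
    cum = np.concatenate(([0.0], np.cumsum(values)))
    width = np.maximum(edges[1:] - edges[:-1], 1)
    return (cum[edges[1:]] - cum[edges[:-1]]) / width
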