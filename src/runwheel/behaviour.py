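"""Behavioural-state segmentation, step detection and session-level metrics.

Three behavioural phases partition every recording:

* **locomotion** — instantaneous speed above 2 cm/s sustained over at least
  2 cm of travel (pooling walk and run epochs);
* **flickering** — wheel movement above 0.25 cm/s that fails the locomotion
  criterion (slow movement, or fast-but-short bouts), a transitional state
  used as a habituation index;
* **immobility** — no effective wheel rotation (speed at or below 0.25 cm/s).

Within locomotion, individual steps are read from the oscillation of the
speed signal: limbs alternate in anti-phase, so the speed trace oscillates
twice per limb cycle and the distance between consecutive speed peaks is
half the limb step length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing
from scipy.signal import find_peaks

from .quadrature import SpeedTrace

__all__ = [
    "IMMOBILITY",
    "FLICKERING",
    "LOCOMOTION",
    "STATE_NAMES",
    "BehaviourSegmentation",
    "StepSeries",
    "StereotypyResult",
    "VariabilityResult",
    "segment_behaviour",
    "detect_steps",
    "stereotypy",
    "variability",
    "habituation_metrics",
]

IMMOBILITY, FLICKERING, LOCOMOTION = 0, 1, 2
STATE_NAMES = {IMMOBILITY: "immobility", FLICKERING: "flickering", LOCOMOTION: "locomotion"}


@dataclass
class BehaviourSegmentation:
    """Per-sample behavioural labels plus an epoch table.

    ``labels`` holds integer codes (see :data:`STATE_NAMES`); ``epochs`` is a
    DataFrame with one row per contiguous run of a state and columns
    ``state, start_s, end_s, duration_s, distance_cm``.
    """

    labels: np.ndarray
    sample_rate: float
    epochs: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def state_fractions(self) -> dict[str, float]:
        """Fraction of recording time spent in each state (sums to 1)."""
        n = len(self.labels)
        return {
            name: float(np.count_nonzero(self.labels == code)) / n
            for code, name in STATE_NAMES.items()
        }

    def mask(self, state: int) -> np.ndarray:
        return self.labels == state


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        stops = np.concatenate((stops, [len(mask)]))
    return list(zip(starts, stops))


def segment_behaviour(
    trace: SpeedTrace,
    locomotion_speed: float = 2.0,
    locomotion_distance: float = 2.0,
    immobility_speed: float = 0.25,
    bridge_s: float = 0.5,
) -> BehaviourSegmentation:
    """Partition a speed trace into locomotion / flickering / immobility.

    Candidate locomotion runs are contiguous stretches with |speed| above
    ``locomotion_speed``; gaps shorter than ``bridge_s`` between them are
    bridged so an epoch does not fragment at each step's speed trough.
    Runs whose integrated travel falls short of ``locomotion_distance`` are
    demoted to flickering.  All remaining movement above
    ``immobility_speed`` is flickering; the rest is immobility.
    """
    fs = trace.sample_rate
    sp = np.abs(trace.speed)
    fast = sp > locomotion_speed
    gap = max(int(round(bridge_s * fs)), 1)
    if fast.any():
        # edge-pad so closing cannot erode runs touching the recording ends
        padded = np.pad(fast, gap, mode="edge")
        fast = binary_closing(padded, structure=np.ones(gap, dtype=bool))[gap:-gap]

    labels = np.full(len(sp), IMMOBILITY, dtype=np.int8)
    labels[sp > immobility_speed] = FLICKERING

    for start, stop in _runs(fast):
        distance = float(np.sum(sp[start:stop])) / fs
        if distance >= locomotion_distance:
            labels[start:stop] = LOCOMOTION

    rows = []
    bounds = np.flatnonzero(np.diff(labels)) + 1
    edges = np.concatenate(([0], bounds, [len(labels)]))
    for start, stop in zip(edges[:-1], edges[1:]):
        rows.append(
            {
                "state": STATE_NAMES[int(labels[start])],
                "start_s": start / fs,
                "end_s": stop / fs,
                "duration_s": (stop - start) / fs,
                "distance_cm": float(np.sum(sp[start:stop])) / fs,
            }
        )
    epochs = pd.DataFrame(rows, columns=["state", "start_s", "end_s", "duration_s", "distance_cm"])
    return BehaviourSegmentation(labels=labels, sample_rate=fs, epochs=epochs)


@dataclass
class StepSeries:
    """Walking steps read from the speed oscillation during locomotion.

    ``step_lengths_speed`` are distances between consecutive speed-signal
    peaks; limb step lengths are exactly twice those (anti-phase limbs make
    the speed signal oscillate twice per limb cycle).  ``step_rate`` is the
    overall peak rate within locomotion time.
    """

    step_times: np.ndarray
    step_lengths_speed: np.ndarray
    step_lengths_limb: np.ndarray
    step_rate: float

    @property
    def n_steps(self) -> int:
        return len(self.step_times)


def detect_steps(
    trace: SpeedTrace,
    seg: BehaviourSegmentation,
    min_prominence_frac: float = 0.25,
    min_separation_s: float = 0.1,
) -> StepSeries:
    """Detect steps as speed-signal peaks within locomotion epochs.

    Peaks must exceed a prominence of ``min_prominence_frac`` times the
    epoch's median speed and be separated by at least ``min_separation_s``.
    Step lengths are position differences between consecutive peaks inside
    the same epoch.
    """
    fs = trace.sample_rate
    times: list[np.ndarray] = []
    lengths: list[np.ndarray] = []
    total_loco_s = 0.0
    n_peaks = 0
    for start, stop in _runs(seg.mask(LOCOMOTION)):
        sp = np.abs(trace.speed[start:stop])
        total_loco_s += (stop - start) / fs
        prominence = min_prominence_frac * float(np.median(sp))
        if prominence <= 0:
            continue
        peaks, _ = find_peaks(sp, prominence=prominence, distance=max(int(min_separation_s * fs), 1))
        if peaks.size == 0:
            continue
        n_peaks += peaks.size
        times.append((start + peaks) / fs)
        if peaks.size >= 2:
            lengths.append(np.abs(np.diff(trace.position[start + peaks])))

    step_times = np.concatenate(times) if times else np.empty(0)
    step_lengths = np.concatenate(lengths) if lengths else np.empty(0)
    rate = n_peaks / total_loco_s if total_loco_s > 0 else 0.0
    return StepSeries(
        step_times=step_times,
        step_lengths_speed=step_lengths,
        step_lengths_limb=2.0 * step_lengths,
        step_rate=rate,
    )


@dataclass
class StereotypyResult:
    """Dispersion index of a session distribution: iqr / median.

    Near zero for a stereotyped (narrow) distribution, above one for a
    broad one.  Scale-invariant and outlier-robust, so distributions of
    different shape and unit can be compared.
    """

    phi: float
    iqr: float
    center: float


def stereotypy(d: np.ndarray) -> StereotypyResult:
    """Stereotypy φ = iqr(D) / median(D) of a positive-centred sample."""
    d = np.asarray(d, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 4:
        raise ValueError("stereotypy requires at least 4 samples")
    q25, med, q75 = np.percentile(d, [25, 50, 75])
    if med <= 0:
        raise ValueError("stereotypy undefined for non-positive median")
    return StereotypyResult(phi=float((q75 - q25) / med), iqr=float(q75 - q25), center=float(med))


@dataclass
class VariabilityResult:
    """Mean within-unit spread of locomotion probabilities.

    For the intra-individual condition, units are the n=7 days and each
    unit holds the m=5 mice's locomotion probabilities; for the
    inter-individual condition, units are the n=5 mice across m=7 days.
    V is the mean over units of the interquartile range within the unit.
    """

    V: float
    condition: str
    per_unit_iqr: np.ndarray = field(default_factory=lambda: np.empty(0))


def variability(sessions: np.ndarray, condition: str = "intra-individual") -> VariabilityResult:
    """Variability V of locomotion probability across units.

    ``sessions`` is an (n_units, m) array: each row is one condition unit
    (a day for the intra-individual condition, a mouse for the
    inter-individual one) holding the m within-unit probabilities.
    NaNs (missing sessions) are skipped with a warning.
    """
    s = np.asarray(sessions, dtype=float)
    if s.ndim != 2:
        raise ValueError("sessions must be a 2-D (units x samples) array")
    if np.isnan(s).any():
        warnings.warn("missing sessions: variability computed on available data", stacklevel=2)
    q75 = np.nanpercentile(s, 75, axis=1)
    q25 = np.nanpercentile(s, 25, axis=1)
    per_unit = q75 - q25
    return VariabilityResult(V=float(np.mean(per_unit)), condition=condition, per_unit_iqr=per_unit)


def habituation_metrics(
    sessions: list[tuple[SpeedTrace, BehaviourSegmentation]],
) -> pd.DataFrame:
    """Per-day habituation summary across consecutive sessions.

    Returns one row per day with the three state-time fractions (summing
    to 1), the median locomotion speed and the speed stereotypy —  the
    series the bootstrap slope test consumes to quantify habituation
    (e.g. the day-to-day decline of flickering time).
    Days without locomotion get NaN speed metrics with a warning.
    """
    rows = []
    for day, (trace, seg) in enumerate(sessions):
        if seg.n_samples == 0:
            warnings.warn(f"day {day}: empty session excluded", stacklevel=2)
            continue
        frac = seg.state_fractions()
        loco_speed = np.abs(trace.speed[seg.mask(LOCOMOTION)])
        if loco_speed.size >= 4:
            med = float(np.median(loco_speed))
            phi = stereotypy(loco_speed).phi
        else:
            warnings.warn(f"day {day}: no locomotion; speed metrics undefined", stacklevel=2)
            med, phi = np.nan, np.nan
        rows.append(
            {
                "day": day,
                "frac_locomotion": frac["locomotion"],
                "frac_flickering": frac["flickering"],
                "frac_immobility": frac["immobility"],
                "median_speed": med,
                "speed_stereotypy": phi,
            }
        )
    return pd.DataFrame(rows)
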