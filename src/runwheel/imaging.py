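"""Two-photon movie processing: rigid motion correction, motion statistics by
behavioural state, axial-stability probability maps with spatial-reshuffling
surrogates, and ΔF/F extraction.

The lateral motion of the brain is corrected frame by frame with plain
cross-correlation against a reference image taken from a quiet period;
residual axial (z) instability is quantified per pixel as the fraction of
frames in which a small structure (e.g. a ~1 µm axonal bouton) stays above
the frame's own 90th intensity percentile, compared against a chance map
built from spatial reshuffling of the frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .behaviour import IMMOBILITY, LOCOMOTION

__all__ = [
    "MovieStack",
    "MotionSummary",
    "StabilityMap",
    "motion_correct",
    "more_stable_template",
    "motion_by_state",
    "stability_map",
    "reference_image",
    "dff",
]


@dataclass
class MovieStack:
    """A (frames, y, x) image stack with its spatial/temporal calibration."""

    frames: np.ndarray
    pixel_size: float          # µm per pixel
    frame_rate: float          # Hz
    shifts: np.ndarray | None = None   # per-frame applied/estimated (dy, dx), px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, y, x) array")
        if not (0.3 <= self.pixel_size <= 2.0):
            warnings.warn("pixel size outside the 0.3-2 um calibrated range", stacklevel=2)
        if not (8.0 <= self.frame_rate <= 39.0):
            warnings.warn("frame rate outside the 8-39 Hz calibrated range", stacklevel=2)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def crop(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        """ROI crop, 0-based half-open pixel coordinates."""
        return self.frames[:, y : y + h, x : x + w]


@dataclass
class MotionSummary:
    """Per-frame rigid shifts and motion-vector lengths.

    ``shifts`` holds the estimated (dy, dx) of each frame relative to the
    reference, in pixels; ``lengths_um`` the Euclidean vector length in µm.
    ``low_confidence`` flags featureless (flat) frames where the shift was
    set to zero.
    """

    shifts: np.ndarray
    pixel_size: float
    frame_rate: float
    low_confidence: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def lengths_um(self) -> np.ndarray:
        return np.hypot(self.shifts[:, 0], self.shifts[:, 1]) * self.pixel_size

    @property
    def mean_length_um(self) -> float:
        return float(np.mean(self.lengths_um))


def _xcorr_shift(frame: np.ndarray, ref_fft_conj: np.ndarray, shape: tuple[int, int]) -> tuple[int, int]:
    """Integer shift (dy, dx) maximizing circular cross-correlation with ref."""
    cc = np.fft.irfft2(np.fft.rfft2(frame) * ref_fft_conj, s=shape)
    dy, dx = np.unravel_index(int(np.argmax(cc)), shape)
    if dy > shape[0] // 2:
        dy -= shape[0]
    if dx > shape[1] // 2:
        dx -= shape[1]
    return int(dy), int(dx)


def _register(frames: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    shape = frames.shape[1:]
    ref = reference - reference.mean()
    ref_fft_conj = np.conj(np.fft.rfft2(ref))
    shifts = np.zeros((frames.shape[0], 2), dtype=int)
    flat = np.zeros(frames.shape[0], dtype=bool)
    for i, f in enumerate(frames):
        if np.ptp(f) < 1e-12:
            flat[i] = True
            continue
        shifts[i] = _xcorr_shift(f - f.mean(), ref_fft_conj, shape)
    return shifts, flat


def motion_correct(
    stack: MovieStack,
    seg_frames: np.ndarray | None = None,
    reference: np.ndarray | None = None,
    n_reference_frames: int = 10,
) -> tuple[MovieStack, MotionSummary]:
    """Rigid, integer-pixel motion correction by cross-correlation.

    Each frame's (dy, dx) drift is the argmax of its cross-correlation with
    a reference image from a period free of motion and activity.  When no
    reference is supplied it is built in two passes: a first registration
    against the median projection, then the mean of the
    ``n_reference_frames`` lowest-motion frames (restricted to immobility
    when per-frame behaviour labels ``seg_frames`` are given).  Frames are
    translated back by their estimated shift (circular boundary).

    Featureless (flat) frames get zero shift and a low-confidence flag.
    """
    frames = np.asarray(stack.frames, dtype=float)
    if frames.shape[0] < 10:
        raise ValueError("motion correction needs at least 10 frames")

    if reference is None:
        shifts0, _ = _register(frames, np.median(frames, axis=0))
        lengths0 = np.hypot(shifts0[:, 0], shifts0[:, 1])
        order = np.argsort(lengths0, kind="stable")
        if seg_frames is not None:
            immobile = np.asarray(seg_frames) == IMMOBILITY
            order = order[immobile[order]] if immobile.any() else order
        pick = order[: max(min(n_reference_frames, len(order)), 1)]
        aligned0 = np.stack(
            [np.roll(frames[i], (-shifts0[i, 0], -shifts0[i, 1]), axis=(0, 1)) for i in pick]
        )
        reference = aligned0.mean(axis=0)

    shifts, flat = _register(frames, np.asarray(reference, dtype=float))
    aligned = np.stack(
        [np.roll(f, (-dy, -dx), axis=(0, 1)) for f, (dy, dx) in zip(frames, shifts)]
    ).astype(stack.frames.dtype, copy=False)

    summary = MotionSummary(
        shifts=shifts,
        pixel_size=stack.pixel_size,
        frame_rate=stack.frame_rate,
        low_confidence=flat,
    )
    out = MovieStack(
        frames=aligned, pixel_size=stack.pixel_size, frame_rate=stack.frame_rate, shifts=shifts
    )
    return out, summary


def more_stable_template(summary: MotionSummary, seg_frames: np.ndarray) -> np.ndarray:
    """Frame indices of the "more stable" template.

    Behavioural immobility does not guarantee brain immobility, so the
    template keeps only immobility frames whose per-axis |shift| stays
    below the recording's mean motion-vector length.
    """
    seg_frames = np.asarray(seg_frames)
    if len(seg_frames) != len(summary.shifts):
        raise ValueError("behaviour labels must be down-sampled to the frame clock")
    mean_len = summary.mean_length_um
    per_axis_um = np.abs(summary.shifts) * summary.pixel_size
    ok = (seg_frames == IMMOBILITY) & np.all(per_axis_um <= mean_len, axis=1)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError(
            "no immobility frames below the mean motion-vector length; "
            "record a longer quiet period"
        )
    return idx


def motion_by_state(
    summary: MotionSummary,
    seg_frames: np.ndarray,
    onset_window_s: float = 8.0,
) -> dict:
    """Motion magnitude per behavioural state and around locomotion onsets.

    Returns medians of the motion-vector length for locomotion and for the
    "more stable" template, their fold change (locomotion / more-stable),
    and the median ± interquartile displacement profile in an
    ``onset_window_s`` window centred on locomotion onsets.  Absent states
    yield NaN entries with a warning.
    """
    seg_frames = np.asarray(seg_frames)
    lengths = summary.lengths_um
    loco = seg_frames == LOCOMOTION

    med_loco = float(np.median(lengths[loco])) if loco.any() else np.nan
    try:
        stable_idx = more_stable_template(summary, seg_frames)
        med_stable = float(np.median(lengths[stable_idx]))
    except ValueError:
        warnings.warn("more-stable template empty; stable-state motion undefined", stacklevel=2)
        med_stable = np.nan
    if not loco.any():
        warnings.warn("no locomotion frames; locomotion motion undefined", stacklevel=2)

    fold = med_loco / med_stable if med_stable and med_stable > 0 else np.nan

    half = int(round(onset_window_s / 2 * summary.frame_rate))
    onsets = np.flatnonzero(np.diff(loco.astype(np.int8)) == 1) + 1
    profiles = [
        lengths[o - half : o + half]
        for o in onsets
        if o - half >= 0 and o + half <= len(lengths)
    ]
    if profiles:
        arr = np.stack(profiles)
        onset_profile = {
            "time_s": (np.arange(-half, half) / summary.frame_rate),
            "median": np.median(arr, axis=0),
            "q25": np.percentile(arr, 25, axis=0),
            "q75": np.percentile(arr, 75, axis=0),
            "n_onsets": len(profiles),
        }
    else:
        onset_profile = None

    return {
        "median_locomotion_um": med_loco,
        "median_stable_um": med_stable,
        "fold_change": fold,
        "onset_profile": onset_profile,
    }


@dataclass
class StabilityMap:
    """Per-pixel probability of staying in focus, with its chance level.

    ``probability`` is the fraction of template frames in which each pixel
    lies above that frame's own 90th intensity percentile;
    ``chance_map`` the per-pixel 95th percentile over spatially reshuffled
    surrogates.  The supra-chance component around the map peak gives the
    equivalent-circle ``diameter_um`` of the stable structure.  The peak is
    reported both as % of frames and relative to the chance level.
    """

    probability: np.ndarray
    chance_map: np.ndarray
    template: str
    pixel_size: float
    n_surrogates: int
    supra_mask: np.ndarray
    diameter_um: float
    peak_percent: float
    peak_over_chance: float
    supra_fraction: float


def stability_map(
    roi_stack: np.ndarray,
    frame_idx: np.ndarray | None = None,
    pixel_size: float = 1.0,
    n_surrogates: int = 1000,
    percentile: float = 90.0,
    surrogate_percentile: float = 95.0,
    template: str = "more_stable",
    seed: int | np.random.Generator = 0,
) -> StabilityMap:
    """Axial-stability probability map of an ROI over a frame template.

    Each selected frame is binarized at its own ``percentile`` (90th)
    intensity threshold; the map is the per-pixel fraction of frames above
    threshold.  Chance level comes from ``n_surrogates`` spatial
    reshufflings: every frame's pixels are permuted within the frame and
    the map recomputed, and the per-pixel 95th percentile of the surrogate
    maps is the statistical threshold.  (A frame's percentile threshold is
    permutation-invariant, so surrogates permute the precomputed binary
    masks — exactly equivalent to permuting the raw frames, at a fraction
    of the cost.)  The supra-chance connected component containing the map
    peak is summarized by its equivalent-circle diameter,
    ``2·sqrt(area/π) · pixel_size``.
    """
    stack = np.asarray(roi_stack, dtype=float)
    if frame_idx is not None:
        stack = stack[np.asarray(frame_idx)]
    n, h, w = stack.shape
    if n < 20:
        raise ValueError("stability map needs at least 20 template frames")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    thr = np.percentile(stack, percentile, axis=(1, 2))
    masks = stack > thr[:, None, None]
    probability = masks.mean(axis=0)

    flat = np.ascontiguousarray(masks.reshape(n, h * w))
    # full precision: surrogate and observed probabilities are multiples of
    # 1/n and must tie exactly, or rounding turns ties into exceedances
    surro = np.empty((n_surrogates, h * w), dtype=np.float64)
    for s in range(n_surrogates):
        surro[s] = rng.permuted(flat, axis=1).mean(axis=0)
    # conservative permutation quantile: the ceil(q*(n+1))-th order statistic
    # guarantees, by exchangeability of the observed map with its surrogates,
    # that the null exceedance stays at or below the nominal rate even with
    # the discreteness of frame-count probabilities
    rank = min(
        int(np.ceil(surrogate_percentile / 100.0 * (n_surrogates + 1))) - 1,
        n_surrogates - 1,
    )
    chance_map = np.sort(surro, axis=0)[rank].reshape(h, w)

    supra = probability > chance_map
    supra_fraction = float(supra.mean())
    peak_yx = np.unravel_index(int(np.argmax(probability)), probability.shape)
    diameter = 0.0
    component = np.zeros_like(supra)
    if supra[peak_yx]:
        lab = measure.label(supra, connectivity=2)
        component = lab == lab[peak_yx]
        area = int(component.sum())
        diameter = 2.0 * np.sqrt(area / np.pi) * pixel_size

    peak = float(probability[peak_yx])
    chance_at_peak = float(chance_map[peak_yx])
    return StabilityMap(
        probability=probability,
        chance_map=chance_map,
        template=template,
        pixel_size=pixel_size,
        n_surrogates=n_surrogates,
        supra_mask=component,
        diameter_um=float(diameter),
        peak_percent=100.0 * peak,
        peak_over_chance=peak / chance_at_peak if chance_at_peak > 0 else np.inf,
        supra_fraction=supra_fraction,
    )


def reference_image(stack: np.ndarray) -> np.ndarray:
    """Contrast reference: pixelwise median projection × SD projection.

    Emphasizes structures that are both bright on average and active/in
    focus intermittently; used to outline ROIs around small terminals.
    """
    stack = np.asarray(stack, dtype=float)
    return np.median(stack, axis=0) * np.std(stack, axis=0)


def dff(trace: np.ndarray, n_bins: int = 50) -> tuple[np.ndarray, float]:
    """ΔF/F with a mode-of-the-quiet-tail baseline.

    F0 is the main mode (on an ``n_bins`` histogram) of the trace values
    lying between the 5th and 10th percentiles of the full distribution —
    a window that excludes transients — and ΔF/F = (F − F0)/F0.
    Raises when the resulting baseline is non-positive.
    """
    f = np.asarray(trace, dtype=float)
    lo, hi = np.percentile(f, [5, 10])
    window = f[(f >= lo) & (f <= hi)]
    if window.size == 0 or hi <= lo:
        f0 = float(lo)
    else:
        counts, edges = np.histogram(window, bins=n_bins)
        k = int(np.argmax(counts))
        f0 = float((edges[k] + edges[k + 1]) / 2.0)
    if f0 <= 0:
        raise ValueError("non-positive fluorescence baseline F0")
    return (f - f0) / f0, f0
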