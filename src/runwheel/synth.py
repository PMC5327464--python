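"""Synthetic session generators.

Emulates the three input streams of a head-fixed wheel experiment with the
statistical structure the analysis assumes, so every downstream stage runs
and can be validated without real recordings:

* a gait/speed profile over immobility / flickering / locomotion epochs,
  with anti-phase limbs so the speed signal oscillates at twice the limb
  frequency;
* the three-channel optical quadrature encoder waveforms driven by the
  wheel position;
* a 1/f local field potential with ripple bursts injected during
  immobility and speed-modulated theta during locomotion;
* a two-photon calcium movie with Gaussian-profile structures, GCaMP6f-like
  transients, lateral motion coupled to locomotion onsets and axial
  (in-focus) dropouts.

Every generator is deterministic under a fixed seed and returns its ground
truth alongside the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import gaussian as gaussian_window
from scipy.stats import truncnorm

from .behaviour import FLICKERING, IMMOBILITY, LOCOMOTION, STATE_NAMES
from .imaging import MovieStack
from .quadrature import AliasingError, EncoderRecording, WheelSpec

__all__ = [
    "GaitProfile",
    "GaitResult",
    "LFPGenSpec",
    "LFPGroundTruth",
    "Structure",
    "MovieGenSpec",
    "MovieResult",
    "simulate_gait",
    "constant_speed_position",
    "synthesize_encoder",
    "synthesize_lfp",
    "synthesize_movie",
]

_STATE_CODES = {name: code for code, name in STATE_NAMES.items()}


# --------------------------------------------------------------------------
# gait
# --------------------------------------------------------------------------

@dataclass
class GaitProfile:
    """Plan of a behavioural session on the wheel.

    ``epoch_plan`` is an ordered list of (state, duration_s) pairs whose
    durations must sum to ``duration``.  During locomotion the speed is a
    rectified sinusoid riding on ``base_speed`` (default 7.5 cm/s, the
    median spontaneous run speed) oscillating at twice the limb frequency;
    the limb frequency defaults to ``base_speed / step_length_limb`` so
    that each limb advances ``step_length_limb`` (default 5.0 cm) per step.
    """

    duration: float
    epoch_plan: list[tuple[str, float]]
    base_speed: float = 7.5            # cm/s
    step_length_limb: float = 5.0      # cm per limb step
    limb_frequency: float | None = None  # Hz; derived from speed if None
    modulation_depth: float = 0.5      # fraction of base speed that oscillates
    flicker_speed: float = 1.0         # cm/s, centre of flickering movement
    edge_ramp_s: float = 0.25
    sample_rate: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(d for _, d in self.epoch_plan)
        if abs(total - self.duration) > 1e-6:
            raise ValueError(
                f"epoch durations sum to {total} s, not the stated {self.duration} s"
            )
        for state, d in self.epoch_plan:
            if state not in _STATE_CODES:
                raise ValueError(f"unknown state {state!r}")
            if d <= 0:
                raise ValueError("epoch durations must be positive")
        if self.base_speed < 0:
            raise ValueError("base_speed must be non-negative")
        if self.step_length_limb <= 0:
            raise ValueError("step_length_limb must be positive")
        if not 0 <= self.modulation_depth < 1:
            raise ValueError("modulation_depth must lie in [0, 1)")


@dataclass
class GaitResult:
    """Generated kinematics with per-sample ground truth."""

    speed: np.ndarray            # cm/s
    position: np.ndarray         # cm, cumulative
    labels: np.ndarray           # behaviour codes per sample
    limb_contacts: np.ndarray    # (2, n) bool, anti-phase stance indicators
    steps: pd.DataFrame          # time_s, length_speed_cm, length_limb_cm
    sample_rate: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.speed)) / self.sample_rate


def simulate_gait(profile: GaitProfile) -> GaitResult:
    """Simulate speed/position with ground-truth labels, steps and limbs.

    Locomotion speed is ``base·(1−d) + base·d·(π/2)·|sin(2π f t)|`` with
    ``f`` the limb frequency — mean ``base``, oscillating at ``2f`` peaks/s
    (limbs strictly anti-phase), with cosine on/off ramps at the epoch
    edges.  Flickering is a slow 0.5 Hz sway confined to (0.25, 2) cm/s;
    immobility is exactly zero.  Ground-truth step events are the peaks of
    the speed oscillation; the per-limb step length is twice the distance
    between consecutive speed peaks.
    """
    fs = profile.sample_rate
    rng = np.random.default_rng(profile.seed)
    n_total = int(round(profile.duration * fs))
    speed = np.zeros(n_total)
    labels = np.full(n_total, IMMOBILITY, dtype=np.int8)
    contacts = np.zeros((2, n_total), dtype=bool)
    step_rows: list[dict] = []

    start = 0
    for state, dur in profile.epoch_plan:
        n = int(round(dur * fs))
        stop = min(start + n, n_total)
        sl = slice(start, stop)
        t_rel = np.arange(stop - start) / fs
        code = _STATE_CODES[state]
        labels[sl] = code
        if code == LOCOMOTION and profile.base_speed > 0:
            f = profile.limb_frequency
            if f is None:
                f = profile.base_speed / profile.step_length_limb
            d = profile.modulation_depth
            osc = np.abs(np.sin(2 * np.pi * f * t_rel))
            sp = profile.base_speed * ((1 - d) + d * (np.pi / 2) * osc)
            ramp_n = min(int(profile.edge_ramp_s * fs), (stop - start) // 4)
            if ramp_n > 0:
                ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
                sp[:ramp_n] *= ramp
                sp[-ramp_n:] *= ramp[::-1]
            speed[sl] = sp
            stance = np.sin(2 * np.pi * f * t_rel) >= 0
            contacts[0, sl] = stance
            contacts[1, sl] = ~stance
            # ground-truth steps: oscillation peaks at |sin| = 1
            k = 0
            peak_samples = []
            while True:
                tp = (2 * k + 1) / (4 * f)
                ip = int(round(tp * fs))
                if ip >= stop - start:
                    break
                peak_samples.append(start + ip)
                k += 1
            for a, b in zip(peak_samples[:-1], peak_samples[1:]):
                step_rows.append({"time_s": b / fs, "_a": a, "_b": b})
        elif code == FLICKERING:
            phase = rng.uniform(0, 2 * np.pi)
            speed[sl] = profile.flicker_speed + 0.5 * np.sin(2 * np.pi * 0.5 * t_rel + phase)
        start = stop

    position = np.cumsum(speed) / fs
    if step_rows:
        a = np.array([r.pop("_a") for r in step_rows])
        b = np.array([r.pop("_b") for r in step_rows])
        length_speed = position[b] - position[a]
        steps = pd.DataFrame(
            {
                "time_s": [r["time_s"] for r in step_rows],
                "length_speed_cm": length_speed,
                "length_limb_cm": 2.0 * length_speed,
            }
        )
    else:
        steps = pd.DataFrame(columns=["time_s", "length_speed_cm", "length_limb_cm"])

    return GaitResult(
        speed=speed,
        position=position,
        labels=labels,
        limb_contacts=contacts,
        steps=steps,
        sample_rate=fs,
    )


def constant_speed_position(
    speed: float, duration: float, sample_rate: float = 10_000.0, start_position: float = 0.0
) -> np.ndarray:
    """Position trace of the wheel turning at a constant speed (cm/s)."""
    n = int(round(duration * sample_rate))
    return start_position + speed * np.arange(n) / sample_rate


# --------------------------------------------------------------------------
# encoder
# --------------------------------------------------------------------------

def synthesize_encoder(position: np.ndarray, spec: WheelSpec = WheelSpec()) -> EncoderRecording:
    """Render a position trace as the three quadrature encoder channels.

    Channels A and B are square waves with one full cycle per fringe
    (``circumference / fringes_per_turn`` cm of travel), B lagging A by a
    quarter pitch so their order encodes direction; channel I emits one
    index pulse per completed revolution (high while the wheel sits within
    the first fringe of the turn).  Waveforms are edge-exact on the sample
    grid: a fringe boundary falling between samples toggles at the next
    sample.  Motion faster than half a fringe per sample is ambiguous for
    any decoder and raises :class:`AliasingError`.
    """
    x = np.asarray(position, dtype=float)
    q = spec.quarter_pitch
    quarter_idx = np.floor(x / q).astype(np.int64)
    if quarter_idx.size > 1 and np.max(np.abs(np.diff(quarter_idx))) >= 2:
        raise AliasingError(
            "wheel moves more than half a fringe per sample; raise the sample "
            f"rate (max decodable speed {spec.max_speed:.1f} cm/s)"
        )
    phase = quarter_idx % 4
    v = spec.index_pulse_volts
    a = ((phase == 1) | (phase == 2)).astype(float) * v
    b = ((phase == 2) | (phase == 3)).astype(float) * v
    i = (np.mod(x, spec.circumference) < spec.fringe_pitch).astype(float) * v
    return EncoderRecording(
        channel_I=i, channel_A=a, channel_B=b, sample_rate=spec.sample_rate, wheel=spec
    )


# --------------------------------------------------------------------------
# LFP
# --------------------------------------------------------------------------

@dataclass
class LFPGenSpec:
    """Parameters of the synthetic hippocampal LFP.

    Ripples are Gaussian-windowed sinusoid bursts inserted during
    immobility as a Poisson process (rate 0.11 Hz, carrier ~143 ± 14 Hz
    truncated to the 100–250 Hz band, nominal duration 37.7 ms — the
    occurrence, frequency and duration observed in CA1).  Theta during
    locomotion has instantaneous frequency ``base + 0.01·speed`` Hz and
    power growing by 0.023 dB per cm/s.  Amplitudes are in units of the
    1/f background SD; defaults make both rhythms dominate their bands, as
    hippocampal theta and ripples do in stratum pyramidale recordings.
    """

    noise_exponent: float = 1.0        # 1/f^exponent power slope
    noise_sd: float = 1.0
    ripple_rate: float = 0.11          # Hz, Poisson, during immobility
    ripple_freq_mean: float = 143.0    # Hz
    ripple_freq_sd: float = 14.0       # Hz
    ripple_duration_ms: float = 37.7
    ripple_amplitude: float = 2.5      # × noise SD
    theta_base_freq: float = 7.0       # Hz
    theta_freq_slope: float = 0.01     # Hz per cm/s
    theta_power_slope_db: float = 0.023  # dB per cm/s
    theta_amplitude: float = 2.5       # × noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not (100.0 <= self.ripple_freq_mean <= 250.0):
            raise ValueError("ripple carrier mean must lie in the 100-250 Hz band")
        if not (5.0 <= self.theta_base_freq <= 15.0):
            raise ValueError("theta base frequency must lie in the 5-15 Hz band")
        if self.ripple_rate < 0:
            raise ValueError("ripple rate must be non-negative")


@dataclass
class LFPGroundTruth:
    """What was injected: per-event ripple table and per-sample theta."""

    ripples: pd.DataFrame          # time_s, freq_hz, duration_ms
    theta_freq: np.ndarray         # Hz per sample, NaN outside locomotion
    theta_amp: np.ndarray          # amplitude per sample, 0 outside locomotion


def _one_over_f_noise(n: int, exponent: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    return x * (sd / np.std(x))


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask.size and mask[0]:
        starts = np.concatenate(([0], starts))
    if mask.size and mask[-1]:
        stops = np.concatenate((stops, [mask.size]))
    return list(zip(starts, stops))


def synthesize_lfp(
    labels: np.ndarray,
    speed: np.ndarray,
    spec: LFPGenSpec = LFPGenSpec(),
    sample_rate: float = 10_000.0,
) -> tuple[np.ndarray, LFPGroundTruth]:
    """Synthesize an LFP trace aligned to a behaviour session.

    1/f background everywhere; ripple bursts only during immobility;
    theta (speed-modulated in frequency and power, with 0.25 s on/off
    ramps) only during locomotion.  Returns the trace and the injected
    ground truth.
    """
    labels = np.asarray(labels)
    speed = np.asarray(speed, dtype=float)
    if len(labels) != len(speed):
        raise ValueError("labels and speed must be aligned and of equal length")
    rng = np.random.default_rng(spec.seed)
    n = len(labels)
    fs = sample_rate
    lfp = _one_over_f_noise(n, spec.noise_exponent, spec.noise_sd, rng)

    theta_freq = np.full(n, np.nan)
    theta_amp = np.zeros(n)
    for a, b in _runs_of(labels == LOCOMOTION):
        f_inst = spec.theta_base_freq + spec.theta_freq_slope * speed[a:b]
        amp = (
            spec.theta_amplitude
            * spec.noise_sd
            * 10.0 ** (spec.theta_power_slope_db * speed[a:b] / 20.0)
        )
        phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
        ramp_n = min(int(0.25 * fs), (b - a) // 4)
        taper = np.ones(b - a)
        if ramp_n > 0:
            r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
            taper[:ramp_n] = r
            taper[-ramp_n:] = r[::-1]
        lfp[a:b] += amp * taper * np.sin(phase)
        theta_freq[a:b] = f_inst
        theta_amp[a:b] = amp * taper

    rows = []
    dur_n = int(round(spec.ripple_duration_ms / 1000.0 * fs))
    if spec.ripple_rate > 0 and dur_n > 0:
        lo = (100.0 - spec.ripple_freq_mean) / spec.ripple_freq_sd
        hi = (250.0 - spec.ripple_freq_mean) / spec.ripple_freq_sd
        for a, b in _runs_of(labels == IMMOBILITY):
            dur_s = (b - a) / fs
            count = rng.poisson(spec.ripple_rate * dur_s)
            if count == 0:
                continue
            centers = np.sort(rng.uniform(a + dur_n, b - dur_n, size=count).astype(int)) \
                if b - a > 2 * dur_n else np.array([], dtype=int)
            freqs = truncnorm.rvs(lo, hi, loc=spec.ripple_freq_mean,
                                  scale=spec.ripple_freq_sd, size=len(centers), random_state=rng)
            for c, f in zip(centers, freqs):
                t_rel = (np.arange(dur_n) - dur_n / 2) / fs
                win = gaussian_window(dur_n, std=dur_n / 4.0)
                burst = spec.ripple_amplitude * spec.noise_sd * win * np.sin(2 * np.pi * f * t_rel)
                s = c - dur_n // 2
                lfp[s : s + dur_n] += burst
                rows.append(
                    {"time_s": c / fs, "freq_hz": float(f), "duration_ms": spec.ripple_duration_ms}
                )
    ripples = pd.DataFrame(rows, columns=["time_s", "freq_hz", "duration_ms"])
    return lfp, LFPGroundTruth(ripples=ripples, theta_freq=theta_freq, theta_amp=theta_amp)


# --------------------------------------------------------------------------
# calcium movie
# --------------------------------------------------------------------------

@dataclass
class Structure:
    """One fluorescent structure rendered as a 2-D Gaussian profile.

    ``center`` is (y, x) in pixels; ``diameter_um`` is the full width at
    half maximum of the profile.  Putative axonal boutons are ~1 µm
    (validated range 0.8–1.3 µm).
    """

    center: tuple[float, float]
    diameter_um: float
    kind: str = "bouton"               # soma | bouton | dendrite
    amplitude: float = 30.0


@dataclass
class MovieGenSpec:
    """Parameters of the synthetic two-photon movie.

    Lateral motion magnitudes are Rayleigh-distributed with state-specific
    medians (1.8 µm during runs, ~5.6× less while stable) plus a decaying
    kick at each locomotion onset; axial stability enters as a per-state
    in-focus probability drawn per frame and structure (an out-of-focus
    sub-µm bouton effectively vanishes, so the defocus factor defaults
    to 0).  Noise is Poisson shot noise plus Gaussian read noise.
    """

    frame_shape: tuple[int, int] = (64, 64)
    pixel_size_um: float = 1.0
    frame_rate: float = 30.0
    structures: list[Structure] = field(default_factory=list)
    transient_rise_s: float = 0.05
    transient_decay_s: float = 0.4
    transient_amplitude: float = 1.0      # peak ΔF/F
    transient_rate_hz: float = 0.05
    loco_motion_um: float = 1.8           # median lateral motion during runs
    stable_motion_um: float = 1.8 / 5.6   # median during immobility
    onset_kick_um: float = 3.0
    onset_kick_decay_s: float = 0.5
    # per-state probability that a thin structure stays in the focal plane;
    # defaults sit in the ~50-70% range of observed bouton stability peaks
    in_focus_prob: dict = field(
        default_factory=lambda: {"immobility": 0.65, "flickering": 0.6, "locomotion": 0.55}
    )
    # axial dropout only affects structures thinner than the focal depth;
    # 10 um somata ride out the ~2 um axial drift that defocuses a bouton
    focus_sensitive_kinds: tuple = ("bouton", "dendrite")
    out_of_focus_factor: float = 0.0
    background: float = 10.0
    texture_amp: float = 3.0              # neuropil-like static texture (SD)
    texture_sigma_px: float = 2.0
    photon_scale: float = 1.0             # photons per intensity unit; 0 disables shot noise
    read_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.3 <= self.pixel_size_um <= 2.0):
            raise ValueError("pixel size must lie in the calibrated 0.3-2 um range")
        if not (8.0 <= self.frame_rate <= 39.0):
            raise ValueError("frame rate must lie in the 8-39 Hz range")
        h, w = self.frame_shape
        for s in self.structures:
            r_px = s.diameter_um / self.pixel_size_um
            cy, cx = s.center
            if not (r_px <= cy <= h - 1 - r_px and r_px <= cx <= w - 1 - r_px):
                raise ValueError(f"structure at {s.center} lies outside the frame")
            if s.kind == "bouton" and not (0.8 <= s.diameter_um <= 1.3):
                raise ValueError("bouton diameters must lie within 0.8-1.3 um")


@dataclass
class MovieResult:
    """Synthetic movie with full ground truth."""

    stack: MovieStack
    true_shifts: np.ndarray              # (n_frames, 2) int, applied (dy, dx)
    roi_masks: list[np.ndarray]          # per structure, profile > half max
    transient_times: list[np.ndarray]    # per structure, s
    in_focus: np.ndarray                 # (n_structures, n_frames) bool
    dff_traces: np.ndarray               # (n_structures, n_frames) injected ΔF/F


def _transient_kernel(rise: float, decay: float, amplitude: float, fr: float) -> np.ndarray:
    t = np.arange(0, decay * 6, 1.0 / fr)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    return amplitude * k / peak if peak > 0 else k


def synthesize_movie(
    labels_frames: np.ndarray,
    speed_frames: np.ndarray,
    spec: MovieGenSpec,
    shift_sequence: np.ndarray | None = None,
) -> MovieResult:
    """Render a calcium movie for a behaviour session at the frame clock.

    ``labels_frames``/``speed_frames`` must already be down-sampled to the
    imaging frame rate.  An explicit integer ``shift_sequence`` (n, 2)
    overrides the motion model and is returned verbatim as ground truth.
    """
    labels = np.asarray(labels_frames)
    speed = np.asarray(speed_frames, dtype=float)
    if len(labels) != len(speed):
        raise ValueError("labels and speed must be aligned at the frame clock")
    rng = np.random.default_rng(spec.seed)
    n = len(labels)
    h, w = spec.frame_shape
    fr = spec.frame_rate

    # per-structure static profiles and ROI masks
    yy, xx = np.mgrid[0:h, 0:w]
    profiles, masks = [], []
    for s in spec.structures:
        sigma_px = s.diameter_um / 2.355 / spec.pixel_size_um
        g = np.exp(-((yy - s.center[0]) ** 2 + (xx - s.center[1]) ** 2) / (2 * sigma_px**2))
        profiles.append(s.amplitude * g)
        masks.append(g > 0.5)

    # motion model
    if shift_sequence is not None:
        shifts = np.asarray(shift_sequence, dtype=int)
        if shifts.shape != (n, 2):
            raise ValueError("shift_sequence must have shape (n_frames, 2)")
    else:
        median_um = np.where(
            labels == LOCOMOTION, spec.loco_motion_um, spec.stable_motion_um
        ).astype(float)
        mag = rng.rayleigh(scale=median_um / np.sqrt(2 * np.log(2)))
        onsets = np.flatnonzero(np.diff((labels == LOCOMOTION).astype(np.int8)) == 1) + 1
        for o in onsets:
            k = np.arange(n - o)
            mag[o:] += spec.onset_kick_um * np.exp(-k / (spec.onset_kick_decay_s * fr))
        ang = rng.uniform(0, 2 * np.pi, size=n)
        shifts = np.round(
            np.column_stack([mag * np.sin(ang), mag * np.cos(ang)]) / spec.pixel_size_um
        ).astype(int)

    # transients and focus draws
    kernel = _transient_kernel(
        spec.transient_rise_s, spec.transient_decay_s, spec.transient_amplitude, fr
    )
    dff_traces = np.zeros((len(spec.structures), n))
    transient_times = []
    in_focus = np.ones((len(spec.structures), n), dtype=bool)
    p_focus = np.array([spec.in_focus_prob.get(STATE_NAMES[int(l)], 1.0) for l in labels])
    for i, s in enumerate(spec.structures):
        n_ev = rng.poisson(spec.transient_rate_hz * n / fr)
        starts = np.sort(rng.integers(0, max(n - 1, 1), size=n_ev))
        for st in starts:
            seg = kernel[: n - st]
            dff_traces[i, st : st + len(seg)] += seg
        transient_times.append(starts / fr)
        if s.kind in spec.focus_sensitive_kinds:
            in_focus[i] = rng.random(n) < p_focus

    # static neuropil-like texture: moves with the tissue, giving the
    # registration content even when every small structure is defocused
    if spec.texture_amp > 0:
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.standard_normal((h, w)), spec.texture_sigma_px, mode="wrap")
        tex *= spec.texture_amp / tex.std()
    else:
        tex = np.zeros((h, w))

    frames = np.empty((n, h, w), dtype=np.float32)
    for t in range(n):
        img = np.full((h, w), spec.background, dtype=float) + tex
        for i, prof in enumerate(profiles):
            factor = 1.0 if in_focus[i, t] else spec.out_of_focus_factor
            img += prof * factor * (1.0 + dff_traces[i, t])
        img = np.roll(img, (shifts[t, 0], shifts[t, 1]), axis=(0, 1))
        if spec.photon_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * spec.photon_scale) / spec.photon_scale
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0, spec.read_noise_sd, size=img.shape)
        frames[t] = img

    stack = MovieStack(
        frames=frames,
        pixel_size=spec.pixel_size_um,
        frame_rate=fr,
        shifts=shifts,
    )
    return MovieResult(
        stack=stack,
        true_shifts=shifts,
        roi_masks=masks,
        transient_times=transient_times,
        in_focus=in_focus,
        dff_traces=dff_traces,
    )
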