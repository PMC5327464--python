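"""Calcium-trace analysis: transient detection, adaptive thresholds,
population sparseness, pairwise correlations and speed covariance.

Per-cell "on/off" thresholds use an adaptive skewness-zero rule: the
highest data points are withdrawn one at a time until the sample skewness
of what remains is no longer positive, and the threshold is the standard
deviation of the surviving (noise-dominated) data.  Transients are steps
of the trace derivative above mean + 2 SD whose local waveform is
clearly right-skewed (skewness above 1).  Population sparseness is the
fraction of cells off per 500 ms bin — the higher the sparseness, the
lower the coactivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skew

from .behaviour import LOCOMOTION

__all__ = [
    "adaptive_threshold",
    "TransientSet",
    "detect_transients",
    "SparsenessSeries",
    "population_sparseness",
    "pairwise_correlations",
    "CovarianceResult",
    "speed_covariance",
]


def _prefix_skewness(sorted_vals: np.ndarray) -> np.ndarray:
    """Adjusted Fisher-Pearson skewness of every prefix of an ascending sort.

    ``out[k]`` is the skewness of the k+1 smallest values; entries with
    fewer than 3 points or zero variance are NaN.
    """
    x = sorted_vals
    n = np.arange(1, len(x) + 1, dtype=float)
    s1 = np.cumsum(x)
    s2 = np.cumsum(x**2)
    s3 = np.cumsum(x**3)
    m = s1 / n
    m2 = s2 / n - m**2
    m3 = s3 / n - 3 * m * s2 / n + 2 * m**3
    with np.errstate(invalid="ignore", divide="ignore"):
        g1 = m3 / np.where(m2 > 0, m2, np.nan) ** 1.5
        adj = np.sqrt(n * (n - 1)) / (n - 2)
    out = g1 * adj
    out[:2] = np.nan
    return out


def adaptive_threshold(
    values: np.ndarray, max_removed_frac: float = 0.5
) -> tuple[float, np.ndarray, int]:
    """Skewness-zero adaptive threshold for on/off labelling.

    Withdraws the highest data points one by one; at the first point where
    the adjusted Fisher-Pearson skewness of the remainder is ≤ 0, the
    threshold is the sample SD of the surviving data.  If the skewness
    never crosses zero before half the points are removed, falls back to
    median + 2·MAD (scaled) with a warning.

    Returns ``(threshold, on_mask, n_removed)`` where ``on_mask`` marks
    values strictly above the threshold.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 50:
        raise ValueError("adaptive threshold needs at least 50 samples")
    x = np.sort(v)
    sk = _prefix_skewness(x)

    max_removed = int(max_removed_frac * v.size)
    n_removed = None
    # walk from the full sample (no points removed) towards more removal
    for k in range(0, max_removed + 1):
        s = sk[v.size - k - 1]
        if np.isnan(s) or s <= 0:
            n_removed = k
            break
    if n_removed is None:
        warnings.warn(
            "skewness never reached zero within half the sample; "
            "falling back to median + 2 MAD",
            stacklevel=2,
        )
        mad = 1.4826 * np.median(np.abs(v - np.median(v)))
        threshold = float(np.median(v) + 2 * mad)
        return threshold, v > threshold, max_removed

    surviving = x[: v.size - n_removed]
    threshold = float(np.std(surviving, ddof=1))
    return threshold, v > threshold, n_removed


@dataclass
class TransientSet:
    """Detected calcium transients of one ROI."""

    onset_times: np.ndarray       # s
    peak_times: np.ndarray        # s
    amplitudes: np.ndarray        # ΔF/F at the peak
    rise_times_ms: np.ndarray
    rate_hz: float
    threshold: float              # derivative threshold used
    normalized_amplitude: float   # median peak / median baseline value

    @property
    def n_events(self) -> int:
        return len(self.onset_times)


def detect_transients(
    trace: np.ndarray,
    frame_rate: float,
    min_skewness: float = 1.0,
    max_event_s: float = 5.0,
    max_rise_s: float = 1.0,
) -> TransientSet:
    """Detect transients from the trace derivative with a skewness gate.

    Candidate onsets are rising crossings of the first derivative above
    its mean + 2 SD.  The event peak is the first sample within one noise
    SD of the maximum inside ``max_rise_s`` of the onset (indicator rise
    times are well under a second); candidates whose elevation over the
    local pre-onset baseline stays within 3× the noise floor (MAD of the
    derivative) are dropped as chance crossings.  The event segment runs
    until the trace returns near baseline (capped at ``max_event_s``).
    The skewness gate evaluates the segment together with 2 s of
    pre-onset context: a genuine sparse transient (baseline mass plus a
    positive tail) is clearly right-skewed there (> ``min_skewness``),
    while oscillations and chance noise excursions are symmetric and are
    excluded as minor or complex signals.  The gate sets a sensitivity
    floor near 8 noise SDs for isolated events — far below typical
    somatic GCaMP6f transients.  Overlapping segments merge into the
    earlier event.
    """
    f = np.asarray(trace, dtype=float)
    fs = frame_rate
    if len(f) < int(10 * fs):
        raise ValueError("transient detection needs at least 10 s of trace")
    df = np.diff(f)
    if np.ptp(f) < 1e-15:
        return TransientSet(
            onset_times=np.empty(0), peak_times=np.empty(0), amplitudes=np.empty(0),
            rise_times_ms=np.empty(0), rate_hz=0.0, threshold=np.nan,
            normalized_amplitude=np.nan,
        )
    thr = float(df.mean() + 2.0 * df.std())
    above = df > thr
    onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        onsets = np.concatenate(([0], onsets))

    max_n = int(max_event_s * fs)
    rise_n = max(int(max_rise_s * fs), 2)
    pre_n = max(int(2.0 * fs), 3)
    noise_sd = 1.4826 * float(np.median(np.abs(df - np.median(df)))) / np.sqrt(2)
    kept_on, kept_peak, kept_end = [], [], []
    last_end = -1
    in_event = np.zeros(len(f), dtype=bool)
    for o in onsets:
        if o <= last_end:
            continue
        hi = min(o + max_n, len(f))
        seg = f[o : min(o + rise_n, hi)]
        if len(seg) < 3:
            continue
        near_max = np.flatnonzero(seg >= seg.max() - noise_sd)
        peak = o + int(near_max[0])
        base = float(np.median(f[max(o - pre_n // 3, 0) : o + 1]))
        if f[peak] - base < 3.0 * noise_sd:
            continue
        floor = base + 0.1 * (f[peak] - base)
        below = f[peak:hi] < floor
        runs = np.flatnonzero(below[:-1] & below[1:])  # 2 consecutive: a single
        end = peak + (int(runs[0]) + 1 if runs.size else hi - peak)  # noise dip
        if end - o < 3:                                # must not end the event
            continue
        context = f[max(o - pre_n, 0) : end]
        if skew(context, bias=False) <= min_skewness:
            continue
        kept_on.append(o)
        kept_peak.append(peak)
        kept_end.append(end)
        in_event[o:end] = True
        last_end = end

    onsets_arr = np.asarray(kept_on, dtype=int)
    peaks_arr = np.asarray(kept_peak, dtype=int)
    amplitudes = f[peaks_arr] if peaks_arr.size else np.empty(0)
    rise_ms = (peaks_arr - onsets_arr) / fs * 1000.0 if peaks_arr.size else np.empty(0)
    duration_s = len(f) / fs
    baseline = f[~in_event]
    if peaks_arr.size and baseline.size and np.abs(np.median(baseline)) > 1e-12:
        norm_amp = float(np.median(amplitudes) / np.abs(np.median(baseline)))
    else:
        norm_amp = np.nan
    return TransientSet(
        onset_times=onsets_arr / fs,
        peak_times=peaks_arr / fs,
        amplitudes=amplitudes,
        rise_times_ms=rise_ms,
        rate_hz=len(onsets_arr) / duration_s,
        threshold=thr,
        normalized_amplitude=norm_amp,
    )


@dataclass
class SparsenessSeries:
    """Fraction of cells off per time bin, with the per-cell thresholds."""

    fractions: np.ndarray
    bin_s: float
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))


def population_sparseness(
    traces: np.ndarray,
    frame_rate: float,
    bin_s: float = 0.5,
    thresholds: np.ndarray | None = None,
) -> SparsenessSeries:
    """Population sparseness: fraction of cells "off" per 500 ms bin.

    Each cell's response within a bin is its maximum there (so transients
    shorter than the bin still mark it "on"); a cell is off when that
    maximum does not exceed its adaptive skewness-zero threshold.
    Thresholds are computed per cell unless supplied.
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("traces must be a (cells >= 2, time) array")
    n_cells, n_t = x.shape
    if thresholds is None:
        thresholds = np.array([adaptive_threshold(row)[0] for row in x])
    thresholds = np.asarray(thresholds, dtype=float)

    w = max(int(round(bin_s * frame_rate)), 1)
    n_bins = n_t // w
    binned = x[:, : n_bins * w].reshape(n_cells, n_bins, w).max(axis=2)
    off = binned <= thresholds[:, None]
    return SparsenessSeries(fractions=off.mean(axis=0), bin_s=bin_s, thresholds=thresholds)


def pairwise_correlations(traces: np.ndarray) -> tuple[np.ndarray, float]:
    """Zero-lag pairwise correlation matrix and its 75th-percentile summary.

    Cross-covariances of mean-removed traces normalized by the two SDs
    (i.e. Pearson correlations).  Zero-variance traces are excluded from
    the summary with a warning (their rows are NaN).
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 traces of equal length")
    sd = x.std(axis=1)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"{np.count_nonzero(~ok)} zero-variance traces excluded", stacklevel=2)
    corr = np.full((x.shape[0], x.shape[0]), np.nan)
    if ok.sum() >= 2:
        sub = np.corrcoef(x[ok])
        corr[np.ix_(ok, ok)] = sub
    iu = np.triu_indices(x.shape[0], k=1)
    vals = corr[iu]
    vals = vals[np.isfinite(vals)]
    p75 = float(np.percentile(vals, 75)) if vals.size else np.nan
    return corr, p75


@dataclass
class CovarianceResult:
    """Speed cross-covariance of one trace with its surrogate band."""

    lags_s: np.ndarray
    covariance: np.ndarray              # normalized, in [-1, 1]
    threshold: float                    # 99th percentile of surrogate maxima
    significant: bool
    peak_lag_s: float
    peak_covariance: float
    n_surrogates: int
    locomotion_dff: np.ndarray = field(default_factory=lambda: np.empty(0))


def speed_covariance(
    trace: np.ndarray,
    speed: np.ndarray,
    frame_rate: float,
    window_s: float = 10.0,
    n_surrogates: int = 5000,
    seed: int | np.random.Generator = 0,
    labels: np.ndarray | None = None,
) -> CovarianceResult:
    """Normalized speed–calcium cross-covariance with a surrogate test.

    The circular cross-covariance of the mean-removed trace and speed,
    normalized by both SDs, is evaluated over ±``window_s`` lags.  The
    null distribution comes from ``n_surrogates`` random circular
    time-shifts of the trace (preserving autocorrelation, destroying
    alignment); the trace is significant when its in-window maximum
    exceeds the 99th percentile of the surrogate in-window maxima
    (a max-statistic correction across lags).  With behaviour labels the
    locomotion-related ΔF/F values are returned as well.
    """
    x = np.asarray(trace, dtype=float)
    y = np.asarray(speed, dtype=float)
    if len(x) != len(y):
        raise ValueError("trace and speed must share one clock")
    n = len(x)
    w = int(round(window_s * frame_rate))
    if n < 3 * w:
        raise ValueError("recording must span at least 3 covariance windows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    xc = x - x.mean()
    yc = y - y.mean()
    sx, sy = xc.std(), yc.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    # cc[l] = (1/n) sum_t x[(t+l) mod n] * y[t] / (sx*sy)
    cc = np.fft.irfft(np.fft.rfft(xc) * np.conj(np.fft.rfft(yc)), n=n) / (n * sx * sy)

    lag_idx = np.concatenate((np.arange(n - w, n), np.arange(0, w + 1)))
    lags_s = np.concatenate((np.arange(-w, 0), np.arange(0, w + 1))) / frame_rate
    observed = cc[lag_idx]

    shifts = rng.integers(2 * w, n - 2 * w, size=n_surrogates)
    surro_max = np.empty(n_surrogates)
    for i, s in enumerate(shifts):
        surro_max[i] = cc[(lag_idx + s) % n].max()
    threshold = float(np.percentile(surro_max, 99))

    k = int(np.argmax(observed))
    loco_dff = x[np.asarray(labels) == LOCOMOTION] if labels is not None else np.empty(0)
    return CovarianceResult(
        lags_s=lags_s,
        covariance=observed,
        threshold=threshold,
        significant=bool(observed.max() > threshold),
        peak_lag_s=float(lags_s[k]),
        peak_covariance=float(observed[k]),
        n_surrogates=n_surrogates,
        locomotion_dff=loco_dff,
    )
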