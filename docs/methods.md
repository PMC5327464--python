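# Methods

This note records the models, parameter choices and numerical decisions
behind `runwheel`, and what the synthetic-data validation does and does
not establish about real recordings.

## Wheel encoder model and decoder

The encoder is modelled as a 500-cycle-per-turn quadrature device on a
24.19 cm wheel: channels A and B are square waves with one full cycle per
optical fringe (pitch 24.19/500 = 0.04838 cm), B lagging A by a quarter
pitch, and channel I pulsing once per revolution. Synthesis is edge-exact
on the 10 kHz sample grid (a fringe boundary falling between samples
toggles at the next sample), matching digitizer behaviour and keeping the
encode/decode round trip testable. Motion beyond half a fringe per sample
is ambiguous for any 4-state decoder and raises an error; at 10 kHz this
bound is 121 cm/s, just above the 0–120 cm/s range the decoder is
validated over.

Decoding walks the Gray sequence of thresholded (half-amplitude) A/B
states; each valid transition contributes ±pitch/4. Simultaneous
double-channel transitions are flagged and the position held rather than
guessed. Instantaneous speed is the position derivative smoothed with a
100 ms centred moving average: long enough to suppress fringe
quantization, short enough to preserve the ~4 Hz speed oscillation of
gait that step detection relies on. The smoothing implies a speed
quantization floor of one quarter fringe per window (~0.12 cm/s);
relative accuracy of 2% therefore holds above roughly 6 cm/s, with the
absolute floor dominating below.

## Behavioural segmentation

Thresholds follow the platform's standard definitions: locomotion is
|speed| > 2 cm/s sustained over at least 2 cm of travel; flickering is
movement above 0.25 cm/s that fails the locomotion rule (including
fast-but-short bouts); immobility is the remainder. Candidate locomotion
runs are bridged across sub-threshold gaps shorter than 0.5 s so that an
epoch does not fragment at each step's speed trough; the closing operation
is computed on an edge-padded mask so epochs touching the recording
boundaries are not eroded (appending immobility to a recording leaves the
segmentation of the original part unchanged).

Step detection looks for speed peaks within locomotion epochs with
prominence ≥ 25% of the epoch's median speed and ≥ 100 ms separation —
values chosen so that the synthetic-gait recovery suite (7.5–10 cm/s,
5 cm limb steps) is passed with step counts within one step of truth.
Because limbs move in anti-phase, the speed signal oscillates twice per
limb cycle: limb step length is reported as twice the speed-signal step
length.

Stereotypy is `φ = iqr(D)/median(D)` (scale-invariant, outlier-robust,
comparable across distribution shapes); variability `V` is the mean over
condition units (days or mice) of the within-unit interquartile range of
locomotion probabilities.

## LFP states

**Ripples.** The trace is band-passed at 100–250 Hz with a 4th-order
Butterworth applied forward and backward — zero net phase, so event times
can be compared across simultaneously recorded signals. "Power" is the
squared analytic (Hilbert) envelope smoothed over 10 ms; detection
statistics (mean, SD) come from the full trace. Candidate cores exceed
mean + 3 SD; event boundaries extend to the mean + 2.25 SD crossings
around the core. The boundary level is the one genuinely open choice and
was calibrated on event-free 1/f noise: at 1 SD, noise excursions
routinely accumulate the 4-cycle minimum (false-positive rate ~0.14
events/s); at 2.25 SD the false-positive rate is ~0.006 events/s while
synthetic ripples at realistic amplitude keep ≥ 85% recall and ~33 ms
median durations, on the same scale as the ~38 ms of real events.
Intra-ripple frequency is 1/lag of the first positive-lag peak of the
autocorrelation of the 100 ms band-passed segment around the event peak;
events whose frequency falls outside the band, or spanning fewer than 4
cycles (duration × F), are rejected. Occurrence is events per analysed
second (immobile time when a segmentation is supplied).

**Theta.** The LFP is decimated to 100 Hz (FIR, zero-phase) and a complex
Morlet scalogram computed over 5–15 Hz in 0.1 Hz steps. The wavelet
bandwidth (cmor8.0-1.0) was chosen so that the power-weighted mean
frequency of a stationary tone is biased by less than ~0.1 Hz anywhere in
the band (the kernel's frequency-proportional width otherwise drags the
estimate toward the band centre); the cost is ~1 s of temporal support,
acceptable for speed-bin averages. Band power is integrated over a 1 s
centred window and expressed in dB. Speed is block-averaged to the
analysis clock, binned at 0.1 cm/s over locomotion samples, and per-bin
mean frequency/power are fitted linearly (bins with ≥ 5 samples). On
synthetic LFP the imposed frequency slope of 0.01 Hz/(cm/s) is recovered
within a few percent; the dB power slope is recovered within ~20% — the
1/f background adds a floor to band power that compresses the measured
dB range, a bias a real recording shares.

Theta epochs for the state-overlap summaries are stretches where band
power exceeds its own mean + 1 SD; this is a module parameter, since
overlap fractions are reported in the literature without a standard
epoch-extraction rule.

## Imaging

**Motion correction** is rigid and integer-pixel (plain FFT
cross-correlation of mean-subtracted frames, circular boundary), run in
two passes when no reference is supplied: first against the median
projection, then against the mean of the 10 lowest-motion immobility
frames — a period free of motion and, for the synthetic movies, of
activity. Featureless frames get zero shift and a low-confidence flag.
Integer shifts of noise-free or realistic-noise synthetic movies are
recovered exactly; sub-pixel motion rounds to the nearest pixel, which
also quantizes state-wise motion medians (at 1 µm/pixel the ~0.3 µm
stable-state motion reads as zero — use 0.3–0.5 µm pixels when the fold
change between states is of interest).

The **"more stable" template** keeps immobility frames whose per-axis
|shift| stays below the recording's mean motion-vector length, because
behavioural immobility does not guarantee brain immobility. Motion by
state reports medians, their locomotion/stable fold change, and the
median ± interquartile displacement profile in an 8 s window around
locomotion onsets.

**Stability maps.** Within a template's frames, each ROI frame is
binarized at its own 90th intensity percentile (making the map invariant
to global intensity rescaling), and the map is the per-pixel fraction of
supra-threshold frames. Chance comes from spatial reshuffling: each
frame's pixels are permuted within the frame, the map recomputed, 1000
times. A frame's percentile threshold is permutation-invariant, so the
implementation permutes the precomputed binary masks — mathematically
identical to permuting the raw frames and ~50× cheaper. The per-pixel
threshold is the ⌈0.95·(n+1)⌉-th order statistic of the surrogate maps
(the conservative permutation-test quantile) rather than an interpolated
percentile; the supra-chance connected component containing the map peak
is summarized by its equivalent-circle diameter `2·sqrt(area/π)·pixel`.
The peak is reported both as % of frames and relative to the local chance
level (the open question of which normalization the headline number uses
is resolved by reporting both).

**ΔF/F.** `F0` is the main mode (50-bin histogram) of the trace values
between its 5th and 10th percentiles — a window that transient activity
cannot reach, making the baseline robust to event load (verified: < 2%
baseline shift under heavy added transients).

## Calcium activity

**Adaptive threshold.** Highest points are withdrawn one at a time until
the adjusted Fisher–Pearson skewness of the remainder is ≤ 0; the
threshold is the SD of the surviving data (computed in one vectorized
pass over prefix moments). If skewness never crosses zero before half the
sample is removed (e.g. exponentially distributed data), the function
falls back to median + 2·MAD with a warning. On Gaussians contaminated
with up to 20% positive outliers the noise σ is recovered within 15%.

**Transient detection.** Candidate onsets are rising crossings of the
first derivative above its mean + 2 SD. The peak is the first sample
within one noise SD of the maximum inside 1 s of onset; candidates whose
elevation over the local pre-onset baseline is under 3× the derivative's
MAD noise floor are dropped as chance crossings. The event segment runs
to the return below baseline + 10% of elevation (two consecutive frames,
so a single noise dip does not truncate the decay). The asymmetry gate —
skewness > 1 — is evaluated on the segment plus 2 s of pre-onset
context: sparse positive transients over a flat baseline are strongly
right-skewed there, while oscillations and chance excursions are
symmetric and are excluded as minor or complex signals. The gate implies
a sensitivity floor: isolated events below roughly 8 noise SD cannot
reach skewness 1 in any window and are not reported. Somatic GCaMP6f
transients in practice sit far above this floor (tens of noise SDs for
ROI-averaged traces); the floor matters only for single-pixel or
dendritic ROIs, where a detection floor well above noise is likewise
reported for real data.

**Sparseness** bins each cell's trace at 500 ms, takes the bin maximum
(so transients shorter than the bin still mark it "on") and reports the
fraction of cells at or below their adaptive threshold per bin. Note that
with thresholds equal to one noise SD, the maximum of ~15 noise samples
exceeds the threshold most of the time, so sparseness computed on raw
noisy traces is biased low; the quantity is faithful to its definition
and exact on thresholded/denoised responses (verified against
hand-counted on/off matrices).

**Speed covariance** evaluates the normalized circular cross-covariance
of the mean-removed trace and speed over ±10 s of lag. The null is built
from 5000 random circular time-shifts of the trace — preserving its
autocorrelation while destroying alignment — and the trace is called
significant when its in-window maximum exceeds the 99th percentile of the
surrogate in-window maxima (a max-statistic correction, so the family of
lags is tested jointly). Shifts are drawn away from the ±2-window
neighbourhood of zero to keep surrogates unaligned.

## Resampling statistics

The bootstrap slope test pools all raw per-day values, fits value against
day by least squares, and compares the slope with 10 000 slopes from full
reshuffling of values across days (permutation of the pooled multiset).
"Positive"/"negative" calls use the 95th/5th surrogate percentiles, a
two-sided nominal rate of 10%, which the calibration test confirms at
10% ± 2% on exchangeable nulls. Slopes are linear in the data, so
surrogate slopes are computed as a matrix product of permuted values with
the fixed hat vector — 500 calibration replicates at 2000 surrogates run
in seconds.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions the validation suite runs
under:

* **Gait**: locomotion speed = base·(1−d) + base·d·(π/2)·|sin(2πft)| with
  modulation depth d = 0.5 and limb frequency f = base_speed/step_length
  (defaults 7.5 cm/s, 5.0 cm → 1.5 Hz per limb, 3 Hz speed oscillation);
  mean speed equals the base speed and the distance between speed peaks
  equals half the limb step length independent of d. Cosine on/off ramps
  (0.25 s) avoid discontinuities; flickering is a 0.5 Hz sway confined to
  (0.25, 2) cm/s; immobility is exactly zero. Real gait has variable
  cadence and step-length jitter that this rectified-sinusoid model does
  not include, so step-recovery results show correctness of the
  detection rule, not robustness to natural gait variability.
* **LFP**: 1/f background (exponent 1, SD 1); ripples during immobility
  as a Poisson process at 0.11 Hz with carrier ~N(143, 14²) Hz truncated
  to 100–250 Hz, 37.7 ms Gaussian-windowed bursts at 2.5× background SD;
  theta during locomotion at base 7 Hz + 0.01 Hz/(cm/s), power slope
  0.023 dB/(cm/s), amplitude 2.5× background SD — theta dominates the
  locomotor hippocampal spectrum, and this amplitude reflects that.
  Rates, frequencies, durations and slopes are the values reported for
  real CA1 recordings; amplitudes are the generator's own choices since
  SNR is rig-specific.
* **Movies**: structures are 2-D Gaussians (FWHM = stated diameter);
  bouton diameters are restricted to the observed 0.8–1.3 µm range.
  Transients follow a difference of exponentials (rise 50 ms, decay
  400 ms, peak ΔF/F 1.0, rate 0.05 Hz). Lateral motion magnitudes are
  Rayleigh with state medians 1.8 µm (runs) and 1.8/5.6 µm (stable),
  plus a 3 µm kick decaying over 0.5 s at each locomotion onset; shifts
  are rounded to integer pixels and applied circularly, so
  motion-correction recovery can be tested exactly. Axial instability is
  a per-frame in-focus Bernoulli draw per structure, applied only to
  sub-µm structures (boutons, dendrites — a 10 µm soma rides out ~2 µm
  of axial drift); state defaults (0.65/0.6/0.55) sit in the observed
  range of bouton stability peaks. A static smooth "neuropil" texture
  (SD 3 intensity units, ~2 px correlation length, at the shot-noise
  scale of the 10-count background) moves with the tissue so that
  registration has content even when every bouton is defocused; noise is
  Poisson shot noise plus Gaussian read noise (SD 1).

Passing the suite demonstrates that each analysis stage recovers the
parameters this model imposes; it does not demonstrate robustness to
non-rigid motion, slow drift, photobleaching, neuropil contamination of
ROI traces, or natural behavioural variability, none of which the
generators produce.

## Problem sizes

The validation suite uses 600 s LFP segments for ripple statistics (≥ 50
events), ten 30 s locomotion blocks spanning 3–30 cm/s for theta slopes,
2-minute 64×64 movies at 30 Hz (3600 frames) for motion and stability,
1000 spatial surrogates per stability map, 2000 surrogates × 500
replicates for slope-test calibration, and 5000 surrogates for speed
covariance — sizes chosen so every recovery statistic has comfortable
margin over its tolerance while the whole suite runs in minutes.
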