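# runwheel

Analysis stack for head-fixed mouse experiments on a circular treadmill
(running wheel) with simultaneous hippocampal LFP recording and two-photon
calcium imaging — plus synthetic generators for every input stream, so the
entire pipeline runs and validates itself without any recorded data.

The package is written for experimenters who have (or want to prototype
against) three synchronized streams sampled on a common 10 kHz clock:

1. **Optical quadrature encoder** (channels I/A/B) on the wheel axle:
   channel I pulses once per revolution (one turn = 24.19 cm), channels A
   and B emit 500 square cycles per turn, phase-offset by a quarter pitch
   so their lead/lag encodes the direction of rotation.
2. **CA1 local field potential** from a depth electrode.
3. **Two-photon movie stacks** (TIFF) of somata or sub-µm axonal boutons,
   0.3–2 µm/pixel at 8–39 frames/s.

## What it computes

**Locomotion** — the quadrature decoder walks the 4-state Gray sequence;
every valid A/B transition moves the wheel by a quarter fringe pitch
(24.19/500/4 cm), signed by direction. Instantaneous speed is the smoothed
position derivative; per-turn median speed uses the channel-I markers,
`speed_n = (P(n+1) − P(n)) / (T(n+1) − T(n))`.

**Behavioural states** — locomotion (speed > 2 cm/s sustained over
≥ 2 cm), flickering (movement above 0.25 cm/s failing the locomotion
rule; a habituation index), immobility (no wheel rotation). Steps are
peaks of the speed oscillation: limbs alternate in anti-phase, so the
speed signal oscillates twice per limb cycle and the limb step length is
twice the distance between consecutive speed peaks. Session dispersion is
summarized by the stereotypy `φ = iqr(D)/median(D)` and by the
inter-/intra-individual variability `V` (mean within-unit iqr of
locomotion probabilities).

**Hippocampal states** — ripples are detected in the 100–250 Hz band
(4th-order zero-phase Butterworth) as envelope-power excursions ≥ 3 SD of
the full-trace power with at least 4 ripple cycles; the intra-ripple
frequency F is 1/lag of the first positive-lag autocorrelation peak of
the 100 ms event segment, and occurrence is `O = N/D`. Theta (5–15 Hz) is
characterized by the power-weighted instantaneous frequency of a complex
Morlet scalogram and 1-s-integrated band power, both regressed on running
speed binned at 0.1 cm/s.

**Imaging stability** — rigid motion correction by cross-correlation with
a reference from a quiet period; a "more stable" frame template
(immobility frames with sub-average motion); per-state motion medians and
the locomotion/stable fold change; and axial-stability probability maps:
each frame binarized at its own 90th intensity percentile, the per-pixel
fraction of supra-threshold frames compared against the 95th percentile
of 1000 spatially reshuffled surrogate maps, with the supra-chance
equivalent-circle diameter of the imaged bouton.

**Calcium activity** — ΔF/F with `F0` = mode of the 5th–10th percentile
window of the trace; transient detection from the derivative
(mean + 2 SD) with a skewness > 1 asymmetry gate; per-cell adaptive
"skewness-zero" thresholds; population sparseness (fraction of cells off
per 500 ms bin); pairwise zero-lag correlations; and speed–calcium
cross-covariance significance against 5000 circular-shift surrogates at
the 99th percentile.

**Statistics** — a bootstrap slope test for day-to-day trends: the
observed least-squares slope against 10 000 slopes recomputed after full
reshuffling of the values across days (significant beyond the 5th/95th
surrogate percentiles).

## Worked example

Simulate a 3-minute session (spontaneous immobility/locomotion
alternation, LFP with ripples and theta, a movie with two somata and two
boutons), then run the full pipeline:

```python
from runwheel import run_pipeline

report = run_pipeline({
    "seed": 1,
    "session": {"duration": 180.0, "epoch_plan": [
        ["immobility", 45.0], ["locomotion", 30.0], ["flickering", 15.0],
        ["immobility", 40.0], ["locomotion", 35.0], ["immobility", 15.0]]},
}, output_dir="out")

print(report["behaviour"]["median_speed"])       # 7.74  (cm/s; generator ran at 7.5)
print(report["behaviour"]["median_step_length_limb_cm"])  # 5.03  (truth: 5.0)
print(report["lfp"]["ripples"])   # n_events 10, occurrence 0.100 Hz, median 142 Hz
print(report["imaging"]["median_motion_locomotion_um"])   # 1.80 µm during runs
print(report["activity"]["transient_rates_hz"])  # [0.033, 0.044] (injected 0.05 Hz)
```

The decoded median run speed, limb step length, ripple statistics,
lateral-motion magnitude and transient rates all recover the generator's
imposed values; `out/report.json` holds the complete record (state
fractions, stereotypy, theta–speed fits, stability-map summary,
sparseness, provenance and seeds), alongside `epochs.csv`, `speed.csv`,
`ripples.csv` and `theta_bins.csv`.

The same stages are available from the shell:

```bash
runwheel simulate session/ --seed 1          # write synthetic CSV/TIFF inputs
runwheel decode session/encoder.csv speed.csv
runwheel segment speed.csv epochs.csv
runwheel ripples session/lfp.csv events.csv stats.json --speed-csv speed.csv
runwheel run out/                            # full pipeline + report
```

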