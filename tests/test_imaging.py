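"""Motion correction, state-wise motion, stability maps and ΔF/F."""

import numpy as np
import pytest

import runwheel as rw
from runwheel.behaviour import IMMOBILITY, LOCOMOTION
from runwheel.imaging import reference_image


def _stack(frames, **kw):
    kw.setdefault("pixel_size", 1.0)
    kw.setdefault("frame_rate", 30.0)
    return rw.MovieStack(frames=np.asarray(frames, dtype=float), **kw)


class TestMotionCorrect:
    def test_identical_frames_give_zero_shifts(self):
        rng = np.random.default_rng(0)
        base = rng.random((16, 16))
        stack = _stack(np.tile(base, (12, 1, 1)))
        _, summary = rw.motion_correct(stack, reference=base)
        assert np.all(summary.shifts == 0)

    def test_single_shifted_frame_recovered_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.random((32, 32))
        frames = np.tile(base, (12, 1, 1))
        frames[5] = np.roll(base, (3, -2), axis=(0, 1))
        aligned, summary = rw.motion_correct(_stack(frames), reference=base)
        assert tuple(summary.shifts[5]) == (3, -2)
        np.testing.assert_allclose(aligned.frames[5], base)

    def test_generator_shift_sequence_recovered_exactly(self, bouton_movie):
        movie, labels_f, _ = bouton_movie
        _, summary = rw.motion_correct(movie.stack, seg_frames=labels_f)
        assert np.array_equal(summary.shifts, movie.true_shifts)

    def test_flat_frames_flagged_low_confidence(self):
        frames = np.zeros((12, 8, 8))
        _, summary = rw.motion_correct(_stack(frames), reference=np.zeros((8, 8)))
        assert summary.low_confidence.all()
        assert np.all(summary.shifts == 0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="10 frames"):
            rw.motion_correct(_stack(np.zeros((5, 8, 8))))


class TestMoreStableTemplate:
    @staticmethod
    def _summary(shifts, labels):
        return (
            rw.MotionSummary(shifts=np.asarray(shifts), pixel_size=1.0, frame_rate=30.0),
            np.asarray(labels, dtype=np.int8),
        )

    def test_zero_motion_selects_all_immobility_frames(self):
        summary, labels = self._summary(np.zeros((10, 2), dtype=int), [0] * 6 + [2] * 4)
        idx = rw.more_stable_template(summary, labels)
        assert list(idx) == list(range(6))

    def test_only_low_motion_frames_kept(self):
        shifts = np.zeros((8, 2), dtype=int)
        shifts[1::2] = [5, 0]  # alternating 0 / 5 um
        summary, labels = self._summary(shifts, [IMMOBILITY] * 8)
        idx = rw.more_stable_template(summary, labels)
        assert np.all(shifts[idx] == 0)

    def test_no_immobility_raises(self):
        summary, labels = self._summary(np.zeros((6, 2), dtype=int), [LOCOMOTION] * 6)
        with pytest.raises(ValueError, match="longer"):
            rw.more_stable_template(summary, labels)


class TestMotionByState:
    def test_constant_motion_has_unit_fold_change(self):
        shifts = np.ones((20, 2), dtype=int)
        labels = np.array([IMMOBILITY] * 10 + [LOCOMOTION] * 10, dtype=np.int8)
        summary = rw.MotionSummary(shifts=shifts, pixel_size=1.0, frame_rate=30.0)
        res = rw.motion_by_state(summary, labels)
        assert res["fold_change"] == pytest.approx(1.0)

    def test_imposed_state_ratio_recovered(self):
        # fine pixels (0.3 um) so the ~0.32 um stable-state motion does not
        # quantize to zero in the integer-shift ground truth
        n = 1200
        labels = np.zeros(n, dtype=np.int8)
        labels[300:600] = LOCOMOTION
        labels[900:1200] = LOCOMOTION
        spec = rw.MovieGenSpec(
            frame_shape=(64, 64),
            pixel_size_um=0.3,
            frame_rate=30.0,
            structures=[rw.Structure(center=(32, 32), diameter_um=1.0, kind="bouton")],
            in_focus_prob={"immobility": 1.0, "flickering": 1.0, "locomotion": 1.0},
            seed=11,
        )
        movie = rw.synthesize_movie(labels, np.where(labels == LOCOMOTION, 7.5, 0.0), spec)
        _, summary = rw.motion_correct(movie.stack, seg_frames=labels)
        res = rw.motion_by_state(summary, labels)
        true_len = np.hypot(*movie.true_shifts.T) * spec.pixel_size_um
        stable = rw.more_stable_template(summary, labels)
        imposed = np.median(true_len[labels == LOCOMOTION]) / np.median(true_len[stable])
        assert np.isfinite(imposed)
        assert res["fold_change"] == pytest.approx(imposed, rel=0.2)

    def test_onset_profile_peaks_just_after_onset(self):
        n = 600
        labels = np.zeros(n, dtype=np.int8)
        shifts = np.zeros((n, 2), dtype=int)
        for o in (150, 450):
            labels[o : o + 90] = LOCOMOTION
            shifts[o : o + 5] = [4, 0]  # onset-locked kick
        summary = rw.MotionSummary(shifts=shifts, pixel_size=1.0, frame_rate=30.0)
        res = rw.motion_by_state(summary, labels)
        prof = res["onset_profile"]
        t_peak = prof["time_s"][int(np.argmax(prof["median"]))]
        assert 0.0 <= t_peak <= 1.0


class TestStabilityMap:
    def test_static_disk_probability_and_background_level(self):
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[0:16, 0:16]
        disk = ((yy - 8) ** 2 + (xx - 8) ** 2 <= 2).astype(float) * 50
        frames = disk[None] + rng.normal(0, 1, (100, 16, 16))
        sm = rw.stability_map(frames, pixel_size=1.0, n_surrogates=200, seed=1)
        assert sm.probability[8, 8] == 1.0
        background = sm.probability[yy > 12]
        assert np.mean(background) == pytest.approx(0.1, abs=0.05)

    def test_intermittent_structure_peak_matches_presence_fraction(self, bouton_movie):
        movie, labels_f, _ = bouton_movie
        aligned, summary = rw.motion_correct(movie.stack, seg_frames=labels_f)
        stable = rw.more_stable_template(summary, labels_f)
        roi = aligned.frames[:, 14:30, 14:30]
        sm = rw.stability_map(roi, frame_idx=stable, pixel_size=1.0, n_surrogates=300, seed=1)
        truth = movie.in_focus[0][stable].mean()  # ~0.6 by construction
        assert sm.peak_percent / 100 == pytest.approx(truth, abs=0.05)
        peak = np.unravel_index(np.argmax(sm.probability), sm.probability.shape)
        assert peak == (8, 8)  # the bouton, not the background texture

    def test_bouton_diameter_recovered_within_one_pixel(self, bouton_movie):
        movie, labels_f, _ = bouton_movie
        aligned, summary = rw.motion_correct(movie.stack, seg_frames=labels_f)
        stable = rw.more_stable_template(summary, labels_f)
        roi = aligned.frames[:, 14:30, 14:30]
        sm = rw.stability_map(roi, frame_idx=stable, pixel_size=1.0, n_surrogates=300, seed=1)
        assert abs(sm.diameter_um - 1.0) <= 1.0 * movie.stack.pixel_size

    def test_pure_noise_roi_supra_chance_area_at_nominal_rate(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(0, 1, (300, 16, 16))
        sm = rw.stability_map(frames, pixel_size=1.0, n_surrogates=500, seed=2)
        assert sm.supra_fraction <= 0.05

    def test_surrogate_chance_map_is_flat_near_decile(self):
        rng = np.random.default_rng(4)
        frames = rng.normal(0, 1, (200, 12, 12))
        sm = rw.stability_map(frames, pixel_size=1.0, n_surrogates=300, seed=5)
        assert np.all(sm.chance_map > 0.1)
        assert np.all(sm.chance_map < 0.2)

    def test_invariant_to_global_intensity_rescaling(self):
        rng = np.random.default_rng(6)
        frames = rng.random((50, 10, 10))
        a = rw.stability_map(frames, n_surrogates=100, seed=7)
        b = rw.stability_map(1000.0 * frames, n_surrogates=100, seed=7)
        np.testing.assert_array_equal(a.probability, b.probability)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="20"):
            rw.stability_map(np.zeros((10, 8, 8)))

    def test_reference_image_is_median_times_sd(self):
        rng = np.random.default_rng(8)
        stack = rng.random((30, 6, 6))
        np.testing.assert_allclose(
            reference_image(stack), np.median(stack, 0) * np.std(stack, 0)
        )


class TestDff:
    def test_constant_trace_gives_zero_dff(self):
        d, f0 = rw.dff(np.full(1000, 50.0))
        assert f0 == pytest.approx(50.0, rel=0.01)
        np.testing.assert_allclose(d, 0.0, atol=0.02)

    def test_peak_amplitude_relative_to_baseline(self):
        rng = np.random.default_rng(0)
        f = 100.0 + rng.normal(0, 1.0, 2000)
        f[1000:1010] = 200.0
        d, f0 = rw.dff(f)
        assert f0 == pytest.approx(100.0, abs=2.0)
        assert d[1005] == pytest.approx(1.0, abs=0.05)  # 100% ΔF/F

    def test_baseline_robust_to_added_transients(self):
        rng = np.random.default_rng(1)
        f = 100.0 + rng.normal(0, 1.0, 5000)
        _, f0_clean = rw.dff(f)
        g = f.copy()
        for start in range(500, 4500, 500):
            g[start : start + 60] += 80.0 * np.exp(-np.arange(60) / 15.0)
        _, f0_loaded = rw.dff(g)
        assert abs(f0_loaded - f0_clean) / f0_clean <= 0.02

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            rw.dff(np.full(100, -5.0))
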