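"""End-to-end session pipeline: simulate (or load) → decode → segment →
steps → LFP → imaging → activity → JSON report.

The pipeline is configured by a single mapping (or YAML file).  Every
threshold it applies is echoed into the report, all randomness flows from
one top-level seed expanded per stage, and totals in the report are sums
of the epoch-level entries it also writes.  Missing input streams skip
their stage with an explicit notice.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import activity as act
from . import behaviour as beh
from . import imaging as img
from . import io as rwio
from . import lfp as lfpmod
from . import synth
from .quadrature import WheelSpec, decode_quadrature, median_speed_per_turn
from .utils import downsample_labels, downsample_mean

__all__ = ["run_pipeline", "default_config"]


def default_config() -> dict:
    """A complete synthetic-session configuration with the standard
    thresholds (2 cm/s, 2 cm, 0.25 cm/s; 3 SD / 4 cycles; 90th / 95th
    percentiles) and generator defaults."""
    return {
        "seed": 0,
        "session": {
            "duration": 120.0,
            "epoch_plan": [
                ["immobility", 30.0],
                ["locomotion", 20.0],
                ["flickering", 10.0],
                ["immobility", 25.0],
                ["locomotion", 25.0],
                ["immobility", 10.0],
            ],
            "base_speed": 7.5,
            "step_length_limb": 5.0,
        },
        "wheel": {"circumference": 24.19, "fringes_per_turn": 500, "sample_rate": 10000.0},
        "thresholds": {
            "locomotion_speed": 2.0,
            "locomotion_distance": 2.0,
            "immobility_speed": 0.25,
        },
        "lfp": {"enabled": True},
        "movie": {
            "enabled": True,
            "frame_shape": [64, 64],
            "pixel_size_um": 0.5,
            "frame_rate": 30.0,
            "n_surrogates": 1000,
            "covariance_surrogates": 5000,
        },
        "inputs": {},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | str | Path | None = None, output_dir: str | Path | None = None) -> dict:
    """Execute the full analysis chain and return the session report.

    ``config`` may be a mapping, a YAML path, or None (defaults).  With
    ``output_dir`` the report JSON plus epoch/step/ripple/theta CSV tables
    are written there.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(default_config(), config or {})
    seed = int(cfg["seed"])
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["gait", "lfp", "movie", "covariance", "stability"],
            np.random.SeedSequence(seed).spawn(5),
        )
    }
    report: dict = {
        "config": cfg,
        "seeds": {"top": seed, **stage_seeds},
        "notices": [],
    }
    out = Path(output_dir) if output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    wheel = WheelSpec(**cfg["wheel"])
    fs = wheel.sample_rate

    # ---- encoder / behaviour -------------------------------------------
    inputs = cfg.get("inputs") or {}
    gait = None
    if inputs.get("encoder_csv"):
        rec = rwio.read_encoder_csv(inputs["encoder_csv"], wheel=wheel)
    else:
        sess = cfg["session"]
        profile = synth.GaitProfile(
            duration=float(sess["duration"]),
            epoch_plan=[(s, float(d)) for s, d in sess["epoch_plan"]],
            base_speed=float(sess["base_speed"]),
            step_length_limb=float(sess["step_length_limb"]),
            sample_rate=fs,
            seed=stage_seeds["gait"],
        )
        gait = synth.simulate_gait(profile)
        rec = synth.synthesize_encoder(gait.position, wheel)

    trace = decode_quadrature(rec)
    thr = cfg["thresholds"]
    seg = beh.segment_behaviour(
        trace,
        locomotion_speed=thr["locomotion_speed"],
        locomotion_distance=thr["locomotion_distance"],
        immobility_speed=thr["immobility_speed"],
    )
    steps = beh.detect_steps(trace, seg)
    turns = median_speed_per_turn(trace) if len(trace.turn_times) >= 2 else None

    loco_speed = np.abs(trace.speed[seg.mask(beh.LOCOMOTION)])
    behaviour_report = {
        "state_fractions": seg.state_fractions(),
        "n_epochs": int(len(seg.epochs)),
        "total_distance_cm": float(seg.epochs["distance_cm"].sum()),
        "locomotion_distance_cm": float(
            seg.epochs.loc[seg.epochs.state == "locomotion", "distance_cm"].sum()
        ),
        "median_speed": float(np.median(loco_speed)) if loco_speed.size else None,
        "speed_stereotypy": (
            beh.stereotypy(loco_speed).phi if loco_speed.size >= 4 else None
        ),
        "n_steps": int(steps.n_steps),
        "step_rate_hz": steps.step_rate,
        "median_step_length_limb_cm": (
            float(np.median(steps.step_lengths_limb)) if steps.step_lengths_limb.size else None
        ),
        "n_turns": int(len(turns)) if turns is not None else 0,
        "median_turn_speed": float(turns["speed"].median()) if turns is not None and len(turns) else None,
    }
    report["behaviour"] = behaviour_report
    if out:
        seg.epochs.to_csv(out / "epochs.csv", index=False)
        rwio.write_trace_csv(out / "speed.csv", trace.speed, fs)

    # ---- LFP ------------------------------------------------------------
    lfp_trace = None
    if inputs.get("lfp_csv"):
        lfp_trace, lfp_fs = rwio.read_trace_csv(inputs["lfp_csv"])
    elif cfg["lfp"].get("enabled", True):
        gen_keys = {
            k: v for k, v in cfg["lfp"].items() if k not in ("enabled",)
        }
        lfp_spec = synth.LFPGenSpec(seed=stage_seeds["lfp"], **gen_keys)
        lfp_trace, lfp_gt = synth.synthesize_lfp(seg.labels, np.abs(trace.speed), lfp_spec, fs)
        lfp_fs = fs
        report["lfp_ground_truth"] = {"n_ripples": int(len(lfp_gt.ripples))}
    if lfp_trace is None:
        report["notices"].append("LFP stage skipped: no input stream")
    else:
        events, stats = lfpmod.detect_ripples(lfp_trace, lfp_fs, seg=seg)
        profile = lfpmod.theta_profile(lfp_trace, lfp_fs, np.abs(trace.speed))
        theta_mask = lfpmod.theta_epochs(profile.power)
        loco_mask = downsample_labels(seg.labels, fs, profile.fs)[: len(theta_mask)] == beh.LOCOMOTION
        overlap = lfpmod.state_overlap(theta_mask[: len(loco_mask)], loco_mask)
        report["lfp"] = {
            "ripples": {
                "n_events": stats.n_events,
                "occurrence_hz": stats.occurrence_hz,
                "median_freq_hz": stats.median_freq_hz,
                "median_duration_ms": stats.median_duration_ms,
            },
            "theta": {
                "freq_slope_hz_per_cms": profile.freq_slope,
                "freq_r": profile.freq_r,
                "power_slope_db_per_cms": profile.power_slope_db,
                "power_r": profile.power_r,
                "fit_defined": profile.fit_defined,
                **overlap,
            },
        }
        if out:
            import pandas as pd

            pd.DataFrame([e.__dict__ for e in events]).to_csv(out / "ripples.csv", index=False)
            profile.bins.to_csv(out / "theta_bins.csv", index=False)

    # ---- imaging / activity --------------------------------------------
    movie_cfg = cfg["movie"]
    movie = None
    roi_masks = None
    roi_kinds: list[str] | None = None
    if inputs.get("movie_tiff"):
        frames = rwio.read_movie_tiff(inputs["movie_tiff"])
        stack = img.MovieStack(
            frames=frames,
            pixel_size=float(movie_cfg["pixel_size_um"]),
            frame_rate=float(movie_cfg["frame_rate"]),
        )
    elif movie_cfg.get("enabled", True):
        fr = float(movie_cfg["frame_rate"])
        labels_f = downsample_labels(seg.labels, fs, fr)
        speed_f = downsample_mean(np.abs(trace.speed), fs, fr)[: len(labels_f)]
        h, w = movie_cfg["frame_shape"]
        px = float(movie_cfg["pixel_size_um"])
        soma_d = 10.0
        margin = int(np.ceil(soma_d / px)) + 1
        structures = [
            synth.Structure(center=(margin, margin), diameter_um=soma_d, kind="soma"),
            synth.Structure(center=(h - margin, w - margin), diameter_um=soma_d, kind="soma"),
            synth.Structure(center=(round(h * 0.3), round(w * 0.7)), diameter_um=1.0, kind="bouton"),
            synth.Structure(center=(round(h * 0.7), round(w * 0.3)), diameter_um=1.2, kind="bouton"),
        ]
        mspec = synth.MovieGenSpec(
            frame_shape=(int(h), int(w)),
            pixel_size_um=float(movie_cfg["pixel_size_um"]),
            frame_rate=fr,
            structures=structures,
            seed=stage_seeds["movie"],
        )
        movie = synth.synthesize_movie(labels_f, speed_f, mspec)
        stack = movie.stack
        roi_masks = movie.roi_masks
        roi_kinds = [s.kind for s in structures]
    else:
        stack = None
        report["notices"].append("imaging stage skipped: no movie stream")

    if stack is not None:
        fr = stack.frame_rate
        labels_f = downsample_labels(seg.labels, fs, fr)[: stack.n_frames]
        speed_f = downsample_mean(np.abs(trace.speed), fs, fr)[: stack.n_frames]
        aligned, summary = img.motion_correct(stack, seg_frames=labels_f)
        motion = img.motion_by_state(summary, labels_f)
        report["imaging"] = {
            "median_motion_locomotion_um": motion["median_locomotion_um"],
            "median_motion_stable_um": motion["median_stable_um"],
            "motion_fold_change": motion["fold_change"],
        }
        try:
            stable_idx = img.more_stable_template(summary, labels_f)
            if roi_masks:
                # stability is assessed on a small structure (first bouton)
                kinds = roi_kinds or ["roi"] * len(roi_masks)
                i_small = next(
                    (i for i, k in enumerate(kinds) if k == "bouton"), 0
                )
                ys, xs = np.nonzero(roi_masks[i_small])
                cy, cx = int(ys.mean()), int(xs.mean())
            else:
                cy = cx = stack.frames.shape[1] // 2
            rhw = 8
            roi = aligned.frames[
                :, max(cy - rhw, 0) : cy + rhw, max(cx - rhw, 0) : cx + rhw
            ]
            smap = img.stability_map(
                roi,
                frame_idx=stable_idx if len(stable_idx) >= 20 else None,
                pixel_size=stack.pixel_size,
                n_surrogates=int(movie_cfg.get("n_surrogates", 1000)),
                seed=stage_seeds["stability"],
            )
            report["imaging"]["stability"] = {
                "peak_percent": smap.peak_percent,
                "peak_over_chance": smap.peak_over_chance,
                "diameter_um": smap.diameter_um,
                "supra_fraction": smap.supra_fraction,
            }
        except ValueError as e:
            report["notices"].append(f"stability stage skipped: {e}")

        if roi_masks:
            # activity analysis runs on the focus-stable cell bodies
            kinds = roi_kinds or ["roi"] * len(roi_masks)
            soma_masks = [
                m for m, k in zip(roi_masks, kinds) if k == "soma"
            ] or roi_masks
            traces = np.stack(
                [aligned.frames[:, m].mean(axis=1) for m in soma_masks]
            )
            dffs = np.stack([img.dff(t)[0] for t in traces])
            transients = [
                act.detect_transients(d, fr) for d in dffs
            ]
            spars = act.population_sparseness(dffs, fr)
            _, p75 = act.pairwise_correlations(dffs)
            cov = act.speed_covariance(
                dffs[0],
                speed_f,
                fr,
                n_surrogates=int(movie_cfg.get("covariance_surrogates", 5000)),
                seed=stage_seeds["covariance"],
                labels=labels_f,
            )
            report["activity"] = {
                "transient_rates_hz": [t.rate_hz for t in transients],
                "median_sparseness": float(np.median(spars.fractions)),
                "pairwise_corr_p75": p75,
                "speed_covariance_significant": cov.significant,
                "speed_covariance_peak": cov.peak_covariance,
            }
        else:
            report["notices"].append("activity stage skipped: no ROI masks")

    if out:
        rwio.dump_json(report, out / "report.json")
    return report
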