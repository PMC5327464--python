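import numpy as np
import pytest

import runwheel as rw
from runwheel.utils import downsample_labels, downsample_mean

FS = 10_000.0


@pytest.fixture(scope="session")
def gait_session():
    """A mixed-behaviour session: immobility, two runs, flickering."""
    profile = rw.GaitProfile(
        duration=60.0,
        epoch_plan=[
            ("immobility", 10.0),
            ("locomotion", 20.0),
            ("flickering", 10.0),
            ("locomotion", 10.0),
            ("immobility", 10.0),
        ],
        base_speed=10.0,
        step_length_limb=5.0,
        seed=1,
    )
    return rw.simulate_gait(profile)


@pytest.fixture(scope="session")
def decoded_session(gait_session):
    rec = rw.synthesize_encoder(gait_session.position, rw.WheelSpec())
    trace = rw.decode_quadrature(rec)
    seg = rw.segment_behaviour(trace)
    return trace, seg


@pytest.fixture(scope="session")
def bouton_movie():
    """Two blinking boutons (60% in focus) over a 2-minute session."""
    profile = rw.GaitProfile(
        duration=120.0,
        epoch_plan=[
            ("immobility", 40.0),
            ("locomotion", 25.0),
            ("immobility", 30.0),
            ("locomotion", 25.0),
        ],
        base_speed=7.5,
        seed=2,
    )
    gait = rw.simulate_gait(profile)
    fr = 30.0
    labels_f = downsample_labels(gait.labels, FS, fr)
    speed_f = downsample_mean(gait.speed, FS, fr)[: len(labels_f)]
    spec = rw.MovieGenSpec(
        frame_shape=(64, 64),
        pixel_size_um=1.0,
        frame_rate=fr,
        structures=[
            rw.Structure(center=(22, 22), diameter_um=1.0, kind="bouton"),
            rw.Structure(center=(44, 40), diameter_um=1.2, kind="bouton"),
        ],
        in_focus_prob={"immobility": 0.6, "flickering": 0.6, "locomotion": 0.6},
        seed=7,
    )
    movie = rw.synthesize_movie(labels_f, speed_f, spec)
    return movie, labels_f, speed_f
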