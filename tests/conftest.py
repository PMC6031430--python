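"""Shared fixtures: costly synthetic runs are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from optomap import behavior_embedding as be
from optomap import synthetic_arena as sa
from optomap import workflows as wf


@pytest.fixture(scope="session")
def activated_run():
    """Full phenotyping analysis of one strong-effect line (test scale)."""
    return wf.run_line_analysis(sa.activated_config(), seed=7)


@pytest.fixture(scope="session")
def three_state_embedding():
    """Trained embedding of three noiseless, long-dwell states."""
    cfg = sa.null_config(n_states=3, n_modes=6, noise_sd=0.0, p_stay=0.998)
    schedule = sa.make_led_schedule(100, 3, 15, 45)
    sessions = wf.simulate_line_features(cfg, schedule, seed=11,
                                         n_experimental=3, n_control=3, stride=5)
    training, embedding, tracks, frac = wf.embed_sessions(
        sessions, 12, quota=200, train_size=900, max_iter=350)
    return dict(config=cfg, schedule=schedule, sessions=sessions,
                training=training, embedding=embedding, tracks=tracks,
                embedded_fraction=frac)


@pytest.fixture(scope="session")
def rendered_movie():
    """Short noiseless rendered movie with its ground truth."""
    cfg = sa.activated_config(noise_sd=0.0)
    schedule = sa.make_led_schedule(100, 1, 15, 45)
    gt = sa.simulate_states(cfg, schedule, seed=2)
    movie = sa.render_movie(gt, cfg, seed=3, size=96, n_frames=300,
                            schedule=schedule)
    return dict(config=cfg, schedule=schedule, gt=gt, movie=movie)


@pytest.fixture(scope="session")
def context_cluster_run():
    """State-cluster session of a deterministic (delta=1) context line."""
    schedule = sa.make_led_schedule(100, 30, 15, 45)
    cfg = sa.context_config(1.0, p_stay=0.993)
    cmap = wf.state_cluster_session(cfg, schedule, seed=3, resolution=24,
                                    spread=0.01, stride=2, sigma=1.0)
    return dict(config=cfg, schedule=schedule, cmap=cmap)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
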