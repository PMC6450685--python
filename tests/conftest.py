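"""Shared fixtures: small fast synthetic sessions and reduced configs.

Heavy cohort-level fixtures used by the acceptance tests live in
tests/test_acceptance.py with module scope so they are computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from nociscope.config import make_default_config
from nociscope.synthetic import generate_session


@pytest.fixture(scope="session")
def default_config():
    return make_default_config()


@pytest.fixture(scope="session")
def small_config():
    """Short, light session: full panel, 6 trials each, ~40 neurons."""
    return make_default_config(
        neurons_per_session_mean=40, neurons_per_session_sd=2,
        trials_per_stimulus=6, inter_trial_interval_s=(15.0, 18.0))


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, seed=11)


@pytest.fixture(scope="session")
def movie_config():
    """25-cell, ~2000-frame configuration for the extraction stage."""
    return make_default_config(
        neurons_per_session_mean=25, neurons_per_session_sd=0,
        trials_per_stimulus=2, inter_trial_interval_s=(4.0, 6.0),
        lead_in_s=5.0, tail_s=5.0, fov_size_px=(100, 100))


@pytest.fixture(scope="session")
def rendered_movie(movie_config):
    from nociscope.synthetic import render_movie
    session, truth = generate_session(movie_config, seed=42)
    movie, footprints, centroids = render_movie(
        session, width=100, height=100, cell_radius=3.0, seed=0, noise_sd=2.0)
    return {"session": session, "truth": truth, "movie": movie,
            "footprints": footprints, "centroids": centroids}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
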