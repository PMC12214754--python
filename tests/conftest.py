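"""Shared fixtures: the full stimulus grid, its data matrices and PCA bases,
and calibrated synthetic populations (session-scoped; built once)."""

import numpy as np
import pytest

import posexis as px
from posexis.keypoint_features import VARIANTS
from posexis.unit_selection import split_half_reliability_matrix


@pytest.fixture(scope="session")
def pose_set():
    return px.generate_pose_set(45, 16, seed=1)


@pytest.fixture(scope="session")
def matrices(pose_set):
    return {v: px.build_data_matrix(pose_set, v) for v in VARIANTS}


@pytest.fixture(scope="session")
def bases(matrices):
    return {v: px.fit_pca(matrices[v], 10) for v in VARIANTS}


@pytest.fixture(scope="session")
def scores(matrices, bases):
    return {v: bases[v].project(matrices[v].X) for v in VARIANTS}


@pytest.fixture(scope="session")
def populations(scores):
    """50 units per generative variant at target reliability 0.7, with the
    realized (100-split) split-half reliabilities."""
    pops = {}
    for i, v in enumerate(VARIANTS):
        units = px.simulate_encoding_units(
            scores[v], n_units=50, target_reliability=0.7, n_trials=6,
            seed=100 + i, variant=v,
        )
        rates = np.stack([u.response_rates for u in units])
        rel = split_half_reliability_matrix(
            rates, n_splits=100, rng=np.random.default_rng(1000 + i)
        )
        pops[v] = (units, rel)
    return pops


@pytest.fixture(scope="session")
def silhouettes(pose_set):
    return px.render_silhouettes(pose_set, grid=25)
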