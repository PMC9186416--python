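"""Shared fixtures: tiny planted instances and one full desk-scale run.

Everything is generated programmatically; the expensive end-to-end fit is
session-scoped so the feature/classification tests and the acceptance
suite share a single fitted model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from htssr import (
    desk_scale_config,
    make_ground_truth,
    run_repeat,
    sample_voxels,
    simulate_dataset,
    synthesize_dataset,
)

# one fixed suite seed; derived seeds stay below 2**31
SUITE_SEED = 7


@pytest.fixture(scope="session")
def tiny_gt():
    """Small planted ground truth: 216 voxels, 12 atoms, canonical designs."""
    return make_ground_truth(grid_shape=(6, 6, 6), t=176, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_gt):
    """Three noisy subjects over the seven tasks, unequal lengths."""
    return synthesize_dataset(tiny_gt, n_subjects=3, seed=SUITE_SEED + 1)


@pytest.fixture(scope="session")
def desk_config():
    return desk_scale_config(
        seed=SUITE_SEED, analyses=("features", "categories", "roa")
    )


@pytest.fixture(scope="session")
def desk_dataset(desk_config):
    return simulate_dataset(desk_config)


@pytest.fixture(scope="session")
def desk_run(desk_config, desk_dataset):
    """One full split/fit/transform/classify/analyze pass, model kept."""
    return run_repeat(desk_dataset, desk_config, repeat=0, keep_model=True)


@pytest.fixture(scope="session")
def desk_sampling(desk_config, desk_dataset, desk_run):
    return sample_voxels(
        desk_dataset.mask, desk_config.voxel_fraction, desk_run.sampling_seed
    )


@pytest.fixture(scope="session")
def desk_samples(desk_dataset, desk_run, desk_sampling):
    """Train/test classification samples rebuilt from the fitted model."""
    from htssr import build_samples, group_matrix_from_dataset

    model = desk_run.model
    S1_test = group_matrix_from_dataset(
        desk_dataset, desk_run.test_subjects, desk_sampling
    )
    codes = model.transform(S1_test)
    train = build_samples(model.ssr.alpha2, model.ssr.index)
    test = build_samples(codes.alpha2, codes.index2)
    return train, test


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
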