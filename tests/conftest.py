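"""Shared fixtures: synthetic pools generated once per session."""

import dataclasses

import numpy as np
import pytest

from patchal.pooldata import ImageCache
from patchal.synthdata import SynthConfig, generate_patch_pool


@pytest.fixture(scope="session")
def mini_pool(tmp_path_factory):
    """Small 64 px pool (600 patches) for loop-level tests."""
    d = tmp_path_factory.mktemp("mini_pool")
    cfg = SynthConfig(n_patches=600, patch_size=64, seed=7)
    pool, truth = generate_patch_pool(cfg, d)
    return pool, truth, ImageCache(pool)


@pytest.fixture(scope="session")
def desk_pool(tmp_path_factory):
    """Desk-scale benchmark pool: 4000 patches, 64 px, 8 styles, 16% positive."""
    d = tmp_path_factory.mktemp("desk_pool")
    cfg = SynthConfig(n_patches=4000, patch_size=64, n_styles=8, seed=101)
    pool, truth = generate_patch_pool(cfg, d)
    return pool, truth, ImageCache(pool)


@pytest.fixture(scope="session")
def test_set(tmp_path_factory):
    """Held-out labeled test set (600 patches) as arrays."""
    d = tmp_path_factory.mktemp("test_set")
    cfg = SynthConfig(n_patches=600, patch_size=64, n_styles=8, seed=909)
    pool, truth = generate_patch_pool(cfg, d)
    cache = ImageCache(pool)
    ids = sorted(pool.U)
    X = cache.batch(ids)
    y = np.array([truth.label[i] for i in ids])
    return X, y


@pytest.fixture(scope="session")
def styled_pool_240(tmp_path_factory):
    """Full-resolution (240 px) pool for style/appearance checks."""
    d = tmp_path_factory.mktemp("styled_pool")
    cfg = SynthConfig(n_patches=160, patch_size=240, n_styles=8, seed=11)
    pool, truth = generate_patch_pool(cfg, d)
    return pool, truth, ImageCache(pool)
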