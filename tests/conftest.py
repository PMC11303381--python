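"""Shared fixtures.

The expensive fixtures (trained desk-scale models) are session-scoped so the
denoising, robustness and tiling tests share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from cnnt import (CNNTConfig, NoiseConfig, SceneConfig, make_paired_dataset)
from cnnt.training import TrainConfig, train_backbone


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Smallest architecturally complete config (fast unit tests)."""
    return CNNTConfig(in_channels=1, base_channels=4, n_levels_down=1,
                      n_levels_up=1, cells_per_block=1, n_heads=1)


def desk_scene(structure: str = "filaments") -> SceneConfig:
    return SceneConfig(structure=structure, volume_shape=(8, 64, 64), n_objects=12)


def desk_noise() -> NoiseConfig:
    return NoiseConfig(photons_high=200.0, exposure_ratio=0.25, read_sigma=2.0)


DESK_MODEL = CNNTConfig(in_channels=1, base_channels=8, n_levels_down=2,
                        n_levels_up=2, cells_per_block=2, n_heads=2)


@pytest.fixture(scope="session")
def desk_trained():
    """A small CNNT trained ~300 steps on synthetic filament pairs.

    Returns (checkpoint, held_out_pairs, scene_cfg, noise_cfg).  16 training
    pairs of 8x64x64 at exposure ratio 0.25; 19 epochs with batch size 1 is
    304 optimizer steps.
    """
    scene, noise = desk_scene(), desk_noise()
    pairs = make_paired_dataset(scene, noise, 20, master_seed=42)
    train_pairs, held = pairs[:16], pairs[16:]
    tc = TrainConfig(regime="backbone", epochs=19, batch_size=1,
                     cutout_shapes=((8, 64, 64),), seed=0)
    ckpt = train_backbone(train_pairs, DESK_MODEL, tc)
    return ckpt, held, scene, noise
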