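"""Cutout sampling, epoch bookkeeping, scheduler behaviour, checkpointing."""

from __future__ import annotations

import numpy as np
import pytest

from cnnt import nn
from cnnt.data_io import NormalizationSpec
from cnnt.model import CNNTConfig, CNNTUnet
from cnnt.nn import AdamW, ReduceLROnPlateau
from cnnt.synthetic import NoiseConfig, SceneConfig, make_paired_dataset
from cnnt.training import (Checkpoint, CheckpointError, TrainConfig,
                           TrainingError, build_model, finetune,
                           load_checkpoint, sample_cutout, save_checkpoint,
                           train_backbone, train_epoch)

TINY = CNNTConfig(in_channels=1, base_channels=4, n_levels_down=1,
                  n_levels_up=1, cells_per_block=1, n_heads=1)


def _pairs(n=4, shape=(4, 24, 24), seed=0):
    scene = SceneConfig(volume_shape=shape, n_objects=4)
    noise = NoiseConfig(photons_high=200, exposure_ratio=0.25)
    return make_paired_dataset(scene, noise, n, master_seed=seed)


def _tc(**kw):
    kw.setdefault("regime", "backbone")
    kw.setdefault("epochs", 2)
    kw.setdefault("batch_size", 2)
    kw.setdefault("cutout_shapes", ((4, 16, 16),))
    return TrainConfig(**kw)


# ------------------------------------------------------------------ cutouts

def test_cutout_shared_offset_and_shape(rng):
    pair = _pairs(1, shape=(8, 64, 64))[0]
    cut = sample_cutout(pair, (4, 16, 16), rng)
    assert cut.low.shape == cut.high.shape == (4, 16, 16)
    # the low/high crops must come from the same offset: locate the low crop
    # and verify the high volume matches at the same place
    found = False
    for z in range(5):
        for y in range(49):
            for x in range(49):
                if np.array_equal(pair.low.voxels[z:z + 4, y:y + 16, x:x + 16],
                                  cut.low.voxels):
                    found = True
                    assert np.array_equal(
                        pair.high.voxels[z:z + 4, y:y + 16, x:x + 16],
                        cut.high.voxels)
    assert found


def test_cutout_exact_size_is_identity(rng):
    pair = _pairs(1, shape=(4, 16, 16))[0]
    cut = sample_cutout(pair, (4, 16, 16), rng)
    assert np.array_equal(cut.low.voxels, pair.low.voxels)


def test_cutout_pads_small_volumes(rng):
    pair = _pairs(1, shape=(2, 8, 8))[0]
    cut = sample_cutout(pair, (4, 16, 16), rng)
    assert cut.low.shape == (4, 16, 16)


def test_cutout_deterministic_sequence():
    pair = _pairs(1, shape=(8, 32, 32))[0]
    a = [sample_cutout(pair, (4, 16, 16), np.random.default_rng(3)).low.voxels
         for _ in range(1)]
    b = [sample_cutout(pair, (4, 16, 16), np.random.default_rng(3)).low.voxels
         for _ in range(1)]
    assert np.array_equal(a[0], b[0])


# ------------------------------------------------------------------ epochs

def test_one_step_per_batch_and_finite_loss():
    pairs = _pairs(10)
    model = CNNTUnet(TINY, rng=0)
    opt = AdamW(model.parameters(), lr=1e-4)
    loss = train_epoch(model, pairs, _tc(batch_size=2), np.random.default_rng(0), opt)
    assert opt.t == 5          # 10 pairs / batch 2 -> 5 optimizer steps
    assert np.isfinite(loss) and loss <= 2.0


def test_empty_dataset_rejected():
    model = CNNTUnet(TINY, rng=0)
    with pytest.raises(TrainingError):
        train_epoch(model, [], _tc(), np.random.default_rng(0))


def test_seeded_histories_reproduce():
    pairs = _pairs(4)
    cfgs = dict(epochs=2, batch_size=2, seed=5)
    h1 = train_backbone(pairs, TINY, _tc(**cfgs)).history
    h2 = train_backbone(pairs, TINY, _tc(**cfgs)).history
    assert h1 == h2


def test_training_reduces_loss():
    pairs = _pairs(6)
    ckpt = train_backbone(pairs, TINY, _tc(epochs=8, batch_size=2, seed=1))
    assert min(ckpt.history) < ckpt.history[0]
    assert len(ckpt.history) == 8


def test_regime_mismatch_rejected():
    pairs = _pairs(2)
    with pytest.raises(TrainingError):
        train_backbone(pairs, TINY, _tc(regime="finetune"))


# ------------------------------------------------------------------ scheduler

def test_scheduler_decays_lr_after_patience():
    opt = AdamW([], lr=1.0)
    sched = ReduceLROnPlateau(opt, factor=0.8, patience=3)
    sched.step(1.0)            # establishes the best
    for _ in range(3):         # three non-improving epochs
        sched.step(1.0)
    assert opt.lr == pytest.approx(0.8)
    sched.step(0.5)            # improvement resets the counter
    sched.step(0.6)
    assert opt.lr == pytest.approx(0.8)


def test_scheduler_respects_min_lr():
    opt = AdamW([], lr=1e-6)
    sched = ReduceLROnPlateau(opt, factor=0.8, patience=1, min_lr=1e-6)
    for _ in range(5):
        sched.step(1.0)
    assert opt.lr == pytest.approx(1e-6)


# ------------------------------------------------------------------ finetune

def test_finetune_defaults_and_zero_epochs():
    pairs = _pairs(5)
    base = train_backbone(pairs, TINY, _tc(epochs=1, seed=2))
    ft_cfg = TrainConfig(regime="finetune", epochs=0,
                         cutout_shapes=((4, 16, 16),))
    same = finetune(base, pairs, ft_cfg)
    for k in base.state:
        assert np.array_equal(same.state[k], base.state[k])
    # per-regime defaults
    assert TrainConfig(regime="finetune").epochs == 30
    assert TrainConfig(regime="finetune").lr == pytest.approx(2.5e-5)
    assert TrainConfig(regime="backbone").epochs == 300
    assert TrainConfig(regime="backbone").lr == pytest.approx(1e-4)


def test_finetune_accepts_five_pairs_and_trains():
    pairs = _pairs(5)
    base = train_backbone(pairs, TINY, _tc(epochs=1, seed=3))
    ft = finetune(base, pairs, TrainConfig(regime="finetune", epochs=2,
                                           batch_size=5,
                                           cutout_shapes=((4, 16, 16),)))
    assert len(ft.history) == 2


# ------------------------------------------------------------------ checkpoints

def _forward_probe(ckpt: Checkpoint, x: np.ndarray) -> np.ndarray:
    model = build_model(ckpt)
    with nn.no_grad():
        return model(nn.Tensor(x)).data


def test_checkpoint_round_trip_bit_identical(tmp_path, rng):
    pairs = _pairs(2)
    ckpt = train_backbone(pairs, TINY, _tc(epochs=1, seed=4))
    x = rng.normal(size=(1, 2, 1, 16, 16)).astype(np.float32)
    before = _forward_probe(ckpt, x)
    path = save_checkpoint(ckpt, tmp_path / "m.npz")
    loaded = load_checkpoint(path)
    after = _forward_probe(loaded, x)
    assert np.array_equal(before, after)
    assert loaded.history == ckpt.history
    assert len(loaded.history) == loaded.epoch == 1
    assert loaded.train_config == ckpt.train_config
    assert loaded.normalization == ckpt.normalization


def test_checkpoint_config_mismatch(tmp_path):
    ckpt = train_backbone(_pairs(2), TINY, _tc(epochs=1))
    path = save_checkpoint(ckpt, tmp_path / "m.npz")
    other = CNNTConfig(in_channels=1, base_channels=8, n_levels_down=1,
                       n_levels_up=1, cells_per_block=1, n_heads=1)
    with pytest.raises(CheckpointError):
        load_checkpoint(path, expect_config=other)


def test_checkpoint_corrupt_file(tmp_path):
    bad = tmp_path / "bad.npz"
    bad.write_bytes(b"garbage")
    with pytest.raises(CheckpointError):
        load_checkpoint(bad)


def test_normalization_used_in_training_is_recorded():
    spec = NormalizationSpec(method="minmax")
    ckpt = train_backbone(_pairs(2), TINY, _tc(epochs=1), normalization=spec)
    assert ckpt.normalization == spec
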