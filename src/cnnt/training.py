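"""Backbone training and fast fine-tuning.

The training scheme is two-stage: a general backbone is trained once on a
pooled, diverse paired dataset (300 epochs by default), then adapted to each
new experiment by briefly fine-tuning the whole model — no layer freezing —
on 5–20 new pairs (30 epochs, 4x smaller learning rate).  Both stages
minimise the SSIM loss on random cutouts: each epoch visits exactly one
random cutout of every pair in the dataset, cutout shapes drawn per pair
from the configured list (defaults 8x128x128 and 8x160x160), and cutouts of
equal shape are batched together.

Optimisation is AdamW (betas 0.90/0.95) with reduce-on-plateau learning-rate
decay (factor 0.8) monitored on the epoch training loss, and global-norm
gradient clipping as a guard against SSIM spikes on near-constant cutouts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import nn
from .data_io import ImageVolume, NormalizationSpec, VolumePair, normalize_volume
from .metrics import SSIMParams, ssim_loss
from .model import CNNTConfig, CNNTUnet

__all__ = ["TrainConfig", "Checkpoint", "TrainingError", "CheckpointError",
           "sample_cutout", "train_epoch", "train_backbone", "finetune",
           "save_checkpoint", "load_checkpoint", "build_model"]

CHECKPOINT_VERSION = 1


class TrainingError(RuntimeError):
    pass


class CheckpointError(ValueError):
    pass


@dataclasses.dataclass
class TrainConfig:
    """Loss/optimizer/scheduler/cutout settings for one training regime.

    ``epochs`` and ``lr`` default per regime: 300 epochs at 1e-4 for the
    backbone, 30 epochs at 2.5e-5 for fine-tuning.
    """

    regime: Literal["backbone", "finetune"] = "backbone"
    epochs: int | None = None
    lr: float | None = None
    betas: tuple[float, float] = (0.90, 0.95)
    scheduler_decay: float = 0.8
    scheduler_patience: int = 5
    min_lr: float = 1e-6
    weight_decay: float = 0.01
    clip_grad_norm: float | None = 1.0
    cutout_shapes: tuple[tuple[int, int, int], ...] = ((8, 128, 128), (8, 160, 160))
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("backbone", "finetune"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.epochs is None:
            self.epochs = 300 if self.regime == "backbone" else 30
        if self.lr is None:
            self.lr = 1e-4 if self.regime == "backbone" else 2.5e-5
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 < self.scheduler_decay < 1.0:
            raise ValueError("scheduler_decay must be in (0, 1)")
        self.cutout_shapes = tuple(tuple(s) for s in self.cutout_shapes)
        if not self.cutout_shapes:
            raise ValueError("need at least one cutout shape")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["betas"] = list(self.betas)
        d["cutout_shapes"] = [list(s) for s in self.cutout_shapes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["betas"] = tuple(d["betas"])
        d["cutout_shapes"] = tuple(tuple(s) for s in d["cutout_shapes"])
        return cls(**d)


@dataclasses.dataclass
class Checkpoint:
    """Everything needed to resume or deploy a model: weights plus the
    architecture, training and normalisation configuration, and the per-epoch
    loss history."""

    state: dict
    cnnt_config: CNNTConfig
    train_config: TrainConfig
    normalization: NormalizationSpec
    epoch: int
    history: list[float]


def build_model(ckpt: Checkpoint) -> CNNTUnet:
    """Instantiate the network a checkpoint describes and load its weights."""
    model = CNNTUnet(ckpt.cnnt_config, rng=0)
    model.load_state_dict(ckpt.state)
    return model


# ----------------------------------------------------------------------
# cutouts and batches

def _reflect_pad_to(v: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    pads = []
    for cur, want in zip(v.shape, shape):
        deficit = max(0, want - cur)
        pads.append((deficit // 2, deficit - deficit // 2))
    if any(p != (0, 0) for p in pads):
        v = np.pad(v, pads, mode="reflect")
    return v


def sample_cutout(pair: VolumePair, shape: tuple[int, int, int],
                  rng: np.random.Generator) -> VolumePair:
    """Random cutout of ``shape`` at one offset shared by low and high.

    Offsets are uniform over all valid positions, so the pair stays
    registered.  Volumes smaller than the cutout in any axis are
    reflect-padded first (never silently truncated).
    """
    low = _reflect_pad_to(pair.low.voxels, shape)
    high = _reflect_pad_to(pair.high.voxels, shape)
    offsets = tuple(int(rng.integers(0, cur - want + 1))
                    for cur, want in zip(low.shape, shape))
    sl = tuple(slice(o, o + want) for o, want in zip(offsets, shape))
    return VolumePair(
        low=ImageVolume(low[sl], pair.low.axis_kind),
        high=ImageVolume(high[sl], pair.high.axis_kind))


def _normalized_pairs(pairs: Sequence[VolumePair],
                      spec: NormalizationSpec) -> list[VolumePair]:
    out = []
    for p in pairs:
        lo, _ = normalize_volume(p.low, spec)
        hi, _ = normalize_volume(p.high, spec)
        out.append(VolumePair(low=lo, high=hi))
    return out


def train_epoch(model: CNNTUnet, pairs: Sequence[VolumePair], cfg: TrainConfig,
                rng: np.random.Generator, optimizer: nn.AdamW | None = None,
                ssim_params: SSIMParams | None = None) -> float:
    """One epoch: one random cutout per pair, same-shape cutouts batched,
    one AdamW step per batch on the SSIM loss.  Returns the mean loss.

    ``pairs`` are assumed already intensity-normalised.
    """
    if not pairs:
        raise TrainingError("empty dataset")
    if optimizer is None:
        optimizer = nn.AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                             weight_decay=cfg.weight_decay)
    ssim_params = ssim_params or SSIMParams()
    order = rng.permutation(len(pairs))
    by_shape: dict[tuple, list[VolumePair]] = {}
    for idx in order:
        shape = cfg.cutout_shapes[int(rng.integers(0, len(cfg.cutout_shapes)))]
        by_shape.setdefault(shape, []).append(sample_cutout(pairs[idx], shape, rng))
    total, count = 0.0, 0
    for shape, cuts in by_shape.items():
        for start in range(0, len(cuts), cfg.batch_size):
            chunk = cuts[start:start + cfg.batch_size]
            x = np.stack([c.low.voxels for c in chunk])[:, :, None]   # [B,T,1,H,W]
            y = np.stack([c.high.voxels for c in chunk])[:, :, None]
            pred = model(nn.Tensor(x.astype(np.float32)))
            loss = ssim_loss(pred, nn.Tensor(y.astype(np.float32)), ssim_params)
            val = loss.item()
            if not np.isfinite(val):
                raise TrainingError(
                    f"non-finite loss {val} in batch of shape {shape} "
                    f"starting at cutout {start}")
            optimizer.zero_grad()
            loss.backward()
            if cfg.clip_grad_norm:
                nn.clip_grad_norm(model.parameters(), cfg.clip_grad_norm)
            optimizer.step()
            total += val * len(chunk)
            count += len(chunk)
    return total / count


def _fit(model: CNNTUnet, pairs: Sequence[VolumePair], cfg: TrainConfig,
         normalization: NormalizationSpec, ssim_params: SSIMParams | None,
         verbose: bool) -> Checkpoint:
    norm_pairs = _normalized_pairs(pairs, normalization)
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                         weight_decay=cfg.weight_decay)
    scheduler = nn.ReduceLROnPlateau(optimizer, factor=cfg.scheduler_decay,
                                     patience=cfg.scheduler_patience,
                                     min_lr=cfg.min_lr)
    history: list[float] = []
    best_loss = np.inf
    best_state = model.state_dict()
    for epoch in range(cfg.epochs):
        loss = train_epoch(model, norm_pairs, cfg, rng, optimizer, ssim_params)
        history.append(loss)
        scheduler.step(loss)
        if loss < best_loss:
            best_loss = loss
            best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}: ssim_loss={loss:.5f} "
                  f"lr={optimizer.lr:.2e}")
    model.load_state_dict(best_state)
    return Checkpoint(state=best_state, cnnt_config=model.cfg, train_config=cfg,
                      normalization=normalization, epoch=len(history),
                      history=history)


def train_backbone(pairs: Sequence[VolumePair], cnnt_cfg: CNNTConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   normalization: NormalizationSpec | None = None,
                   ssim_params: SSIMParams | None = None,
                   verbose: bool = False) -> Checkpoint:
    """Train a general backbone from scratch on a pooled paired dataset.

    Keeps the best-loss weights; the returned checkpoint records the full
    per-epoch loss history.
    """
    cnnt_cfg = cnnt_cfg or CNNTConfig()
    train_cfg = train_cfg or TrainConfig(regime="backbone")
    if train_cfg.regime != "backbone":
        raise TrainingError("train_backbone requires regime='backbone'")
    normalization = normalization or NormalizationSpec()
    model = CNNTUnet(cnnt_cfg, rng=np.random.default_rng(train_cfg.seed))
    return _fit(model, pairs, train_cfg, normalization, ssim_params, verbose)


def finetune(base: Checkpoint, pairs: Sequence[VolumePair],
             train_cfg: TrainConfig | None = None,
             ssim_params: SSIMParams | None = None,
             verbose: bool = False) -> Checkpoint:
    """Adapt a trained backbone to a new experiment on a handful of pairs.

    All weights stay trainable; only the learning rate and epoch budget
    shrink.  Zero epochs returns the base weights unchanged.
    """
    train_cfg = train_cfg or TrainConfig(regime="finetune")
    if train_cfg.regime != "finetune":
        raise TrainingError("finetune requires regime='finetune'")
    model = build_model(base)
    if train_cfg.epochs == 0:
        return Checkpoint(state=model.state_dict(), cnnt_config=base.cnnt_config,
                          train_config=train_cfg, normalization=base.normalization,
                          epoch=0, history=[])
    return _fit(model, pairs, train_cfg, base.normalization, ssim_params, verbose)


# ----------------------------------------------------------------------
# checkpoint files

def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> Path:
    """Write weights + configuration to a single ``.npz`` checkpoint file."""
    path = Path(path)
    if path.suffix != ".npz":   # np.savez would silently append it
        path = path.with_suffix(path.suffix + ".npz")
    meta = {
        "version": CHECKPOINT_VERSION,
        "param_names": list(ckpt.state.keys()),
        "cnnt_config": ckpt.cnnt_config.to_dict(),
        "train_config": ckpt.train_config.to_dict(),
        "normalization": dataclasses.asdict(ckpt.normalization),
        "epoch": ckpt.epoch,
        "history": list(map(float, ckpt.history)),
    }
    arrays = {f"param_{i}": arr for i, arr in enumerate(ckpt.state.values())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_checkpoint(path: str | Path,
                    expect_config: CNNTConfig | None = None) -> Checkpoint:
    """Read a checkpoint; optionally fail if its architecture differs from
    ``expect_config``."""
    path = Path(path)
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"unsupported checkpoint version {meta.get('version')!r} "
                    f"(expected {CHECKPOINT_VERSION})")
            state = {name: data[f"param_{i}"]
                     for i, name in enumerate(meta["param_names"])}
    except (KeyError, ValueError, json.JSONDecodeError, OSError) as exc:
        if isinstance(exc, CheckpointError):
            raise
        raise CheckpointError(f"corrupt or incompatible checkpoint {path}: {exc}")
    cfg = CNNTConfig.from_dict(meta["cnnt_config"])
    if expect_config is not None and cfg != expect_config:
        raise CheckpointError(
            f"checkpoint architecture {cfg} does not match expected {expect_config}")
    return Checkpoint(
        state=state,
        cnnt_config=cfg,
        train_config=TrainConfig.from_dict(meta["train_config"]),
        normalization=NormalizationSpec(**meta["normalization"]),
        epoch=int(meta["epoch"]),
        history=[float(x) for x in meta["history"]],
    )
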