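"""Training and evaluation loops.

The recipe: Adam (first-moment decay 0.9) minimising the soft Dice loss,
batch size 4, learning rate cosine-annealed per epoch from 1e-4 down to
1e-7, seed 2024, with flip/rotation augmentation.  Validation follows the
grouped protocol: per-image metrics are averaged in ordered groups of ten
and the group means are averaged.  Runs are bit-reproducible for a fixed
seed (weight init, shuffling and augmentation all derive from it).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .autodiff import Tensor, no_grad
from .data_pipeline import SegSample, augment, to_model_input
from .losses_metrics import MetricsReport, dice_loss, image_metrics, overlay
from .model import BFNet, ModelConfig, build_model


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 4
    lr_max: float = 1e-4
    lr_min: float = 1e-7
    beta1: float = 0.9  # "momentum" of the adaptive optimizer
    beta2: float = 0.999
    seed: int = 2024
    augment: bool = True
    max_angle: float = 15.0
    group_size: int = 10

    def __post_init__(self):
        if not (self.lr_max > self.lr_min > 0):
            raise ValueError("need lr_max > lr_min > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def cosine_lr(epoch: int, epochs: int, lr_max: float, lr_min: float) -> float:
    """Half-cosine decay; exactly lr_max at epoch 0 and lr_min at the last."""
    if epochs == 1:
        return lr_max
    t = epoch / (epochs - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t))


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _batch_arrays(samples: list[SegSample]):
    x = np.stack([to_model_input(s) for s in samples])
    t = np.stack([s.mask for s in samples])[:, None].astype(np.float32)
    return x, t


def train_step(model: BFNet, opt: Adam, x: np.ndarray, t: np.ndarray) -> float:
    """One optimisation step on a prepared batch; returns the batch loss."""
    opt.zero_grad()
    loss = dice_loss(model(Tensor(x)), t)
    value = loss.item()
    if not np.isfinite(value):
        raise TrainingDiverged(f"non-finite Dice loss at step {opt.t + 1}: {value}")
    loss.backward()
    opt.step()
    return value


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    train_samples: list[SegSample],
    val_samples: list[SegSample] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[BFNet, dict]:
    """Train a model; returns (model-with-best-weights, history).

    History records per-epoch learning rate, mean train loss and (when a
    validation split is given) the grouped-mean validation Dice; the
    best-Dice weights are restored at the end and checkpointed if
    ``out_dir`` is given.
    """
    if not train_samples:
        raise ValueError("empty training corpus")
    model = build_model(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), train_cfg.lr_max, train_cfg.beta1, train_cfg.beta2)
    rng = np.random.default_rng(train_cfg.seed)
    history: dict = {"lr": [], "train_loss": [], "val_dice": []}
    best = (-1.0, None)
    n = len(train_samples)
    for epoch in range(train_cfg.epochs):
        opt.lr = cosine_lr(epoch, train_cfg.epochs, train_cfg.lr_max, train_cfg.lr_min)
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            batch = [train_samples[i] for i in order[start : start + train_cfg.batch_size]]
            if train_cfg.augment:
                batch = [augment(s, rng, train_cfg.max_angle) for s in batch]
            x, t = _batch_arrays(batch)
            losses.append(train_step(model, opt, x, t))
        history["lr"].append(opt.lr)
        history["train_loss"].append(float(np.mean(losses)))
        if val_samples:
            report = evaluate(model, val_samples, group_size=train_cfg.group_size)
            history["val_dice"].append(report.dice)
            if report.dice > best[0]:
                best = (report.dice, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
        history["best_val_dice"] = best[0]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out / "checkpoint.npz", model)
        (out / "history.json").write_text(json.dumps(history, indent=2))
    return model, history


def evaluate(
    model: BFNet,
    samples: list[SegSample],
    group_size: int = 10,
    batch_size: int = 8,
    overlay_dir: str | Path | None = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Per-image metrics with grouped-mean aggregation."""
    if not samples:
        raise ValueError("empty evaluation corpus")
    model.eval()
    per_image = []
    for start in range(0, len(samples), batch_size):
        batch = samples[start : start + batch_size]
        x, _ = _batch_arrays(batch)
        with no_grad():
            probs = model(Tensor(x)).data[:, 0]
        for s, prob in zip(batch, probs):
            pred = (prob >= threshold).astype(np.uint8)
            m = {"id": s.id} | image_metrics(pred, s.mask)
            per_image.append(m)
            if overlay_dir is not None:
                Path(overlay_dir).mkdir(parents=True, exist_ok=True)
                Image.fromarray(overlay(pred, s.mask, s.image)).save(
                    Path(overlay_dir) / f"{s.id}_overlay.png"
                )
    return MetricsReport.from_per_image(per_image, group_size)


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(path, model: BFNet) -> None:
    """Single-file checkpoint: weights + embedded model config."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8
    )
    buf = io.BytesIO()
    np.savez(buf, **state)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path) -> BFNet:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = build_model(cfg, seed=0)
    model.load_state_dict(state)
    return model
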