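"""Training, evaluation and ablation of the network on phantom datasets.

The protocol follows the study setup: Adam, global learning rate 1e-4,
weight decay 5e-2, 10 epochs, cross-entropy over the two logits.  A desk
preset (128-px input, window 4, channel plan 24/48/96/192, batch 8) keeps
every architectural mechanism while training in minutes on a single CPU.

25% of the train/validation pool is carved out as a stratified, seeded
validation set; the checkpoint with the best validation accuracy is kept
alongside the final weights.  Runs are fully reproducible given the seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Parameter, Tensor, log_softmax
from .metrics import MetricsReport, confusion, report
from .network import (BiNet, NetworkConfig, build_variant, desk_config,
                      save_checkpoint, VARIANTS)
from .phantom import load_split


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 10
    weight_decay: float = 5e-2
    batch_size: int = 8
    input_size: int = 224
    seed: int = 0
    variant: str = "binet"
    feedback_passes: int = 1
    val_fraction: float = 0.25
    desk: bool = False

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def network_config(self) -> NetworkConfig:
        kw = dict(input_size=self.input_size, variant=self.variant,
                  feedback_passes=self.feedback_passes)
        return desk_config(**kw) if self.desk else NetworkConfig(**kw)


def desk_train_config(**overrides) -> TrainConfig:
    base = dict(input_size=128, batch_size=8, desk=True)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class RunRecord:
    """Per-epoch curves, the final test report and the config snapshot."""
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    best_epoch: int = -1
    test_report: MetricsReport | None = None
    config: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(epoch=np.arange(1, len(self.train_loss) + 1),
                                 train_loss=self.train_loss, train_acc=self.train_acc,
                                 val_loss=self.val_loss, val_acc=self.val_acc))


class Adam:
    """Adam with the L2 term added to the gradient (classic convention)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch of integer labels."""
    logp = log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape, dtype=logits.data.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    return (logp * onehot).sum() * (-1.0 / len(labels))


def predict(model: BiNet, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Argmax class per image (fatty = 1)."""
    preds = []
    for i in range(0, len(images), batch_size):
        logits = model(Tensor(images[i:i + batch_size])).logits.data
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def _eval_arrays(model: BiNet, X: np.ndarray, y: np.ndarray,
                 batch_size: int = 16) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        logits = model(Tensor(X[i:i + batch_size])).logits
        losses.append(float(cross_entropy(logits, y[i:i + batch_size]).data)
                      * (len(X[i:i + batch_size])))
        correct += int(np.sum(np.argmax(logits.data, axis=1) == y[i:i + batch_size]))
    return sum(losses) / len(X), correct / len(X)


def _stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    val_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = max(1, int(round(frac * len(idx))))
        val_idx.extend(idx[:k])
    val = np.zeros(len(y), dtype=bool)
    val[val_idx] = True
    return ~val, val


def train(cfg: TrainConfig, manifest: pd.DataFrame,
          root: str | Path | None = None,
          checkpoint_dir: str | Path | None = None,
          model: BiNet | None = None) -> tuple[RunRecord, BiNet, dict]:
    """Train a network on the manifest's trainval pool.

    Returns (record, model-with-final-weights, best-validation state dict).
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    net_cfg = cfg.network_config()
    if model is None:
        model = build_variant(cfg.variant, net_cfg, rng=rng)

    X, y = load_split(manifest, "trainval", cfg.input_size, root=root)
    train_m, val_m = _stratified_split(y, cfg.val_fraction, rng)
    Xtr, ytr = X[train_m], y[train_m]
    Xval, yval = X[val_m], y[val_m]
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ValueError("empty train or validation split")

    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    record = RunRecord(config=asdict(cfg))
    best_acc, best_state = -1.0, model.state_dict()

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        losses, correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model(Tensor(Xtr[idx])).logits
            loss = cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, step {i // cfg.batch_size}")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            correct += int(np.sum(np.argmax(logits.data, axis=1) == ytr[idx]))
        record.train_loss.append(sum(losses) / len(order))
        record.train_acc.append(correct / len(order))

        vloss, vacc = _eval_arrays(model, Xval, yval, cfg.batch_size)
        record.val_loss.append(vloss)
        record.val_acc.append(vacc)
        if vacc > best_acc:
            best_acc, best_state = vacc, model.state_dict()
            record.best_epoch = epoch + 1

    record.wall_clock_s = time.perf_counter() - t0
    if checkpoint_dir is not None:
        ckpt = Path(checkpoint_dir)
        ckpt.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, ckpt / "final.npz")
        final_state = model.state_dict()
        model.load_state_dict(best_state)
        save_checkpoint(model, ckpt / "best.npz")
        model.load_state_dict(final_state)
    return record, model, best_state


def evaluate(model: BiNet, manifest: pd.DataFrame, split: str,
             input_size: int | None = None,
             root: str | Path | None = None) -> MetricsReport:
    """Argmax evaluation of a trained model on one manifest split."""
    size = input_size or model.cfg.input_size
    X, y = load_split(manifest, split, size, root=root)
    preds = predict(model, X)
    return report(confusion(preds, y, positive_label=1))


def ablate(manifest: pd.DataFrame, cfg: TrainConfig,
           root: str | Path | None = None,
           variants: tuple[str, ...] = VARIANTS) -> pd.DataFrame:
    """Train and test every architecture variant under one seed/config."""
    rows = []
    for name in variants:
        vcfg = TrainConfig(**{**asdict(cfg), "variant": name})
        record, model, best_state = train(vcfg, manifest, root=root)
        final_state = model.state_dict()
        model.load_state_dict(best_state)
        test = evaluate(model, manifest, "test", cfg.input_size, root=root)
        model.load_state_dict(final_state)
        rows.append(dict(
            variant=name,
            parameters=model.num_parameters(),
            accuracy_val=max(record.val_acc),
            accuracy_test=test.accuracy,
            sensitivity=test.sensitivity,
            specificity=test.specificity,
            f1=test.f1))
    return pd.DataFrame(rows)
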