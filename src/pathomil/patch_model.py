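"""Weakly-supervised patch-level survival classifier.

Every patch of a slide inherits the patient's 5-year survival status as a
weak label (positive class = death within 5 years). A small CNN is trained
with softmax cross-entropy and mini-batch SGD (momentum 0.9) under two
cosine-annealing learning-rate schedules:

* the classifier head follows ``eta_min + (eta_max - eta_min)/2 * (1 +
  cos(pi * t/T_i))`` from epoch 0;
* the backbone stays frozen (rate 0) for the first half of training and
  joins the same cosine schedule afterwards — the standard fine-tuning
  recipe when starting from transferred weights.

After training, each patch receives a positive-class probability; the
per-slide vector of these likelihoods is the multi-instance bag consumed
by the MIL encoders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RGBPatch, SlideLikelihoods
from .nn import SmallConvNet

__all__ = [
    "LRScheduleConfig",
    "TrainConfig",
    "PatchClassifier",
    "cosine_lr",
    "backbone_lr",
    "assign_weak_labels",
    "train_patch_classifier",
    "infer_slide_likelihoods",
    "save_checkpoint",
    "load_checkpoint",
]

EXCLUDED = "excluded"


@dataclass(frozen=True)
class LRScheduleConfig:
    """Cosine-annealing schedule parameters (rates per epoch)."""

    eta_min: float = 0.0
    eta_max: float = 0.01
    t_i: int = 30

    def __post_init__(self) -> None:
        if not 0 <= self.eta_min <= self.eta_max:
            raise ValueError("require 0 <= eta_min <= eta_max")
        if self.t_i < 1:
            raise ValueError("t_i must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch SGD configuration for patch training."""

    batch_size: int = 32
    momentum: float = 0.9
    seed: int = 0
    channels: tuple[int, ...] = (8, 16, 32, 32)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")


def cosine_lr(t_cur: float, cfg: LRScheduleConfig) -> float:
    """Cosine-annealed learning rate at epoch ``t_cur``."""
    if not 0 <= t_cur <= cfg.t_i:
        raise ValueError(f"t_cur must lie in [0, {cfg.t_i}]")
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) * (1.0 + math.cos(math.pi * t_cur / cfg.t_i))


def backbone_lr(t_cur: float, cfg: LRScheduleConfig) -> float:
    """Backbone rate: 0 while frozen (t_cur <= T_i/2), cosine afterwards."""
    if not 0 <= t_cur <= cfg.t_i:
        raise ValueError(f"t_cur must lie in [0, {cfg.t_i}]")
    if t_cur <= cfg.t_i / 2:
        return 0.0
    return cosine_lr(t_cur, cfg)


def assign_weak_labels(cohort: pd.DataFrame, horizon_months: float = 60.0,
                       time_col: str = "time", event_col: str = "event",
                       id_col: str = "slide_id") -> dict[str, int | str]:
    """Slide-level 5-year-survival labels for weak supervision.

    Death on or before the horizon -> 1; follow-up past the horizon -> 0;
    censored before the horizon -> ``"excluded"`` (the label is undefined,
    so those slides are left out of patch training).
    """
    times = cohort[time_col].to_numpy(dtype=float)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    labels: dict[str, int | str] = {}
    for sid, t, e in zip(cohort[id_col], times, cohort[event_col].astype(int)):
        if t > horizon_months or (e == 0 and t == horizon_months):
            labels[str(sid)] = 0
        elif e == 1:
            labels[str(sid)] = 1
        else:
            labels[str(sid)] = EXCLUDED
    return labels


def _patch_tensor(patches: list[RGBPatch]) -> np.ndarray:
    x = np.stack([p.pixels for p in patches]).astype(float) / 255.0
    return (x - 0.5).transpose(0, 3, 1, 2)  # (N, 3, H, W), centered


class PatchClassifier:
    """Trained patch -> 2-class probability predictor.

    Wraps the CNN with patch preprocessing; exposes the last-convolution
    activations and their gradients for Grad-CAM.
    """

    def __init__(self, net: SmallConvNet, train_config: TrainConfig | None = None,
                 lr_config: LRScheduleConfig | None = None):
        self.net = net
        self.train_config = train_config
        self.lr_config = lr_config
        self.loss_history: list[float] = []

    def predict_proba(self, patches: list[RGBPatch], batch_size: int = 64) -> np.ndarray:
        if not patches:
            raise ValueError("empty patch list")
        probs = []
        for i in range(0, len(patches), batch_size):
            probs.append(self.net.predict_proba(_patch_tensor(patches[i : i + batch_size])))
        return np.vstack(probs)

    def class_activation_gradient(self, patch: RGBPatch, target_class: int):
        x = _patch_tensor([patch])
        return self.net.class_activation_gradient(x, target_class)

    def penultimate_features(self, patches: list[RGBPatch], batch_size: int = 64) -> np.ndarray:
        """Globally pooled last-conv activations (descriptor space)."""
        feats = []
        for i in range(0, len(patches), batch_size):
            self.net.forward(_patch_tensor(patches[i : i + batch_size]))
            feats.append(self.net.last_conv_activation.mean(axis=(2, 3)))
        return np.vstack(feats)


def train_patch_classifier(
    patches: list[RGBPatch],
    labels: np.ndarray,
    train_cfg: TrainConfig | None = None,
    lr_cfg: LRScheduleConfig | None = None,
) -> PatchClassifier:
    """Train the patch classifier under the two cosine LR schedules.

    ``labels`` must contain both classes; the loss trace is recorded per
    epoch and is bit-identical across runs with the same seed.
    """
    train_cfg = train_cfg or TrainConfig()
    lr_cfg = lr_cfg or LRScheduleConfig()
    if not patches:
        raise ValueError("no training patches")
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    if len(patches) < 2 * train_cfg.batch_size:
        raise ValueError(f"need >= {2 * train_cfg.batch_size} patches for batch size {train_cfg.batch_size}")
    x = _patch_tensor(patches)
    net = SmallConvNet(channels=train_cfg.channels, seed=train_cfg.seed)
    clf = PatchClassifier(net, train_cfg, lr_cfg)
    rng = np.random.default_rng(train_cfg.seed)
    n = x.shape[0]
    for epoch in range(lr_cfg.t_i):
        lr_head = cosine_lr(epoch, lr_cfg)
        lr_back = backbone_lr(epoch, lr_cfg)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n - train_cfg.batch_size + 1, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            loss, _ = net.loss_and_grad(x[idx], y[idx])
            net.sgd_step(lr_back, lr_head, train_cfg.momentum)
            epoch_loss += loss
            n_batches += 1
        clf.loss_history.append(epoch_loss / max(n_batches, 1))
    return clf


def infer_slide_likelihoods(model: PatchClassifier, patches: list[RGBPatch]) -> SlideLikelihoods:
    """Per-patch positive-class probabilities and argmax labels for one slide."""
    if not patches:
        raise ValueError("empty patch list")
    slide_ids = {p.slide_id for p in patches}
    if len(slide_ids) != 1:
        raise ValueError(f"patches span multiple slides: {sorted(slide_ids)}")
    proba = model.predict_proba(patches)
    return SlideLikelihoods(
        slide_id=patches[0].slide_id,
        probabilities=proba[:, 1],
        predicted_labels=proba.argmax(axis=1),
    )


def save_checkpoint(path: str | Path, model: PatchClassifier) -> None:
    state = model.net.state_dict()
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> PatchClassifier:
    with np.load(path) as data:
        channels = tuple(int(c) for c in data["channels"])
        net = SmallConvNet(channels=channels, n_classes=int(data["n_classes"]))
        net.load_state_dict({k: data[k] for k in data.files})
    return PatchClassifier(net)
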