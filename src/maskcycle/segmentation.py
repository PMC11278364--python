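"""U-Net segmenter training with the staged recipe.

Three phases share one training routine: a baseline model trained on the
raw composites, a model trained on the translated dataset, and a final
model fine-tuned on the translated data pooled with pseudo-labeled images.
All phases use SGD (lr 0.01, weight decay 0.001, momentum 0.95) with a step
schedule multiplying the rate by 0.1 every 5 epochs, binary cross-entropy
as the loss, and the validation Dice score to pick the epoch whose
parameters are returned.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor, no_grad
from .nn import autograd as ag
from .imgio import read_image, read_mask
from .manifest import DatasetManifest
from .metrics import dice, iou

_PROB_EPS = 1e-7


@dataclass(frozen=True)
class SegConfig:
    epochs: int = 45
    learning_rate: float = 0.01
    weight_decay: float = 0.001
    momentum: float = 0.95
    scheduler_step: int = 5
    scheduler_gamma: float = 0.1
    binarize_threshold: float = 0.5
    seed: int = 0
    batch_size: int = 4
    hflip_augment: bool = True

    def validate(self) -> None:
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must be in (0,1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass(frozen=True)
class UNetSpec:
    depth: int = 4
    base_channels: int = 64
    in_channels: int = 3
    out_channels: int = 1

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)  # train_loss, val_dice, val_iou, lr

    @property
    def best_epoch(self) -> int:
        """0-based index of the epoch with the highest validation Dice."""
        if not self.epochs:
            raise ValueError("empty history")
        return int(np.argmax([e["val_dice"] for e in self.epochs]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"epoch": i, "train_loss": e["train_loss"],
             "val_dice": e["val_dice"], "val_iou": e["val_iou"]}
            for i, e in enumerate(self.epochs)])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_unet(spec: UNetSpec, rng: np.random.Generator) -> nn.UNet:
    """Instantiate the segmenter; per-pixel probabilities, dims preserved."""
    spec.validate()
    return nn.UNet(rng, depth=spec.depth, base_channels=spec.base_channels,
                   in_ch=spec.in_channels, out_ch=spec.out_channels)


def bce_loss(probabilities, mask) -> Tensor:
    """Mean binary cross-entropy; probabilities clipped away from {0,1}."""
    p = probabilities if isinstance(probabilities, Tensor) else Tensor(probabilities)
    m = np.asarray(mask, dtype=np.float32)
    if p.data.shape != m.shape:
        raise ValueError(f"probabilities {p.data.shape} and mask {m.shape} dims differ")
    p = ag.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)
    mt = Tensor(m)
    one = Tensor(np.float32(1.0))
    term = mt * ag.log(p) + (one - mt) * ag.log(one - p)
    return -ag.tmean(term)


def _image_to_input(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=np.float32).transpose(2, 0, 1) / 127.5 - 1.0


def predict_probabilities(model: nn.UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probabilities (H×W float in [0,1])."""
    x = _image_to_input(image)[None]
    with no_grad():
        out = model(Tensor(x))
    return out.data[0, 0]


def predict_mask(model: nn.UNet, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Thresholded probability map; ties (p == threshold) go to foreground."""
    return (predict_probabilities(model, image) >= threshold).astype(np.uint8)


def _load_pairs(manifest: DatasetManifest) -> list[tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for row in manifest:
        if not row.has_mask:
            raise ValueError(f"segmentation row without mask: {row.image_path}")
        pairs.append((read_image(row.image_path), read_mask(row.mask_path)))
    return pairs


def _validate(model: nn.UNet, pairs, threshold: float) -> tuple[float, float]:
    dices, ious = [], []
    for image, mask in pairs:
        pred = predict_mask(model, image, threshold)
        dices.append(dice(pred, mask))
        ious.append(iou(pred, mask))
    return float(np.mean(dices)), float(np.mean(ious))


def train_segmenter(config: SegConfig, spec: UNetSpec,
                    train: DatasetManifest, val: DatasetManifest,
                    model: nn.UNet | None = None,
                    checkpoint_dir=None, phase: str = "a"
                    ) -> tuple[nn.UNet, TrainHistory]:
    """Train (or continue training) the segmenter.

    Returns the parameters of the epoch with the best validation Dice.
    With ``model`` given, training continues from its parameters (the
    fine-tuning phases); otherwise a fresh network is initialized from
    config.seed.
    """
    config.validate()
    spec.validate()
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and val manifests must be non-empty")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = build_unet(spec, rng)
    history = TrainHistory()
    if config.epochs == 0:
        return model, history
    train_pairs = _load_pairs(train)
    val_pairs = _load_pairs(val)
    opt = nn.SGD(model.parameters(), lr=config.learning_rate,
                 momentum=config.momentum, weight_decay=config.weight_decay)
    best_params: list[np.ndarray] | None = None
    best_dice = -1.0
    if checkpoint_dir is not None:
        Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
    for epoch in range(config.epochs):
        opt.lr = nn.step_lr(config.learning_rate, epoch,
                            config.scheduler_step, config.scheduler_gamma)
        order = rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            imgs, masks = [], []
            for i in idx:
                image, mask = train_pairs[i]
                if config.hflip_augment and rng.random() < 0.5:
                    image, mask = image[:, ::-1], mask[:, ::-1]
                imgs.append(_image_to_input(image))
                masks.append(mask.astype(np.float32)[None])
            out = model(Tensor(np.stack(imgs)))
            loss = bce_loss(out, np.stack(masks))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_dice, val_iou = _validate(model, val_pairs, config.binarize_threshold)
        history.epochs.append({"train_loss": float(np.mean(losses)),
                               "val_dice": val_dice, "val_iou": val_iou,
                               "lr": opt.lr})
        if val_dice > best_dice:
            best_dice = val_dice
            best_params = [p.copy() for p in model.state_arrays()]
        if checkpoint_dir is not None:
            save_segmenter(model, spec, Path(checkpoint_dir) /
                           f"seg_{phase}_{epoch + 1}.ckpt")
    if best_params is not None:
        model.load_state_arrays(best_params)
    return model, history


def fine_tune(model: nn.UNet, config: SegConfig, spec: UNetSpec,
              manifests: list[DatasetManifest], val: DatasetManifest,
              checkpoint_dir=None, phase: str = "c"
              ) -> tuple[nn.UNet, TrainHistory]:
    """Continue training from ``model`` on the concatenation of manifests."""
    pooled = DatasetManifest([row for m in manifests for row in m.rows])
    if config.epochs == 0:
        return model, TrainHistory()
    return train_segmenter(config, spec, pooled, val, model=model,
                           checkpoint_dir=checkpoint_dir, phase=phase)


def save_segmenter(model: nn.UNet, spec: UNetSpec, path) -> None:
    payload = {"spec": asdict(spec), "params": model.state_arrays()}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_segmenter(path) -> tuple[nn.UNet, UNetSpec]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    spec = UNetSpec(**payload["spec"])
    model = build_unet(spec, np.random.default_rng(0))
    model.load_state_arrays(payload["params"])
    return model, spec
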