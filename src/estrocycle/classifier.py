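"""Pluggable softmax stage classifier and its transfer-learning schedule.

The training harness implements the schedule used for fine-tuning cytology
classifiers: RMSprop (squared-gradient decay 0.99) with minibatches, a
piecewise step-decay learning rate

    lr(epoch) = max(lr_floor, lr0 * drop ** floor(epoch / epochs_drop))

and per-epoch shuffling.  The default hyperparameters (lr0 = 1e-5,
minibatch 80, drop 0.1 every epoch, 3 epochs) are those found by Bayesian
optimization for fine-tuning a pretrained ResNet-50.  Zoo backbones
(ResNet-50, VGG-19, Inception v3, MobileNet v2) are loaded from
torchvision when the optional torch backend is installed; the bundled
``smallcnn`` backbone trains from scratch in minutes on a CPU and is the
backbone exercised by the test suite (see :func:`smallcnn_config` for its
from-scratch preset).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from ._smallcnn import OPTIMIZERS, RMSProp, SmallCNN
from .io import DatasetManifest, ImageRecord
from .posthoc import confidence_index
from .preprocess import (
    Augmenter,
    AugmentParams,
    preprocess_image,
    quadrisect,
    resize_to_input,
)
from .results import ClassificationResult, StageProbabilities
from .stages import CANONICAL_STAGES

logger = logging.getLogger("estrocycle")

VALID_BACKBONES = ("resnet50", "vgg19", "inceptionv3", "mobilenetv2", "smallcnn")
ZOO_BACKBONES = ("resnet50", "vgg19", "inceptionv3", "mobilenetv2")


@dataclass
class TrainingConfig:
    """Hyperparameters of the training schedule."""

    backbone: str = "smallcnn"
    n_stages: int = 4
    stage_names: tuple[str, ...] | None = None
    initial_lr: float = 1e-5
    minibatch: int = 80
    optimizer: str = "rmsprop"
    squared_gradient_decay: float = 0.99
    epochs: int = 3
    shuffle_every_epoch: bool = True
    lr_drop: float = 0.1
    epochs_drop: int = 1
    lr_floor: float = 0.0
    grad_clip: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in VALID_BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; valid: {', '.join(VALID_BACKBONES)}"
            )
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if not 0 < self.lr_drop <= 1:
            raise ValueError("lr_drop must lie in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.epochs_drop < 1:
            raise ValueError("epochs_drop must be >= 1")
        if self.lr_floor < 0:
            raise ValueError("lr_floor must be >= 0")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {tuple(OPTIMIZERS)}")
        if self.stage_names is not None:
            self.stage_names = tuple(self.stage_names)
            if len(self.stage_names) != self.n_stages:
                raise ValueError("stage_names length must equal n_stages")
        elif self.n_stages == 4:
            self.stage_names = CANONICAL_STAGES

    def stages(self) -> tuple[str, ...]:
        if self.stage_names is None:
            raise ValueError("stage_names must be given when n_stages != 4")
        return self.stage_names


def smallcnn_config(seed: int = 0, **overrides) -> TrainingConfig:
    """Preset for training the bundled smallcnn from scratch.

    A randomly initialized CNN needs a far larger learning rate, a smaller
    minibatch and gradient-norm clipping, compared with the fine-tuning
    defaults, to converge stably within 3 epochs.
    """
    kw = dict(backbone="smallcnn", initial_lr=3e-3, minibatch=8, grad_clip=1.0,
              seed=seed)
    kw.update(overrides)
    return TrainingConfig(**kw)


def step_decay_lr(epoch: int, cfg: TrainingConfig) -> float:
    """Piecewise step-decay learning rate, clamped below at ``lr_floor``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    lr = cfg.initial_lr * cfg.lr_drop ** math.floor(epoch / cfg.epochs_drop)
    return max(cfg.lr_floor, lr)


def _load_zoo_backbone(name: str, n_stages: int):
    try:
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            f"backbone {name!r} requires the optional deep-learning backend "
            "(torch + torchvision), which is not installed; use "
            "backbone='smallcnn' or install torchvision"
        ) from exc
    raise NotImplementedError(
        f"zoo backbone {name!r} loading is delegated to torchvision"
    )


def build_model(cfg: TrainingConfig):
    """Instantiate an untrained model with an ``n_stages``-way softmax head."""
    if cfg.backbone == "smallcnn":
        return SmallCNN(n_stages=cfg.n_stages, seed=cfg.seed)
    return _load_zoo_backbone(cfg.backbone, cfg.n_stages)


def load_image(source: str | Path | ImageRecord | np.ndarray) -> np.ndarray:
    """Load an image as a float array in [0, 1]."""
    if isinstance(source, np.ndarray):
        img = source.astype(float)
        return img / 255.0 if img.max() > 1.5 else img
    path = source.image_path if isinstance(source, ImageRecord) else source
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return arr


def prepare_input(source, model) -> np.ndarray:
    """Preprocess one image through the standard chain into model input."""
    img = load_image(source)
    img = preprocess_image(img)
    img = resize_to_input(img)
    return model.reduce(img)


@dataclass
class TrainedModel:
    """A trained classifier with its config snapshot and training history."""

    model: SmallCNN
    config: TrainingConfig
    stage_names: tuple[str, ...]
    history: list[dict] = field(default_factory=list)

    def predict_proba(self, inputs: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(inputs)

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "weights.npz", **self.model.params)
        cfg = dataclasses.asdict(self.config)
        (out_dir / "config.json").write_text(json.dumps(cfg, indent=2))
        (out_dir / "stages.txt").write_text("\n".join(self.stage_names) + "\n")
        (out_dir / "history.json").write_text(json.dumps(self.history, indent=2))
        return out_dir

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedModel":
        model_dir = Path(model_dir)
        cfg_dict = json.loads((model_dir / "config.json").read_text())
        if cfg_dict.get("stage_names") is not None:
            cfg_dict["stage_names"] = tuple(cfg_dict["stage_names"])
        cfg = TrainingConfig(**cfg_dict)
        if cfg.backbone != "smallcnn":
            raise ValueError("only smallcnn model directories can be reloaded")
        model = SmallCNN(n_stages=cfg.n_stages, seed=cfg.seed)
        with np.load(model_dir / "weights.npz") as data:
            model.params = {k: data[k] for k in data.files}
        stages = tuple((model_dir / "stages.txt").read_text().split())
        history = json.loads((model_dir / "history.json").read_text())
        return cls(model=model, config=cfg, stage_names=stages, history=history)


def _stage_index(cfg: TrainingConfig) -> dict[str, int]:
    return {s: i for i, s in enumerate(cfg.stages())}


def _prepare_dataset(
    manifest: DatasetManifest, model, cfg: TrainingConfig,
    augmenter: Augmenter | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    index = _stage_index(cfg)
    xs, ys = [], []
    for r in manifest:
        if r.benchmark_stage not in index:
            continue
        img = load_image(r)
        img = preprocess_image(img)
        if augmenter is not None:
            img = augmenter(img)
        img = resize_to_input(img)
        xs.append(model.reduce(img))
        ys.append(index[r.benchmark_stage])
    return np.stack(xs), np.asarray(ys)


def train(
    model,
    split,
    cfg: TrainingConfig,
    augment_params: AugmentParams | None = None,
    labels: Sequence[str] | None = None,
) -> TrainedModel:
    """Run the step-decay minibatch schedule on a dataset split.

    ``labels`` optionally overrides the training labels (same order as the
    train manifest) — used for permutation controls.  Validation accuracy is
    recorded each epoch when a validation set is present.
    """
    if len(split.train) == 0:
        raise ValueError("training manifest is empty")
    index = _stage_index(cfg)
    rng = np.random.default_rng(cfg.seed)

    augmenter = Augmenter(augment_params) if augment_params is not None else None
    X, y = _prepare_dataset(split.train, model, cfg, augmenter=augmenter)
    if labels is not None:
        if len(labels) != len(y):
            raise ValueError("labels must match the training manifest length")
        y = np.asarray([index[s] for s in labels])
    present = set(int(v) for v in np.unique(y))
    missing = [s for s, i in index.items() if i not in present]
    if missing:
        raise ValueError(f"stage(s) absent from training data: {', '.join(missing)}")
    Xv = yv = None
    if len(split.validation) > 0:
        Xv, yv = _prepare_dataset(split.validation, model, cfg)

    opt_cls = OPTIMIZERS[cfg.optimizer]
    if opt_cls is RMSProp:
        opt = RMSProp(model.params, rho=cfg.squared_gradient_decay)
    else:
        opt = opt_cls(model.params)
    history = []
    n = X.shape[0]
    order = np.arange(n)
    for epoch in range(cfg.epochs):
        lr = step_decay_lr(epoch, cfg)
        if cfg.shuffle_every_epoch:
            rng.shuffle(order)
        losses = []
        for start in range(0, n, cfg.minibatch):
            idx = order[start:start + cfg.minibatch]
            xb = X[idx]
            loss, grads = model.loss_and_grads(xb, y[idx])
            if cfg.grad_clip is not None:
                norm = float(np.sqrt(sum((g ** 2).sum() for g in grads.values())))
                if norm > cfg.grad_clip:
                    grads = {k: g * (cfg.grad_clip / norm) for k, g in grads.items()}
            opt.step(model.params, grads, lr)
            losses.append(loss)
        entry = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}
        if Xv is not None:
            preds = np.argmax(model.predict_proba(Xv), axis=1)
            entry["val_accuracy"] = float(np.mean(preds == yv))
        history.append(entry)
        logger.info("epoch %d: lr=%.2e loss=%.4f val_acc=%s", epoch, lr,
                    entry["train_loss"], entry.get("val_accuracy"))
    return TrainedModel(model=model, config=cfg, stage_names=cfg.stages(),
                        history=history)


def predict_probabilities(
    trained: TrainedModel,
    source: str | Path | ImageRecord | np.ndarray,
    aggregate_quadrants: bool = False,
) -> StageProbabilities:
    """Per-stage softmax probabilities for one image.

    With ``aggregate_quadrants`` the image is quadrisected after luminance
    normalization; the four quadrant probability vectors are averaged and
    renormalized.
    """
    img = load_image(source)
    img = preprocess_image(img)
    if aggregate_quadrants:
        tiles = quadrisect(img)
    else:
        tiles = [img]
    inputs = np.stack([trained.model.reduce(resize_to_input(t)) for t in tiles])
    probs = trained.predict_proba(inputs).mean(axis=0)
    probs = probs / probs.sum()
    return StageProbabilities(probs=tuple(float(p) for p in probs),
                              stages=trained.stage_names)


def classify_manifest(
    trained: TrainedModel,
    manifest: DatasetManifest,
    aggregate_quadrants: bool = False,
) -> list[ClassificationResult]:
    """Classify every image in a manifest, attaching the Confidence Index."""
    out = []
    for r in manifest:
        probs = predict_probabilities(trained, r, aggregate_quadrants)
        out.append(
            ClassificationResult(
                image_path=r.image_path,
                stage=probs.top_stage(),
                probabilities=probs,
                confidence_index=confidence_index(probs),
            )
        )
    return out
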