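"""Frozen-backbone transfer classifiers, the cross-entropy loss and the
training loop.

The architecture mirrors the three transfer models compared in the
study: a convolutional backbone with its classification top removed,
pooled (flatten for the VGG family, global average for ResNet50),
followed by two trainable fully connected layers and a 2-neuron softmax
(seizure / nonseizure). Only the head is ever trained; backbone
parameters stay frozen.

Backbones
---------
``tiny_random``
    A small random-weight conv stack (see :mod:`szdetect._nn`) that runs
    everywhere with no weight download; the default for desk-scale work.
``vgg16`` / ``vgg19`` / ``resnet50``
    Architectural descriptors carrying the pooled feature dimension and
    conv parameter counts of the ImageNet models. Building one yields a
    real (trainable) head, but running its feature extractor requires
    pretrained weights; without them a :class:`WeightsUnavailableError`
    is raised suggesting ``tiny_random`` for offline use.

Training recipes follow the study protocol: the VGG-family head uses
SGD (lr 0.001, per-update decay 1e-5, batch 64); the ResNet50 head uses
Adam (lr 0.001, beta1 0.9, beta2 0.999, batch 16) with the learning
rate reduced by a factor 0.8 after validation loss stalls for 5 epochs.
All paths cap epochs at 500 and stop early when validation loss has not
descended for 20 epochs, restoring the best-validation parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import Adam, DenseHead, SGD, TinyConvBackbone
from .dataset import DatasetSplit, ImageDataset, split_dataset
from .metrics import MetricsReport, mean_report

__all__ = ["ModelSpec", "TrainConfig", "TransferModel", "TrainingHistory",
           "WeightsUnavailableError", "softmax_cross_entropy", "build_model",
           "train", "predict", "evaluate", "repeat_runs", "reference_recipe"]

logger = logging.getLogger(__name__)

#: feature-map shape after the conv stack (ImageNet models at 224x224 input)
_BACKBONE_INFO = {
    "vgg16": {"feature_shape": (7, 7, 512), "pooling": "flatten",
              "conv_params": 14_714_688},
    "vgg19": {"feature_shape": (7, 7, 512), "pooling": "flatten",
              "conv_params": 20_024_384},
    "resnet50": {"feature_shape": (7, 7, 2048), "pooling": "global_average",
                 "conv_params": 23_587_712},
    "tiny_random": {"feature_shape": (27, 27, 32), "pooling": "flatten",
                    "conv_params": None},
}


class WeightsUnavailableError(RuntimeError):
    """Pretrained backbone weights are not available in this environment."""


@dataclass
class ModelSpec:
    """Backbone identity plus the trainable-head configuration."""

    backbone: str = "tiny_random"
    fc_sizes: tuple[int, int] = (4096, 4096)
    pooling: str | None = None  # None -> backbone's native pooling
    pretrained: bool = False
    freeze_backbone: bool = True
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONE_INFO:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; "
                f"choose from {sorted(_BACKBONE_INFO)}"
            )
        if len(self.fc_sizes) != 2 or any(s <= 0 for s in self.fc_sizes):
            raise ValueError(f"fc_sizes must be two positive ints, got {self.fc_sizes}")
        if self.pretrained and self.backbone == "tiny_random":
            raise ValueError("tiny_random has no pretrained weights")
        if self.pooling is None:
            self.pooling = _BACKBONE_INFO[self.backbone]["pooling"]
        if self.pooling not in ("flatten", "global_average"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


@dataclass
class TrainConfig:
    """Optimizer recipe and stopping rules for head training."""

    optimizer: str = "sgd"
    lr: float = 1e-3
    sgd_decay: float = 1e-5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 64
    max_epochs: int = 500
    early_stop_patience: int = 20
    plateau_factor: float = 0.8
    plateau_patience: int = 5
    use_plateau: bool | None = None  # None -> only on the Adam path
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"optimizer must be 'sgd' or 'adam', got {self.optimizer!r}")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ValueError("batch_size and patience values must be >= 1")
        if self.use_plateau is None:
            self.use_plateau = self.optimizer == "adam"


def reference_recipe(backbone: str) -> TrainConfig:
    """The study's training recipe for a backbone family."""
    if backbone == "resnet50":
        return TrainConfig(optimizer="adam", lr=1e-3, batch_size=16)
    return TrainConfig(optimizer="sgd", lr=1e-3, sgd_decay=1e-5, batch_size=64)


def softmax_cross_entropy(true_probs, pred_probs, eps: float = 1e-12) -> float:
    """Cross entropy H(r, p) = -sum_i r_i log p_i (natural log).

    Both arguments are length-2 probability vectors summing to 1 within
    1e-6; predicted entries are clipped to [eps, 1] before the log.
    """
    r = np.asarray(true_probs, dtype=np.float64)
    p = np.asarray(pred_probs, dtype=np.float64)
    for name, v in (("true_probs", r), ("pred_probs", p)):
        if v.shape != (2,):
            raise ValueError(f"{name} must be a length-2 vector, got shape {v.shape}")
        if (v < -1e-9).any() or (v > 1 + 1e-9).any():
            raise ValueError(f"{name} entries must lie in [0, 1]")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} must sum to 1, got {v.sum():.8f}")
    return float(-(r * np.log(np.clip(p, eps, 1.0))).sum())


def _batched_cross_entropy(y_onehot: np.ndarray, probs: np.ndarray,
                           eps: float = 1e-12) -> float:
    return float(-(y_onehot * np.log(np.clip(probs, eps, 1.0))).sum(axis=1).mean())


class _DescriptorBackbone:
    """Architecture stub for an ImageNet backbone without weights."""

    def __init__(self, name: str):
        self.name = name
        self.info = _BACKBONE_INFO[name]

    def forward(self, images, batch: int = 16):
        raise WeightsUnavailableError(
            f"pretrained weights for {self.name!r} are not available in this "
            "environment; use backbone='tiny_random' for offline runs"
        )

    def parameters(self) -> list[np.ndarray]:
        return []

    def parameter_count(self) -> int:
        return self.info["conv_params"]

    def feature_shape(self) -> tuple[int, int, int]:
        return self.info["feature_shape"]


class TransferModel:
    """A frozen backbone, a pooling stage and a trainable dense head."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        if spec.backbone == "tiny_random":
            self.backbone = TinyConvBackbone(seed=seed)
        else:
            self.backbone = _DescriptorBackbone(spec.backbone)
        h, w, c = self.backbone.feature_shape()
        self.pooled_dim = h * w * c if spec.pooling == "flatten" else c
        self.head = DenseHead(self.pooled_dim, tuple(spec.fc_sizes),
                              spec.n_classes,
                              rng=np.random.default_rng(seed))

    # -- feature path -----------------------------------------------------
    def _pool(self, feature_maps: np.ndarray) -> np.ndarray:
        if self.spec.pooling == "flatten":
            return feature_maps.reshape(len(feature_maps), -1)
        return feature_maps.mean(axis=(1, 2))

    def features(self, images: np.ndarray, batch: int = 16) -> np.ndarray:
        """Pooled backbone features, shape (N, pooled_dim)."""
        return self._pool(self.backbone.forward(images, batch=batch))

    # -- inference --------------------------------------------------------
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        if images.ndim != 4 or images.shape[1:] != (224, 224, 3):
            raise ValueError(
                f"expected images of shape (N, 224, 224, 3), got {images.shape}"
            )
        return self.head.predict_proba(self.features(images))

    # -- bookkeeping ------------------------------------------------------
    def trainable_parameter_count(self) -> int:
        if self.spec.freeze_backbone:
            return self.head.parameter_count()
        return self.head.parameter_count() + self.backbone.parameter_count()

    def backbone_parameters(self) -> list[np.ndarray]:
        return self.backbone.parameters()

    def save(self, path) -> None:
        arrays = {f"head_{i}": p for i, p in enumerate(self.head.parameters())}
        np.savez(path, backbone=self.spec.backbone,
                 fc_sizes=np.asarray(self.spec.fc_sizes),
                 pooling=self.spec.pooling, seed=self.seed, **arrays)

    @classmethod
    def load(cls, path) -> "TransferModel":
        with np.load(path, allow_pickle=False) as npz:
            spec = ModelSpec(backbone=str(npz["backbone"]),
                             fc_sizes=tuple(int(s) for s in npz["fc_sizes"]),
                             pooling=str(npz["pooling"]))
            model = cls(spec, seed=int(npz["seed"]))
            params = [npz[f"head_{i}"]
                      for i in range(len(model.head.parameters()))]
        model.head.set_parameters(params)
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> TransferModel:
    """Instantiate backbone + pooling + randomly initialized head.

    With ``pretrained=True`` the backbone weights must be obtainable;
    in an offline environment this raises
    :class:`WeightsUnavailableError` (use ``tiny_random`` instead).
    """
    if spec.pretrained:
        raise WeightsUnavailableError(
            f"pretrained ImageNet weights for {spec.backbone!r} cannot be "
            "loaded here; use backbone='tiny_random' for offline runs"
        )
    return TransferModel(spec, seed=seed)


@dataclass
class TrainingHistory:
    """Per-epoch curves plus stopping metadata."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_early: bool = False
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.epoch)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({k: getattr(self, k) for k in
                             ("epoch", "train_loss", "val_loss",
                              "train_acc", "val_acc", "lr")})


def train(model: TransferModel, dataset: ImageDataset, split: DatasetSplit,
          config: TrainConfig | None = None) -> TrainingHistory:
    """Train the dense head on precomputed frozen-backbone features.

    Early stopping monitors validation loss with the configured patience
    and the best-validation parameters are restored afterwards. With the
    Adam recipe the learning rate is additionally reduced by
    ``plateau_factor`` after ``plateau_patience`` non-improving epochs.
    Deterministic for a given ``config.seed``.
    """
    config = config or reference_recipe(model.spec.backbone)
    if not model.spec.freeze_backbone:
        raise NotImplementedError(
            "backbone fine-tuning is out of scope; freeze_backbone must be True"
        )
    if len(split.train_idx) == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng(config.seed)

    f_train = model.features(dataset.images[split.train_idx])
    f_val = model.features(dataset.images[split.val_idx])
    y_train = dataset.labels[split.train_idx]
    y_val = dataset.labels[split.val_idx]
    eye = np.eye(model.spec.n_classes)
    y_train_1h = eye[y_train]
    y_val_1h = eye[y_val]

    if config.optimizer == "sgd":
        opt = SGD(lr=config.lr, decay=config.sgd_decay)
    else:
        opt = Adam(lr=config.lr, beta1=config.adam_beta1,
                   beta2=config.adam_beta2)

    history = TrainingHistory()
    best_val = np.inf
    best_params = model.head.copy_parameters()
    since_improve = 0
    since_plateau = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(f_train))
        losses, accs = [], []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            probs, cache = model.head.forward(f_train[idx])
            losses.append(_batched_cross_entropy(y_train_1h[idx], probs))
            accs.append(float((probs.argmax(1) == y_train[idx]).mean()))
            grads = model.head.backward(probs, cache, y_train_1h[idx])
            opt.step(model.head.parameters(), grads)

        val_probs = model.head.predict_proba(f_val)
        val_loss = _batched_cross_entropy(y_val_1h, val_probs)
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.train_acc.append(float(np.mean(accs)))
        history.val_loss.append(val_loss)
        history.val_acc.append(float((val_probs.argmax(1) == y_val).mean()))
        history.lr.append(opt.lr)

        if val_loss < best_val:
            best_val = val_loss
            best_params = model.head.copy_parameters()
            history.best_epoch = epoch
            since_improve = 0
            since_plateau = 0
        else:
            since_improve += 1
            since_plateau += 1
            if config.use_plateau and since_plateau >= config.plateau_patience:
                opt.lr_scale *= config.plateau_factor
                since_plateau = 0
                logger.info("epoch %d: reducing lr by %.2f to %.2e",
                            epoch, config.plateau_factor, opt.lr)
            if since_improve >= config.early_stop_patience:
                history.stopped_early = True
                logger.info("early stop at epoch %d (best %d)",
                            epoch, history.best_epoch)
                break

    model.head.set_parameters(best_params)
    return history


def predict(model: TransferModel, images: np.ndarray) -> np.ndarray:
    """Per-image class probabilities, shape (N, 2); argmax gives the class
    (0 = nonseizure, 1 = seizure)."""
    return model.predict_proba(images)


def evaluate(model: TransferModel, dataset: ImageDataset,
             test_idx: np.ndarray):
    """Confusion counts and the metric suite on a test index set."""
    from .metrics import compute_metrics, counts_from_predictions

    test_idx = np.asarray(test_idx)
    if len(test_idx) == 0:
        raise ValueError("empty test set")
    probs = model.predict_proba(dataset.images[test_idx])
    y_true = dataset.labels[test_idx]
    counts = counts_from_predictions(y_true, probs.argmax(1))
    eye = np.eye(model.spec.n_classes)
    loss = _batched_cross_entropy(eye[y_true], probs)
    return counts, compute_metrics(counts, loss=loss)


def repeat_runs(dataset: ImageDataset, spec: ModelSpec,
                config: TrainConfig | None = None, repeats: int = 10,
                fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                base_seed: int = 0) -> tuple[list[MetricsReport], MetricsReport]:
    """Re-split, retrain and re-test ``repeats`` times; report per-run
    metrics and their arithmetic mean (the study's 10-run averaging)."""
    reports = []
    for k in range(repeats):
        seed = base_seed + k
        split = split_dataset(dataset, fractions, seed=seed)
        model = build_model(spec, seed=seed)
        cfg = replace(config, seed=seed) if config else None
        train(model, dataset, split, cfg)
        _, report = evaluate(model, dataset, split.test_idx)
        reports.append(report)
    return reports, mean_report(reports)
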