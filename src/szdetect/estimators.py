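"""scikit-learn estimator front end for the transfer classifiers.

:class:`SeizureClassifier` wraps backbone construction, the internal
train/validation carve-out, head training with early stopping, and
probability prediction behind the standard fit/predict surface, so it
composes with sklearn model selection and pipelines operating on image
arrays of shape (n_samples, 224, 224, 3).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .models import ModelSpec, TrainConfig, TransferModel, build_model, train
from .dataset import DatasetSplit, ImageDataset

__all__ = ["SeizureClassifier"]


class SeizureClassifier(ClassifierMixin, BaseEstimator):
    """Frozen-backbone transfer classifier with a trainable dense head.

    Parameters
    ----------
    backbone : str, default "tiny_random"
        "tiny_random" runs offline; "vgg16"/"vgg19"/"resnet50" describe
        the ImageNet architectures and need pretrained weights.
    fc_sizes : tuple of int, default (128, 64)
        Sizes of the two trainable fully connected layers. (The study's
        full-scale heads use 4096x4096 / 2048x2048; the smaller default
        matches the tiny backbone's feature width.)
    optimizer, lr, sgd_decay, batch_size, max_epochs, patience,
    plateau_factor, plateau_patience
        Head-training recipe; defaults follow the SGD protocol
        (lr 0.001, decay 1e-5, batch 64, max 500 epochs, early stopping
        patience 20 on validation loss).
    val_fraction : float, default 0.25
        Fraction of the fitting data carved out for early stopping.
    random_state : int, default 0
        Seeds initialization, shuffling and the validation carve-out.

    Attributes
    ----------
    model_ : TransferModel
        The fitted backbone + head.
    history_ : TrainingHistory
        Per-epoch training curves.
    classes_ : ndarray
        Sorted class labels (0 = nonseizure, 1 = seizure).
    """

    def __init__(self, backbone: str = "tiny_random",
                 fc_sizes: tuple[int, int] = (128, 64),
                 optimizer: str = "sgd", lr: float = 1e-3,
                 sgd_decay: float = 1e-5, batch_size: int = 64,
                 max_epochs: int = 500, patience: int = 20,
                 plateau_factor: float = 0.8, plateau_patience: int = 5,
                 val_fraction: float = 0.25, random_state: int = 0):
        self.backbone = backbone
        self.fc_sizes = fc_sizes
        self.optimizer = optimizer
        self.lr = lr
        self.sgd_decay = sgd_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:] != (224, 224, 3):
            raise ValueError(
                f"X must have shape (n_samples, 224, 224, 3), got {X.shape}"
            )
        return X

    def fit(self, X, y) -> "SeizureClassifier":
        X = self._validate_images(X)
        y = np.asarray(y).astype(int)
        if len(X) != len(y):
            raise ValueError("X and y differ in length")
        self.classes_ = np.unique(y)
        if not set(self.classes_) <= {0, 1}:
            raise ValueError("labels must be binary (0 = nonseizure, 1 = seizure)")

        spec = ModelSpec(backbone=self.backbone,
                         fc_sizes=tuple(self.fc_sizes))
        config = TrainConfig(
            optimizer=self.optimizer, lr=self.lr, sgd_decay=self.sgd_decay,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            early_stop_patience=self.patience,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience, seed=self.random_state,
        )
        self.model_ = build_model(spec, seed=self.random_state)

        # carve a validation set out of the fitting data for early stopping
        rng = np.random.default_rng(self.random_state)
        perm = rng.permutation(len(X))
        n_val = max(1, int(np.floor(self.val_fraction * len(X) + 0.5)))
        if n_val >= len(X):
            raise ValueError("val_fraction leaves no training samples")
        split = DatasetSplit(train_idx=perm[n_val:], val_idx=perm[:n_val],
                             test_idx=np.zeros(0, dtype=np.int64),
                             fractions=(1 - self.val_fraction,
                                        self.val_fraction, 0.0),
                             seed=self.random_state)
        dataset = ImageDataset(images=X, labels=y)
        self.history_ = train(self.model_, dataset, split, config)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._validate_images(X))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
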