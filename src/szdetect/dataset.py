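"""Pooled image datasets and shuffled train/validation/test splits.

Images from all records (all subjects) are pooled into one dataset —
the cross-subject protocol — then split by a seeded uniform shuffle into
60/20/20 train/validation/test partitions. The shuffle is deliberately
not subject-stratified: windows from one subject can land in both train
and test. An optional leave-subject-out splitter is provided for
stricter generalization estimates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import EEGRecord
from .segmentation import (
    SegmentationParams,
    extract_samples,
    segment_seizure_augment,
    segment_sliding,
)
from .spectrogram import StftConfig, TFImage, to_tf_image

__all__ = ["ImageDataset", "DatasetSplit", "build_dataset", "split_dataset",
           "split_leave_subject_out"]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["record_ref", "start_s", "length_s", "label", "source"]


@dataclass
class ImageDataset:
    """Fused time-frequency images with labels and per-image provenance."""

    images: np.ndarray  # (N, 224, 224, 3) float32
    labels: np.ndarray  # (N,) int
    manifest: pd.DataFrame = None
    skipped_records: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        if self.manifest is None:
            self.manifest = pd.DataFrame(
                {"record_ref": [""] * len(self.labels),
                 "start_s": np.nan, "length_s": np.nan,
                 "label": self.labels, "source": "sliding"}
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_balance(self) -> float:
        """Fraction of positive (seizure) images."""
        return float(self.labels.mean()) if len(self.labels) else 0.0

    @classmethod
    def from_images(cls, images: list[TFImage],
                    length_s: float = 180.0) -> "ImageDataset":
        manifest = pd.DataFrame(
            [(im.record_ref, im.start_s, length_s, im.label, im.source)
             for im in images],
            columns=MANIFEST_COLUMNS,
        )
        return cls(
            images=np.stack([im.pixels for im in images]) if images
            else np.zeros((0, 224, 224, 3), np.float32),
            labels=np.array([im.label for im in images], dtype=np.int64),
            manifest=manifest,
        )

    def save(self, path) -> None:
        """Write images+labels (.npz) and the manifest CSV alongside."""
        path = Path(path)
        np.savez_compressed(path, images=self.images, labels=self.labels)
        self.manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)

    @classmethod
    def load(cls, path) -> "ImageDataset":
        path = Path(path)
        with np.load(path) as npz:
            images, labels = npz["images"], npz["labels"]
        manifest_path = path.with_suffix(".manifest.csv")
        manifest = pd.read_csv(manifest_path) if manifest_path.exists() else None
        return cls(images=images, labels=labels, manifest=manifest)


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive index sets from a seeded shuffle."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        self.val_idx = np.asarray(self.val_idx, dtype=np.int64)
        self.test_idx = np.asarray(self.test_idx, dtype=np.int64)
        n = len(self.train_idx) + len(self.val_idx) + len(self.test_idx)
        union = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(union)) != n:
            raise ValueError("split index sets are not disjoint")

    def save(self, path) -> None:
        payload = {
            "seed": self.seed,
            "fractions": list(self.fractions),
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "DatasetSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_idx=payload["train_idx"], val_idx=payload["val_idx"],
            test_idx=payload["test_idx"],
            fractions=tuple(payload["fractions"]), seed=payload["seed"],
        )


def build_dataset(records: list[EEGRecord],
                  stft: StftConfig | None = None,
                  seg_params: SegmentationParams | None = None,
                  n_channels: int = 3) -> ImageDataset:
    """Pool step-one and step-two images from many records.

    For each record, all sliding windows are imaged (labels from seizure
    overlap) and every seizure interval contributes its augmentation
    windows (all positive). Records without the expected channel count
    are skipped with a warning and listed in ``skipped_records``.
    """
    stft = stft or StftConfig()
    seg = seg_params or SegmentationParams()
    images: list[TFImage] = []
    rows = []
    skipped = []
    for record in records:
        if record.n_channels != n_channels:
            logger.warning(
                "skipping record %r: %d channels, expected %d",
                record.subject_id, record.n_channels, n_channels,
            )
            skipped.append(record.subject_id)
            continue
        windows = segment_sliding(record, seg.length_s, seg.overlap_frac)
        for interval in record.seizures:
            windows += segment_seizure_augment(
                record, interval, seg.length_s, seg.step_s, seg.min_overlap_s
            )
        for win in windows:
            images.append(
                to_tf_image(extract_samples(record, win), stft, win.label,
                            record_ref=win.record_ref, start_s=win.start_s,
                            source=win.source)
            )
            rows.append((win.record_ref, win.start_s, win.length_s,
                         win.label, win.source))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return ImageDataset(
        images=np.stack([im.pixels for im in images]) if images
        else np.zeros((0, 224, 224, 3), np.float32),
        labels=manifest["label"].to_numpy(np.int64) if len(manifest)
        else np.zeros(0, np.int64),
        manifest=manifest,
        skipped_records=skipped,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(dataset, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> DatasetSplit:
    """Shuffle and cut into train/val/test index sets.

    ``dataset`` may be an :class:`ImageDataset` or a plain length N.
    Train and validation sizes round to nearest; test takes the
    remainder. Deterministic for a given seed.
    """
    n = dataset if isinstance(dataset, (int, np.integer)) else len(dataset)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if n < 3:
        raise ValueError(f"need at least 3 images to split, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = _round_half_up(fractions[0] * n)
    n_val = _round_half_up(fractions[1] * n)
    return DatasetSplit(
        train_idx=perm[:n_train],
        val_idx=perm[n_train : n_train + n_val],
        test_idx=perm[n_train + n_val :],
        fractions=tuple(fractions),
        seed=seed,
    )


def split_leave_subject_out(dataset: ImageDataset, test_subjects: list[str],
                            val_fraction: float = 0.25,
                            seed: int = 0) -> DatasetSplit:
    """Stricter extension: hold out whole subjects as the test set.

    Remaining images are shuffled and cut into train/validation. Not the
    pooled-shuffle protocol; off by default everywhere.
    """
    subjects = dataset.manifest["record_ref"].astype(str)
    test_mask = subjects.isin(list(test_subjects)).to_numpy()
    test_idx = np.flatnonzero(test_mask)
    rest = np.flatnonzero(~test_mask)
    if len(test_idx) == 0 or len(rest) == 0:
        raise ValueError("leave-subject-out split leaves an empty partition")
    rest = np.random.default_rng(seed).permutation(rest)
    n_val = _round_half_up(val_fraction * len(rest))
    n = len(dataset)
    return DatasetSplit(
        train_idx=rest[n_val:], val_idx=rest[:n_val], test_idx=test_idx,
        fractions=((len(rest) - n_val) / n, n_val / n, len(test_idx) / n),
        seed=seed,
    )
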