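"""Core data containers: a multichannel EEG record and its seizure annotations.

An :class:`EEGRecord` holds the raw signal the whole pipeline consumes:
equal-length per-channel sample arrays in microvolts at a fixed sampling
rate, together with expert seizure intervals in seconds. Annotations are
kept in float seconds internally even though the CHB-MIT convention labels
them at integer seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SeizureInterval", "EEGRecord"]


@dataclass(frozen=True, order=True)
class SeizureInterval:
    """A seizure episode spanning ``[t1, t2]`` seconds within a record."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t1 >= 0:
            raise ValueError(f"seizure start must be >= 0, got t1={self.t1}")
        if not self.t2 > self.t1:
            raise ValueError(
                f"seizure end must exceed start, got [{self.t1}, {self.t2}]"
            )

    @property
    def duration(self) -> float:
        return self.t2 - self.t1


def validate_intervals(
    seizures: list[SeizureInterval], duration_s: float
) -> list[SeizureInterval]:
    """Sort intervals, then enforce bounds and non-overlap."""
    seizures = sorted(seizures, key=lambda s: s.t1)
    for s in seizures:
        if s.t2 > duration_s + 1e-9:
            raise ValueError(
                f"seizure [{s.t1}, {s.t2}] extends past record end ({duration_s} s)"
            )
    for a, b in zip(seizures, seizures[1:]):
        if b.t1 < a.t2:
            raise ValueError(
                f"overlapping seizure intervals [{a.t1}, {a.t2}] and [{b.t1}, {b.t2}]"
            )
    return seizures


@dataclass
class EEGRecord:
    """Multichannel scalp-EEG signal with labeled seizure intervals.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    channel_labels
        Ordered channel names, e.g. ``["FP2-F8", "F8-T8", "T8-P8"]``.
    fs
        Sampling rate in Hz (positive).
    seizures
        Non-overlapping seizure intervals, sorted by start time.
    subject_id
        Free-form subject/record identifier used for provenance.
    """

    signals: np.ndarray
    channel_labels: list[str]
    fs: float
    seizures: list[SeizureInterval] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError(
                f"signals must be 2-D (channels, samples), got shape {self.signals.shape}"
            )
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.signals.shape[0]} channels"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.seizures = validate_intervals(list(self.seizures), self.duration_s)

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        """Record length in seconds; sample count equals round(fs * duration)."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in record (has {self.channel_labels})"
            ) from None
        return self.signals[idx]
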