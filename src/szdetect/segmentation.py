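"""Two-step windowing of EEG records into labeled 180 s segments.

Step one slides a fixed-length window (180 s default) along the record
with fractional overlap (30% default, i.e. a 126 s stride) and labels
each window positive iff it overlaps any seizure interval. Step two
augments the positive class: starting at each seizure onset t1, a window
advances one second per step and is kept while it overlaps [t1, t2] by
at least 3 seconds.

Windows are half-open ``[start, start + length)``; overlap is the length
of the half-open intersection. Windows that would run past the record
end are dropped, never truncated, so every window downstream is exactly
one window long.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .records import EEGRecord, SeizureInterval

__all__ = [
    "SegmentWindow",
    "SegmentationParams",
    "segment_sliding",
    "segment_seizure_augment",
    "label_window",
    "overlap_length",
]

_TOL = 1e-9


@dataclass(frozen=True)
class SegmentWindow:
    """One labeled time slice of a record.

    ``source`` records provenance: ``"sliding"`` for step-one windows,
    ``"augment"`` for step-two seizure-augmentation windows (always
    positive).
    """

    start_s: float
    length_s: float = 180.0
    label: int = 0
    source: str = "sliding"
    record_ref: str = ""

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"window start must be >= 0, got {self.start_s}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.source not in ("sliding", "augment"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "augment" and self.label != 1:
            raise ValueError("augmentation windows must be labeled positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s


@dataclass
class SegmentationParams:
    """Step-one and step-two windowing parameters (seconds)."""

    length_s: float = 180.0
    overlap_frac: float = 0.30
    step_s: float = 1.0
    min_overlap_s: float = 3.0


def overlap_length(start: float, end: float, t1: float, t2: float) -> float:
    """Length of the half-open intersection [start, end) ∩ [t1, t2)."""
    return max(0.0, min(end, t2) - max(start, t1))


def label_window(window: SegmentWindow,
                 seizures: list[SeizureInterval]) -> int:
    """1 iff the window's half-open overlap with any seizure exceeds 0."""
    for s in seizures:
        if overlap_length(window.start_s, window.end_s, s.t1, s.t2) > 0:
            return 1
    return 0


def segment_sliding(record: EEGRecord, length_s: float = 180.0,
                    overlap_frac: float = 0.30) -> list[SegmentWindow]:
    """Step one: slide a window from time 0 with fractional overlap.

    Stride = ``length_s * (1 - overlap_frac)`` (126 s at defaults);
    windows are emitted while ``start + length <= duration`` and labeled
    via :func:`label_window`. A record shorter than one window yields an
    empty list with a warning.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    if length_s <= 0:
        raise ValueError("length_s must be positive")
    duration = record.duration_s
    if duration + _TOL < length_s:
        warnings.warn(
            f"record {record.subject_id!r} ({duration:.1f} s) shorter than "
            f"one {length_s:.0f} s window; no segments produced",
            stacklevel=2,
        )
        return []
    stride = length_s * (1.0 - overlap_frac)
    windows = []
    k = 0
    while k * stride + length_s <= duration + _TOL:
        start = k * stride
        win = SegmentWindow(start_s=start, length_s=length_s,
                            source="sliding", record_ref=record.subject_id)
        windows.append(
            SegmentWindow(start_s=start, length_s=length_s,
                          label=label_window(win, record.seizures),
                          source="sliding", record_ref=record.subject_id)
        )
        k += 1
    return windows


def segment_seizure_augment(record: EEGRecord, interval: SeizureInterval,
                            length_s: float = 180.0, step_s: float = 1.0,
                            min_overlap_s: float = 3.0) -> list[SegmentWindow]:
    """Step two: augment positives by stepping a window across a seizure.

    Starts at ``t1`` and advances ``step_s`` (1 s) per step; a start is
    kept iff the window overlaps [t1, t2] by at least ``min_overlap_s``
    and fits within the record. All emitted windows carry label 1 and
    source ``"augment"``. An empty list is a valid outcome (seizure
    shorter than the overlap rule, or window clipped by the record end).
    """
    if step_s <= 0 or min_overlap_s <= 0:
        raise ValueError("step_s and min_overlap_s must be positive")
    duration = record.duration_s
    windows = []
    k = 0
    while True:
        start = interval.t1 + k * step_s
        ov = overlap_length(start, start + length_s, interval.t1, interval.t2)
        if ov + _TOL < min_overlap_s:
            break
        if start + length_s <= duration + _TOL:
            windows.append(
                SegmentWindow(start_s=start, length_s=length_s, label=1,
                              source="augment", record_ref=record.subject_id)
            )
        k += 1
    return windows


def extract_samples(record: EEGRecord, window: SegmentWindow):
    """Slice the record's sample block for a window: shape (n_channels, n)."""
    i0 = int(round(window.start_s * record.fs))
    n = int(round(window.length_s * record.fs))
    if i0 < 0 or i0 + n > record.n_samples:
        raise ValueError(
            f"window [{window.start_s}, {window.end_s}) outside record "
            f"of {record.duration_s} s"
        )
    return record.signals[:, i0 : i0 + n]
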