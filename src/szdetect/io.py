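"""EDF and CHB-MIT annotation I/O.

Reading EDF goes through :mod:`mne`; writing (used for fixtures and the
``simulate`` subcommand) is a minimal EDF writer with 16-bit physical/digital
scaling, the physical range per channel taken from the signal min/max.

Seizure annotations follow the CHB-MIT ``chbXX-summary.txt`` dialect:
per-file blocks with ``Seizure Start Time: N seconds`` / ``Seizure End
Time: M seconds`` lines (optionally numbered ``Seizure 1 Start Time``).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .records import EEGRecord, SeizureInterval

__all__ = [
    "read_edf",
    "write_edf",
    "read_chbmit_annotations",
    "write_chbmit_summary",
    "ChannelNotFoundError",
    "EDFFormatError",
    "AnnotationParseError",
]


class ChannelNotFoundError(KeyError):
    """A requested channel label is absent from the EDF file."""


class EDFFormatError(ValueError):
    """The EDF file violates an assumption (e.g. mixed sampling rates)."""


class AnnotationParseError(ValueError):
    """A malformed CHB-MIT summary block; message carries the line number."""


# --------------------------------------------------------------------------
# EDF header inspection (labels + per-channel sampling rates)

def _read_edf_header(path: Path) -> dict:
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise EDFFormatError(f"{path}: truncated EDF header")
        n_signals = int(fixed[252:256].decode("ascii").strip())
        var = fh.read(256 * n_signals)
    labels = [
        var[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(n_signals)
    ]
    off = n_signals * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [
        int(var[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(n_signals)
    ]
    record_dur = float(fixed[244:252].decode("ascii").strip())
    return {"labels": labels, "samples_per_record": spr, "record_duration": record_dur}


def _resolve_channel(label: str, available: list[str]) -> tuple[str, ...]:
    """Map a requested (possibly bipolar) label onto stored channels.

    The stored bipolar channel is preferred when present; otherwise a label
    of the form ``A-B`` is derived by subtracting referential channels A
    and B. Returns the source channel name(s).
    """
    norm = {c.strip().upper(): c for c in reversed(available)}
    key = label.strip().upper()
    if key in norm:
        return (norm[key],)
    if "-" in key:
        a, b = key.split("-", 1)
        if a in norm and b in norm:
            return (norm[a], norm[b])
    raise ChannelNotFoundError(
        f"channel {label!r} not found in EDF (available: {available})"
    )


def read_edf(path, channel_labels: list[str]) -> EEGRecord:
    """Read an EDF recording, selecting (or deriving) the given channels.

    Parameters
    ----------
    path
        EDF file path.
    channel_labels
        Requested channels in output order. Bipolar labels like
        ``"FP2-F8"`` match a stored channel of that name if present, else
        are derived by subtracting the two referential channels.

    Returns
    -------
    EEGRecord
        With exactly the requested channels in the requested order,
        samples in microvolts, ``fs`` from the file header and no
        seizure annotations (see :func:`read_chbmit_annotations`).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    header = _read_edf_header(path)
    sources: list[tuple[str, ...]] = [
        _resolve_channel(lab, header["labels"]) for lab in channel_labels
    ]
    needed = sorted({c for src in sources for c in src})
    fs_per = {
        c: header["samples_per_record"][header["labels"].index(c)]
        / header["record_duration"]
        for c in needed
    }
    if len(set(fs_per.values())) > 1:
        raise EDFFormatError(
            f"{path}: requested channels have inconsistent sampling rates {fs_per}"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    ch_index = {name.strip().upper(): i for i, name in enumerate(raw.ch_names)}
    data_v = raw.get_data()

    def get(chan: str) -> np.ndarray:
        return data_v[ch_index[chan.strip().upper()]] * 1e6  # volts -> uV

    rows = []
    for src in sources:
        rows.append(get(src[0]) if len(src) == 1 else get(src[0]) - get(src[1]))
    return EEGRecord(
        signals=np.vstack(rows),
        channel_labels=list(channel_labels),
        fs=float(raw.info["sfreq"]),
        subject_id=path.stem,
    )


# --------------------------------------------------------------------------
# EDF writing (fixtures / simulate output)

def _pad(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _fmt8(value: float) -> str:
    """Format a physical-range bound into EDF's 8-char numeric field."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g"):
        s = fmt % value
        if len(s) <= 8:
            return s
    return ("%.2e" % value)[:8]


def write_edf(record: EEGRecord, path) -> None:
    """Write a record as 16-bit EDF (one-second data records).

    The physical range per channel is the signal min/max (quantization
    step = range / 65535); ``record.duration_s`` must be a whole number
    of seconds and ``fs`` an integer.
    """
    path = Path(path)
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires integer fs, got {fs}")
    spr = int(round(fs))
    if record.n_samples % spr != 0:
        raise ValueError("EDF writer requires an integer number of seconds")
    n_records = record.n_samples // spr
    n_ch = record.n_channels

    digitized, phys_lo, phys_hi = [], [], []
    for sig in record.signals:
        lo, hi = float(sig.min()), float(sig.max())
        if hi <= lo:
            hi = lo + 1.0
        # use the values as they will be re-parsed from the 8-char fields
        lo, hi = float(_fmt8(lo)), float(_fmt8(hi))
        if hi <= lo:
            hi = lo + 1.0
        phys_lo.append(lo)
        phys_hi.append(hi)
        scaled = np.round((sig - lo) / (hi - lo) * 65535.0 - 32768.0)
        digitized.append(np.clip(scaled, -32768, 32767).astype("<i2"))

    hdr = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad(f"Startdate 01-JAN-2020 X X {record.subject_id or 'X'}", 80),
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(256 * (n_ch + 1), 8),
            _pad("", 44),
            _pad(n_records, 8),
            _pad("1", 8),
            _pad(n_ch, 4),
        ]
    )
    hdr += b"".join(_pad(lab, 16) for lab in record.channel_labels)
    hdr += b"".join(_pad("EEG", 80) for _ in range(n_ch))
    hdr += b"".join(_pad("uV", 8) for _ in range(n_ch))
    hdr += b"".join(_pad(_fmt8(v), 8) for v in phys_lo)
    hdr += b"".join(_pad(_fmt8(v), 8) for v in phys_hi)
    hdr += b"".join(_pad(-32768, 8) for _ in range(n_ch))
    hdr += b"".join(_pad(32767, 8) for _ in range(n_ch))
    hdr += b"".join(_pad("", 80) for _ in range(n_ch))
    hdr += b"".join(_pad(spr, 8) for _ in range(n_ch))
    hdr += b"".join(_pad("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            for d in digitized:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())


# --------------------------------------------------------------------------
# CHB-MIT summary annotations

_FILE_RE = re.compile(r"^File Name:\s*(\S+)", re.I)
_NSEIZ_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)", re.I)
_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*sec", re.I)
_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*sec", re.I)


def _norm_record(name: str) -> str:
    name = name.strip()
    return name[:-4] if name.lower().endswith(".edf") else name


def read_chbmit_annotations(path, record_name: str) -> list[SeizureInterval]:
    """Parse seizure intervals for one record from a CHB-MIT summary file.

    Returns the record's intervals sorted by start time; an empty list
    when its block declares no seizures. Raises
    :class:`AnnotationParseError` (with the offending line number) for a
    start without an end or an end not after its start, and
    ``ValueError`` if the record has no block in the file.
    """
    target = _norm_record(record_name)
    intervals: list[SeizureInterval] = []
    current: str | None = None
    seen = False
    pending: tuple[float, int] | None = None  # (start_s, line_no)

    def close_pending() -> None:
        nonlocal pending
        if pending is not None:
            raise AnnotationParseError(
                f"line {pending[1]}: seizure start without matching end time"
            )

    with open(path, encoding="utf-8", errors="replace") as fh:
        for line_no, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            m = _FILE_RE.match(line)
            if m:
                close_pending()
                current = _norm_record(m.group(1))
                seen = seen or current == target
                continue
            if current != target:
                continue
            m = _START_RE.match(line)
            if m:
                close_pending()
                pending = (float(m.group(1)), line_no)
                continue
            m = _END_RE.match(line)
            if m:
                if pending is None:
                    raise AnnotationParseError(
                        f"line {line_no}: seizure end without a preceding start"
                    )
                t1, start_line = pending
                t2 = float(m.group(1))
                if t2 <= t1:
                    raise AnnotationParseError(
                        f"line {line_no}: seizure end {t2} s not after start {t1} s"
                    )
                intervals.append(SeizureInterval(t1, t2))
                pending = None
    close_pending()
    if not seen:
        raise ValueError(f"record {record_name!r} not found in summary file {path}")
    return sorted(intervals, key=lambda s: s.t1)


def write_chbmit_summary(path, entries: list[tuple[str, list[SeizureInterval]]],
                         fs: float = 256.0) -> None:
    """Write a summary file in the CHB-MIT dialect (integer-second times)."""
    lines = [f"Data Sampling Rate: {int(round(fs))} Hz", ""]
    for record_name, seizures in entries:
        name = _norm_record(record_name) + ".edf"
        lines += [f"File Name: {name}",
                  f"Number of Seizures in File: {len(seizures)}"]
        for k, s in enumerate(seizures, start=1):
            lines += [
                f"Seizure {k} Start Time: {int(round(s.t1))} seconds",
                f"Seizure {k} End Time: {int(round(s.t2))} seconds",
            ]
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
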