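"""STFT spectrograms and fused RGB time-frequency images.

Each 180 s, 3-channel segment becomes one 224x224x3 image: per channel,
a magnitude spectrogram from a 413-sample tapered window (207 one-sided
frequency bins), log-scaled, min-max normalized to [0, 1], resized from
207x224 to 224x224 bilinearly, then stacked with FP2-F8 as red, F8-T8
as green and T8-P8 as blue.

Frame convention: no padding and no mean removal; the window advances by
``hop_samples`` so a segment of ``n`` samples yields
``floor((n - win) / hop) + 1`` frames. The default hop of 204 samples
(overlap 209/413, about 50.6%) is the largest hop that turns a
46080-sample segment (180 s at 256 Hz) into exactly 224 frames, giving
the canonical 207x224 spectrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window
from skimage.transform import resize as _sk_resize

__all__ = ["StftConfig", "TFImage", "stft_magnitude", "to_tf_image",
           "freq_to_row", "save_png"]

IMAGE_SIZE = 224  # output image height and width
RGB_CHANNEL_ORDER = ("FP2-F8", "F8-T8", "T8-P8")  # red, green, blue


@dataclass
class StftConfig:
    """STFT parameters; defaults give a 207x224 spectrogram at 256 Hz.

    ``window_fn`` is any scipy window name (``"hann"`` default,
    ``"boxcar"`` for rectangular). ``log_scale`` applies log10 to the
    magnitude with an ``eps`` floor before min-max normalization.
    """

    win_samples: int = 413
    hop_samples: int = 204
    window_fn: str = "hann"
    fs: float = 256.0
    log_scale: bool = True
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if not 0 < self.hop_samples <= self.win_samples:
            raise ValueError(
                f"need 0 < hop ({self.hop_samples}) <= win ({self.win_samples})"
            )

    @property
    def n_freq_bins(self) -> int:
        return self.win_samples // 2 + 1

    def n_frames(self, n_samples: int) -> int:
        return (n_samples - self.win_samples) // self.hop_samples + 1

    def taper(self) -> np.ndarray:
        return get_window(self.window_fn, self.win_samples, fftbins=True)


@dataclass
class TFImage:
    """A fused 224x224x3 time-frequency image with its binary label."""

    pixels: np.ndarray  # (224, 224, 3) float32 in [0, 1]
    label: int
    record_ref: str = ""
    start_s: float = 0.0
    source: str = "sliding"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(f"expected {IMAGE_SIZE}x{IMAGE_SIZE}x3 pixels, "
                             f"got {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("non-finite pixel values")


def stft_magnitude(signal: np.ndarray, config: StftConfig) -> np.ndarray:
    """Magnitude STFT of a 1-D signal: shape (freq_bins, frames).

    Frames are the tapered windows at ``k * hop_samples``; a one-sided
    rFFT gives ``win // 2 + 1`` frequency bins. The signal must be at
    least one window long.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"signal must be 1-D, got shape {x.shape}")
    if len(x) < config.win_samples:
        raise ValueError(
            f"signal of {len(x)} samples shorter than STFT window "
            f"({config.win_samples})"
        )
    frames = sliding_window_view(x, config.win_samples)[:: config.hop_samples]
    return np.abs(np.fft.rfft(frames * config.taper(), axis=1)).T


def _normalize_plane(mag: np.ndarray, config: StftConfig) -> np.ndarray:
    plane = np.log10(mag + config.eps) if config.log_scale else mag
    lo, hi = plane.min(), plane.max()
    if hi <= lo:
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def to_tf_image(segment: np.ndarray, config: StftConfig, label: int,
                record_ref: str = "", start_s: float = 0.0,
                source: str = "sliding") -> TFImage:
    """Fuse a 3-channel segment into one RGB time-frequency image.

    Channel order is fixed (FP2-F8 red, F8-T8 green, T8-P8 blue). Each
    plane is min-max normalized independently and resized bilinearly to
    224x224; rows are flipped so frequency runs low to high from the
    image bottom.
    """
    seg = np.asarray(segment, dtype=np.float64)
    if seg.ndim != 2 or seg.shape[0] != 3:
        raise ValueError(f"segment must have shape (3, n_samples), got {seg.shape}")
    planes = []
    for ch in seg:
        plane = _normalize_plane(stft_magnitude(ch, config), config)
        plane = _sk_resize(plane, (IMAGE_SIZE, IMAGE_SIZE), order=1,
                           mode="edge", anti_aliasing=False,
                           preserve_range=True)
        planes.append(plane[::-1])  # low frequencies at the bottom row
    pixels = np.clip(np.stack(planes, axis=-1), 0.0, 1.0)
    return TFImage(pixels=pixels, label=int(label), record_ref=record_ref,
                   start_s=start_s, source=source)


def freq_to_row(freq_hz: float, config: StftConfig,
                image_height: int = IMAGE_SIZE) -> int:
    """Image row (after the low-at-bottom flip) closest to a frequency.

    Maps through the spectrogram bin grid (bin = f * win / fs) and the
    207 -> 224 resize.
    """
    bin_idx = freq_hz * config.win_samples / config.fs
    row = round(bin_idx * (image_height - 1) / (config.n_freq_bins - 1))
    row = min(max(row, 0), image_height - 1)
    return int(image_height - 1 - row)


def save_png(image: TFImage, path) -> None:
    """Export as 8-bit RGB PNG (quantizes the [0, 1] pixel range)."""
    from PIL import Image

    arr = np.round(image.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
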