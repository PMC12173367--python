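"""Kaiser-window short-time Fourier spectrograms of beat segments.

The window length is 0.2 s and the hop 0.01 s of the (nominal) sampling
rate, both rounded to whole samples.  Frames are taken without any
zero-padding of the segment, and the full N-point DFT magnitude is kept,
so a 288-sample beat at 360 Hz becomes a 72 x 55 image and an 864-sample
context becomes 72 x 199; segments resized to 400/1200 at a nominal
500 Hz become 100 x 61 and 100 x 221.  Row r and row N-r are complex
conjugates for real input; both are retained because the classifier
consumes the full square-ish image, but a one-sided view is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0

__all__ = ["StftConfig", "Spectrogram", "kaiser_window", "stft_spectrogram"]


@dataclass(frozen=True)
class StftConfig:
    window_seconds: float = 0.2
    hop_seconds: float = 0.01
    kaiser_alpha: float = 3.0
    magnitude_mode: str = "linear"  # or "log"

    def __post_init__(self):
        if not (self.window_seconds > self.hop_seconds > 0):
            raise ValueError("need window_seconds > hop_seconds > 0")
        if self.kaiser_alpha < 0:
            raise ValueError("kaiser_alpha must be >= 0")
        if self.magnitude_mode not in ("linear", "log"):
            raise ValueError("magnitude_mode must be 'linear' or 'log'")

    def window_len(self, sampling_rate: float) -> int:
        return int(np.floor(self.window_seconds * sampling_rate + 0.5))

    def hop(self, sampling_rate: float) -> int:
        return int(np.floor(self.hop_seconds * sampling_rate + 0.5))


@dataclass
class Spectrogram:
    """Magnitude time-frequency matrix: rows = frequency bins, cols = frames."""

    values: np.ndarray
    window_len: int
    hop: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def kaiser_window(N: int, alpha: float) -> np.ndarray:
    """Kaiser taper w(n) = I0(pi*alpha*sqrt(1-(2n/(N-1)-1)^2)) / I0(pi*alpha).

    Symmetric with peak value 1 at the center; alpha = 0 degenerates to the
    rectangular window.
    """
    if N < 1:
        raise ValueError("window length must be >= 1")
    if N == 1:
        return np.ones(1)
    n = np.arange(N)
    arg = 1.0 - (2.0 * n / (N - 1) - 1.0) ** 2
    arg = np.clip(arg, 0.0, None)  # guard fp dust at the ends
    return i0(np.pi * alpha * np.sqrt(arg)) / i0(np.pi * alpha)


def frame_count(n_samples: int, window_len: int, hop: int) -> int:
    """Number of full frames: floor((L - win)/hop) + 1."""
    if n_samples < window_len:
        raise ValueError(
            f"segment of {n_samples} samples is shorter than one window ({window_len})"
        )
    return (n_samples - window_len) // hop + 1


def stft_spectrogram(
    segment: np.ndarray, sampling_rate: float, cfg: StftConfig = StftConfig()
) -> Spectrogram:
    """Magnitude STFT with a Kaiser window and no segment padding.

    Frame t covers samples [t*hop, t*hop + window_len); each frame is
    tapered and passed through an N-point DFT with N = window_len, and all
    N magnitude bins are kept as rows.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("stft_spectrogram expects a 1-D segment")
    win = cfg.window_len(sampling_rate)
    hop = cfg.hop(sampling_rate)
    if hop < 1:
        raise ValueError("hop rounds to zero samples at this sampling rate")
    n_frames = frame_count(segment.size, win, hop)
    frames = np.lib.stride_tricks.sliding_window_view(segment, win)[:: hop][:n_frames]
    tapered = frames * kaiser_window(win, cfg.kaiser_alpha)
    mag = np.abs(np.fft.fft(tapered, n=win, axis=1)).T  # (bins, frames)
    if cfg.magnitude_mode == "log":
        mag = np.log1p(mag)
    return Spectrogram(values=mag, window_len=win, hop=hop)
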