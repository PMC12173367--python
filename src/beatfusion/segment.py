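"""Dual-scale beat segmentation around R-peaks.

Every training sample pairs a single-cycle window with a three-cycle
window sharing the same center R-peak.  Two conventions exist:

* **fixed** (360 Hz layout): 143 samples left / 144 right of the R sample
  for one cycle (288 total, R included in the left count) and 431/432 for
  three cycles (864 total).  The single-cycle window is exactly the middle
  third of the three-cycle window.
* **adaptive** (500 Hz layout): the per-record cycle length is
  ``Ns = 60 / Hr * Sr`` from the record's heart rate; crops take
  round(Ns/2) resp. round(3*Ns/2) samples per side (round-half-up) and are
  bicubically resized to fixed lengths (defaults 400 and 1200).

Beats whose three-cycle window would run off the record are skipped (at
both scales, keeping the pairing intact) and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .resize import resize_1d

__all__ = [
    "DualScaleSample",
    "SegmentationResult",
    "FIXED_SINGLE_LEFT",
    "FIXED_SINGLE_RIGHT",
    "FIXED_THREE_LEFT",
    "FIXED_THREE_RIGHT",
    "crop_fixed",
    "adaptive_cycle_length",
    "crop_adaptive",
    "build_samples",
    "record_heart_rate",
]

FIXED_SINGLE_LEFT, FIXED_SINGLE_RIGHT = 143, 144
FIXED_THREE_LEFT, FIXED_THREE_RIGHT = 431, 432


@dataclass
class DualScaleSample:
    single_cycle: np.ndarray
    three_cycle: np.ndarray
    center_r: int
    label: str
    augmented: bool = False


@dataclass
class SegmentationResult:
    samples: list[DualScaleSample]
    n_skipped: int = 0
    skipped_centers: list[int] = field(default_factory=list)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def crop_fixed(sig: np.ndarray, r_index: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Fixed-length crops: 288-sample single cycle, 864-sample three cycle.

    Returns None when the three-cycle window does not fit in the signal;
    callers count such beats as skipped.
    """
    if r_index - FIXED_THREE_LEFT < 0 or r_index + FIXED_THREE_RIGHT >= len(sig):
        return None
    single = np.array(sig[r_index - FIXED_SINGLE_LEFT : r_index + FIXED_SINGLE_RIGHT + 1])
    three = np.array(sig[r_index - FIXED_THREE_LEFT : r_index + FIXED_THREE_RIGHT + 1])
    return single, three


def adaptive_cycle_length(heart_rate_bpm: float, sampling_rate: float) -> float:
    """Samples per cardiac cycle, Ns = (60 / heart-rate) * sampling-rate."""
    if heart_rate_bpm <= 0:
        raise ValueError("heart rate must be positive")
    return 60.0 / heart_rate_bpm * sampling_rate


def crop_adaptive(
    sig: np.ndarray, r_index: int, ns: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Heart-rate-adaptive crops: round(Ns/2) and round(3*Ns/2) samples per side.

    Rounding is half-up.  Returns None (skip) if the three-cycle window is
    out of range or Ns is degenerate (< 8 samples per side).
    """
    half_single = _round_half_up(ns / 2.0)
    half_three = _round_half_up(3.0 * ns / 2.0)
    if half_single < 4:
        return None
    if r_index - half_three < 0 or r_index + half_three > len(sig):
        return None
    single = np.array(sig[r_index - half_single : r_index + half_single])
    three = np.array(sig[r_index - half_three : r_index + half_three])
    return single, three


def record_heart_rate(r_peaks: np.ndarray, sampling_rate: float) -> float:
    """Per-record heart rate in bpm from the median R-R interval."""
    r_peaks = np.asarray(r_peaks)
    if r_peaks.size < 2:
        raise ValueError("need at least two R-peaks to estimate heart rate")
    median_rr = float(np.median(np.diff(r_peaks)))
    return 60.0 * sampling_rate / median_rr


def build_samples(
    sig: np.ndarray,
    r_peaks: np.ndarray,
    labels,
    mode: str = "fixed",
    sampling_rate: float | None = None,
    resize_targets: tuple[int, int] = (400, 1200),
    heart_rate_bpm: float | None = None,
) -> SegmentationResult:
    """Segment one record into dual-scale samples.

    In adaptive mode the cycle length comes from ``heart_rate_bpm`` if
    given, otherwise from the record's median R-R interval, and each crop
    is resized to ``resize_targets``.
    """
    r_peaks = np.asarray(r_peaks)
    labels = list(labels)
    if len(labels) != r_peaks.size:
        raise ValueError("one label per R-peak required")
    if mode not in ("fixed", "adaptive"):
        raise ValueError("mode must be 'fixed' or 'adaptive'")

    ns = None
    if mode == "adaptive":
        if sampling_rate is None:
            raise ValueError("adaptive mode needs the sampling rate")
        hr = heart_rate_bpm if heart_rate_bpm is not None else record_heart_rate(r_peaks, sampling_rate)
        ns = adaptive_cycle_length(hr, sampling_rate)

    result = SegmentationResult(samples=[])
    for r, lab in zip(r_peaks, labels):
        crop = crop_fixed(sig, int(r)) if mode == "fixed" else crop_adaptive(sig, int(r), ns)
        if crop is None:
            result.n_skipped += 1
            result.skipped_centers.append(int(r))
            continue
        single, three = crop
        if mode == "adaptive":
            single = resize_1d(single, resize_targets[0])
            three = resize_1d(three, resize_targets[1])
        result.samples.append(
            DualScaleSample(single_cycle=single, three_cycle=three, center_r=int(r), label=lab)
        )
    return result
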