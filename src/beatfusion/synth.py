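"""Synthetic single-lead ECG with known R-peaks, labels, and noise.

Each beat class is a sum of Gaussian bumps (P, Q, R, S, T waves) whose
amplitudes/widths/offsets differ per class, so classes are separable by
construction and every ground-truth quantity (peak index, label, clean
signal) is available to downstream tests.  Records carry three optional
noise terms mimicking common acquisition artefacts: sinusoidal baseline
wander, powerline (mains) interference, and broadband Gaussian noise
standing in for EMG.

This generator is deliberately phenomenological: it is not a dynamical
model of the heart and produces a single lead only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WaveParams",
    "BeatMorphology",
    "SynthConfig",
    "SynthRecord",
    "generate_record",
    "generate_dataset",
    "DEFAULT_MORPHOLOGIES",
]


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian bump: amplitude (mV), center offset from R (s), width (s)."""

    amp: float
    offset: float
    width: float


@dataclass(frozen=True)
class BeatMorphology:
    """A beat template as a list of waves; the R wave must dominate |amplitude|."""

    waves: tuple[WaveParams, ...]

    def render(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t)
        for w in self.waves:
            out += w.amp * np.exp(-0.5 * ((t - w.offset) / w.width) ** 2)
        return out

    @property
    def r_amp(self) -> float:
        return max(self.waves, key=lambda w: abs(w.amp)).amp


def _morph(p, q, r, s, t, *, qrs_w=0.02, t_w=0.06, p_off=-0.2, t_off=0.3) -> BeatMorphology:
    return BeatMorphology(
        waves=(
            WaveParams(p, p_off, 0.025),
            WaveParams(q, -0.045, qrs_w),
            WaveParams(r, 0.0, qrs_w),
            WaveParams(s, 0.045, qrs_w),
            WaveParams(t, t_off, t_w),
        )
    )


#: Default class templates, loosely evoking the AAMI beat groups: a normal
#: beat, a supraventricular beat (small/absent P, low R), a ventricular beat
#: (wide, large QRS, no P), a fusion beat (intermediate width and height),
#: and an unclassifiable/paced beat (small R, broad T).  The classes are
#: abstract identifiers and may be re-mapped onto any scheme.
DEFAULT_MORPHOLOGIES: dict[str, BeatMorphology] = {
    "N": _morph(0.15, -0.12, 1.00, -0.25, 0.30),
    "S": _morph(0.02, -0.05, 0.65, -0.12, 0.18, t_off=0.26),
    "V": _morph(0.00, -0.30, 1.45, -0.60, -0.35, qrs_w=0.05, t_w=0.09, t_off=0.34),
    "F": _morph(0.05, -0.18, 0.85, -0.40, 0.12, qrs_w=0.035),
    "Q": _morph(0.08, -0.04, 0.45, -0.08, 0.40, t_w=0.11, t_off=0.38),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic record.

    heart-rate jitter is a fraction: each R-R interval is the nominal
    interval scaled by ``1 + U(-jitter, +jitter)``.
    """

    sampling_rate: float = 360.0
    n_beats: int = 100
    heart_rate_bpm: float = 72.0
    hr_jitter: float = 0.1
    class_labels: tuple[str, ...] = ("N", "S", "V", "F", "Q")
    class_proportions: tuple[float, ...] | None = None
    morphologies: dict[str, BeatMorphology] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGIES)
    )
    baseline_amp: float = 0.10
    baseline_freq: float = 0.3
    powerline_amp: float = 0.02
    powerline_freq: float = 50.0
    broadband_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if not (0 <= self.hr_jitter < 0.5):
            raise ValueError("hr_jitter must lie in [0, 0.5)")
        for name, amp in (
            ("baseline_amp", self.baseline_amp),
            ("powerline_amp", self.powerline_amp),
            ("broadband_sigma", self.broadband_sigma),
        ):
            if amp < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = set(self.class_labels) - set(self.morphologies)
        if missing:
            raise ValueError(f"no morphology for classes: {sorted(missing)}")
        if self.class_proportions is not None:
            if len(self.class_proportions) != len(self.class_labels):
                raise ValueError("class_proportions must match class_labels")
            if not np.isclose(sum(self.class_proportions), 1.0):
                raise ValueError("class_proportions must sum to 1")


@dataclass
class SynthRecord:
    """A generated record with ground truth attached."""

    samples: np.ndarray
    sampling_rate: float
    r_peaks: np.ndarray
    beat_labels: list[str]
    clean_samples: np.ndarray
    record_id: str = "synth"

    def __post_init__(self):
        assert len(self.beat_labels) == len(self.r_peaks)
        assert np.all(np.diff(self.r_peaks) > 0)
        assert self.r_peaks.size == 0 or (
            self.r_peaks[0] >= 0 and self.r_peaks[-1] < len(self.samples)
        )


def generate_record(config: SynthConfig) -> SynthRecord:
    """Render one record: beat templates placed at jittered R-R intervals plus noise.

    The same config (including seed) always yields bit-identical output.
    ``clean_samples`` is the template sum before any noise is added.
    """
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)

    nominal_rr = 60.0 / config.heart_rate_bpm * fs
    jit = rng.uniform(-config.hr_jitter, config.hr_jitter, size=config.n_beats)
    rr = nominal_rr * (1.0 + jit)
    # first beat sits one nominal cycle in so it has left context
    r_times = np.cumsum(np.concatenate([[nominal_rr], rr[:-1]]))
    r_peaks = np.round(r_times).astype(int)

    if config.class_proportions is not None:
        labels = list(
            rng.choice(config.class_labels, size=config.n_beats, p=config.class_proportions)
        )
    else:
        labels = [config.class_labels[i % len(config.class_labels)] for i in range(config.n_beats)]
        rng.shuffle(labels)

    n_samples = int(r_peaks[-1] + round(1.5 * nominal_rr))
    t = np.arange(n_samples) / fs
    clean = np.zeros(n_samples)
    for r, lab in zip(r_peaks, labels):
        clean += config.morphologies[lab].render(t - r / fs)

    noise = np.zeros(n_samples)
    if config.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noise += config.baseline_amp * np.sin(2 * np.pi * config.baseline_freq * t + phase)
    if config.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noise += config.powerline_amp * np.sin(2 * np.pi * config.powerline_freq * t + phase)
    if config.broadband_sigma > 0:
        noise += rng.normal(0.0, config.broadband_sigma, size=n_samples)

    return SynthRecord(
        samples=clean + noise,
        sampling_rate=fs,
        r_peaks=r_peaks,
        beat_labels=labels,
        clean_samples=clean,
        record_id=f"synth-{config.seed}",
    )


def generate_dataset(config: SynthConfig, n_records: int) -> list[SynthRecord]:
    """Generate ``n_records`` records with distinct seeds derived from config.seed."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_records)
    out = []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        rec = generate_record(replace(config, seed=seed))
        rec.record_id = f"synth-{config.seed}-{i:03d}"
        out.append(rec)
    return out
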