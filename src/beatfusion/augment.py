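"""Mixup oversampling of minority beat classes.

New samples are convex combinations of two parents,

    x_mix = eps * x_a + (1 - eps) * x_b,   y_mix = eps * y_a + (1 - eps) * y_b,

with eps drawn from a Beta(1, 1) distribution, i.e. uniform on [0, 1].
Mixing acts on the three-cycle signal; the paired single-cycle signal is
re-extracted as the central window of the mixed three-cycle signal, which
by linearity equals the eps-mix of the parents' single cycles.

By default parents are drawn within one class, so generated labels stay
hard and per-class counts follow the exact law
``n_new(c) = round(ratio_c * n_c)`` (round-half-up).  The default ratios
oversample the supraventricular (1.0), ventricular (0.5) and fusion (2.0)
classes.  Cross-class mixing with genuinely soft labels is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segment import DualScaleSample

__all__ = ["MixupConfig", "MixedSample", "mixup_pair", "augment_training_set"]

DEFAULT_RATIOS = {"S": 1.0, "V": 0.5, "F": 2.0}


@dataclass(frozen=True)
class MixupConfig:
    beta_a: float = 1.0
    beta_b: float = 1.0
    class_ratios: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATIOS))
    intra_class: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta parameters must be positive")
        if any(r < 0 for r in self.class_ratios.values()):
            raise ValueError("generation ratios must be >= 0")


@dataclass
class MixedSample:
    single_cycle: np.ndarray
    three_cycle: np.ndarray
    soft_label: dict[str, float]
    epsilon: float
    augmented: bool = True

    @property
    def label(self) -> str:
        """Hardened label (argmax); exact for intra-class mixing."""
        return max(self.soft_label, key=self.soft_label.get)


def mixup_pair(a: DualScaleSample, b: DualScaleSample, epsilon: float) -> MixedSample:
    """Mix two dual-scale samples with coefficient ``epsilon`` in [0, 1]."""
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must lie in [0, 1]")
    if a.three_cycle.shape != b.three_cycle.shape or a.single_cycle.shape != b.single_cycle.shape:
        raise ValueError("parents must have equal segment lengths")
    three = epsilon * a.three_cycle + (1.0 - epsilon) * b.three_cycle
    n_single = a.single_cycle.size
    off = (three.size - n_single) // 2
    single = three[off : off + n_single].copy()
    soft: dict[str, float] = {}
    soft[a.label] = soft.get(a.label, 0.0) + epsilon
    soft[b.label] = soft.get(b.label, 0.0) + (1.0 - epsilon)
    return MixedSample(single_cycle=single, three_cycle=three, soft_label=soft, epsilon=epsilon)


def augment_training_set(samples: list[DualScaleSample], cfg: MixupConfig = MixupConfig()):
    """Append round(ratio_c * n_c) mixed samples per class; originals untouched.

    Parents of each pair are two distinct same-class samples (or, with
    ``intra_class=False``, any two distinct samples); pairs are drawn with
    replacement across pairs by a seeded generator.
    """
    rng = np.random.default_rng(cfg.seed)
    by_class: dict[str, list[DualScaleSample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)

    out: list = list(samples)
    for cls in sorted(cfg.class_ratios):
        ratio = cfg.class_ratios[cls]
        if ratio == 0 or cls not in by_class:
            continue
        pool = by_class[cls] if cfg.intra_class else samples
        if len(pool) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 samples for Mixup")
        n_new = int(np.floor(ratio * len(by_class[cls]) + 0.5))
        for _ in range(n_new):
            i, j = rng.choice(len(pool), size=2, replace=False)
            eps = float(rng.beta(cfg.beta_a, cfg.beta_b))
            out.append(mixup_pair(pool[i], pool[j], eps))
    return out
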