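"""Mixup: convex endpoints, the per-class count law, and coefficient distribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beatfusion.augment import MixupConfig, augment_training_set, mixup_pair
from beatfusion.segment import DualScaleSample


def _sample(label, rng, n_single=6, n_three=18):
    return DualScaleSample(
        single_cycle=rng.normal(size=n_single),
        three_cycle=rng.normal(size=n_three),
        center_r=0,
        label=label,
    )


@pytest.fixture()
def parents(rng):
    return _sample("S", rng), _sample("V", rng)


def test_epsilon_one_returns_first_parent(parents):
    a, b = parents
    m = mixup_pair(a, b, 1.0)
    np.testing.assert_array_equal(m.three_cycle, a.three_cycle)
    assert m.soft_label["S"] == 1.0


def test_epsilon_zero_returns_second_parent(parents):
    a, b = parents
    m = mixup_pair(a, b, 0.0)
    np.testing.assert_array_equal(m.three_cycle, b.three_cycle)
    assert m.soft_label["V"] == 1.0


def test_opposite_signals_cancel_at_half(rng):
    a = _sample("S", rng)
    b = DualScaleSample(-a.single_cycle, -a.three_cycle, 0, "S")
    m = mixup_pair(a, b, 0.5)
    np.testing.assert_allclose(m.three_cycle, 0.0, atol=1e-12)


def test_single_cycle_is_central_window_of_mixed_three(parents):
    a, b = parents
    m = mixup_pair(a, b, 0.3)
    np.testing.assert_allclose(m.three_cycle[6:12], m.single_cycle)


def test_length_mismatch_rejected(rng):
    a = _sample("S", rng)
    b = _sample("S", rng, n_three=20)
    with pytest.raises(ValueError):
        mixup_pair(a, b, 0.5)


@settings(max_examples=30, deadline=None)
@given(eps=st.floats(0.0, 1.0), seed=st.integers(0, 100))
def test_mixed_values_are_convex_combinations(eps, seed):
    r = np.random.default_rng(seed)
    a, b = _sample("S", r), _sample("S", r)
    m = mixup_pair(a, b, eps)
    lo = np.minimum(a.three_cycle, b.three_cycle) - 1e-12
    hi = np.maximum(a.three_cycle, b.three_cycle) + 1e-12
    assert np.all(m.three_cycle >= lo) and np.all(m.three_cycle <= hi)
    assert sum(m.soft_label.values()) == pytest.approx(1.0)


def test_training_set_count_law_matches_generation_ratios(rng):
    # ratios (S:1, V:0.5, F:2) on counts (2486, 6459, 718) -> (4972, 9689, 2154)
    pool = (
        [_sample("N", rng) for _ in range(100)]
        + [_sample("S", rng) for _ in range(2486)]
        + [_sample("V", rng) for _ in range(6459)]
        + [_sample("F", rng) for _ in range(718)]
    )
    out = augment_training_set(pool, MixupConfig(seed=0))
    counts = {c: sum(s.label == c for s in out) for c in "NSVF"}
    assert counts == {"N": 100, "S": 4972, "V": 9689, "F": 2154}
    # originals are untouched, appended samples carry the provenance flag
    assert all(o is p_ for o, p_ in zip(out, pool))
    assert all(s.augmented for s in out[len(pool) :])


def test_zero_ratios_are_identity(rng):
    pool = [_sample("S", rng) for _ in range(5)]
    out = augment_training_set(pool, MixupConfig(class_ratios={}))
    assert len(out) == len(pool) and all(o is p_ for o, p_ in zip(out, pool))


def test_ratio_one_on_two_member_class(rng):
    pool = [_sample("F", rng), _sample("F", rng)]
    out = augment_training_set(pool, MixupConfig(class_ratios={"F": 1.0}, seed=3))
    assert len(out) == 4


def test_small_class_with_positive_ratio_rejected(rng):
    with pytest.raises(ValueError):
        augment_training_set([_sample("F", rng)], MixupConfig(class_ratios={"F": 1.0}))


def test_intra_class_mixing_keeps_hard_labels(rng):
    pool = [_sample("S", rng) for _ in range(10)]
    out = augment_training_set(pool, MixupConfig(class_ratios={"S": 1.0}, seed=2))
    for s in out[10:]:
        assert s.soft_label == {"S": 1.0} or set(s.soft_label) == {"S"}


def test_epsilon_distribution_is_uniform():
    # Beta(1,1) = U(0,1): Kolmogorov-Smirnov on 10,000 draws
    from scipy import stats

    rng = np.random.default_rng(0)
    pool = [_sample("S", rng) for _ in range(4)]
    cfg = MixupConfig(class_ratios={"S": 2500.0}, seed=5)
    out = augment_training_set(pool, cfg)
    eps = np.array([s.epsilon for s in out[4:]])
    assert eps.size == 10_000
    assert stats.kstest(eps, "uniform").pvalue > 0.01
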