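"""Window arithmetic of the dual-scale crops and the adaptive resize path."""

import numpy as np
import pytest

from beatfusion import synth
from beatfusion.segment import (
    adaptive_cycle_length,
    build_samples,
    crop_adaptive,
    crop_fixed,
    record_heart_rate,
)
from beatfusion.resize import resize_1d


def test_fixed_crop_lengths_and_centering():
    sig = np.arange(2000, dtype=float)
    single, three = crop_fixed(sig, 1000)
    assert single.size == 288 and three.size == 864
    # single cycle is the middle third of the three-cycle window
    np.testing.assert_array_equal(three[288:576], single)
    assert single[143] == 1000  # the R sample itself


def test_fixed_crop_boundary_fits_exactly():
    sig = np.arange(864, dtype=float)
    single, three = crop_fixed(sig, 431)
    np.testing.assert_array_equal(three, sig)


def test_out_of_range_beat_is_skipped_not_raised():
    sig = np.zeros(1000)
    assert crop_fixed(sig, 100) is None
    assert crop_fixed(sig, 900) is None


@pytest.mark.parametrize(
    "hr,sr,expected", [(75.0, 500.0, 400.0), (60.0, 360.0, 360.0), (100.0, 500.0, 300.0)]
)
def test_adaptive_cycle_length_formula(hr, sr, expected):
    assert adaptive_cycle_length(hr, sr) == pytest.approx(expected)


def test_adaptive_cycle_length_rejects_nonpositive_rate():
    with pytest.raises(ValueError):
        adaptive_cycle_length(0.0, 500.0)


def test_adaptive_crop_lengths_round_half_up():
    sig = np.zeros(5000)
    single, three = crop_adaptive(sig, 2500, 400.0)
    assert single.size == 2 * 200 and three.size == 2 * 600
    # Ns = 401: round-half-up gives 201 and 602 samples per side
    single, three = crop_adaptive(sig, 2500, 401.0)
    assert single.size == 402 and three.size == 1204


def test_degenerate_cycle_is_rejected():
    assert crop_adaptive(np.zeros(5000), 2500, 1.0) is None


def test_record_heart_rate_from_median_rr():
    peaks = np.arange(10) * 360  # 360 samples at 360 Hz = 60 bpm
    assert record_heart_rate(peaks, 360.0) == pytest.approx(60.0)


def test_build_samples_fixed_counts_and_skips():
    rec = synth.generate_record(synth.SynthConfig(seed=5, n_beats=30, hr_jitter=0.0,
                                                  heart_rate_bpm=72.0))
    res = build_samples(rec.samples, rec.r_peaks, rec.beat_labels, mode="fixed")
    # first beat sits 300 samples in: lacks the 431-sample left context
    assert res.n_skipped == 1
    assert res.skipped_centers == [int(rec.r_peaks[0])]
    assert len(res.samples) == 29
    assert all(s.single_cycle.size == 288 and s.three_cycle.size == 864 for s in res.samples)


def test_build_samples_adaptive_shapes_for_any_heart_rate():
    for hr in (55.0, 75.0, 110.0):
        rec = synth.generate_record(
            synth.SynthConfig(seed=2, n_beats=25, heart_rate_bpm=hr, sampling_rate=500.0)
        )
        res = build_samples(rec.samples, rec.r_peaks, rec.beat_labels, mode="adaptive",
                            sampling_rate=500.0)
        assert res.samples, f"no samples at {hr} bpm"
        assert all(s.single_cycle.size == 400 for s in res.samples)
        assert all(s.three_cycle.size == 1200 for s in res.samples)


def test_build_samples_validates_inputs():
    with pytest.raises(ValueError):
        build_samples(np.zeros(100), np.array([50]), ["N", "V"])
    with pytest.raises(ValueError):
        build_samples(np.zeros(100), np.array([50]), ["N"], mode="bogus")


# --- bicubic resize ---------------------------------------------------------


def test_resize_reproduces_constants():
    np.testing.assert_allclose(resize_1d(np.full(33, 2.5), 100), 2.5, atol=1e-12)


def test_resize_linear_ramp_stays_monotone_with_exact_endpoints():
    ramp = np.linspace(0.0, 1.0, 100)
    out = resize_1d(ramp, 400)
    assert out[0] == pytest.approx(0.0, abs=1e-6)
    assert out[-1] == pytest.approx(1.0, abs=1e-6)
    assert np.all(np.diff(out) >= -1e-12)


def test_resize_identity_length():
    x = np.sin(np.arange(50) * 0.3)
    np.testing.assert_allclose(resize_1d(x, 50), x, atol=1e-9)


def test_resize_rejects_short_inputs():
    with pytest.raises(ValueError):
        resize_1d(np.zeros(3), 100)
    with pytest.raises(ValueError):
        resize_1d(np.zeros(10), 3)
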