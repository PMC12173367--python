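"""Metric formulas against hand counts and a brute-force recount oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beatfusion.evaluate import (
    ConfusionMatrix,
    ablation_report,
    confusion_matrix,
    evaluate_predictions,
    f1_score,
    macro_scores,
    per_class_metrics,
)


def test_confusion_matrix_hand_count():
    cm = confusion_matrix(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
    np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])


def test_perfect_predictions_are_diagonal():
    y = ["N", "S", "V", "N", "S"]
    cm = confusion_matrix(y, y, ["N", "S", "V"])
    assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
    rep = per_class_metrics(cm)
    assert rep.overall_acc == 100.0
    assert all(v == 100.0 for v in rep.f1[:2])  # classes with support
    assert rep.macro_f1 <= 100.0


def test_empty_input_gives_zero_matrix():
    cm = confusion_matrix([], [], ["a", "b"])
    assert cm.counts.sum() == 0
    with pytest.raises(ValueError):
        per_class_metrics(cm)


def test_unknown_label_rejected():
    with pytest.raises(ValueError):
        confusion_matrix(["x"], ["x"], ["a", "b"])


def _brute_force(counts, classes):
    """Independent recount: loop over samples and one-vs-rest tabulations."""
    pairs = [
        (i, j) for i in range(len(classes)) for j in range(len(classes))
        for _ in range(counts[i][j])
    ]
    out = {}
    for c in range(len(classes)):
        tp = sum(1 for t, p in pairs if t == c and p == c)
        fn = sum(1 for t, p in pairs if t == c and p != c)
        fp = sum(1 for t, p in pairs if t != c and p == c)
        tn = sum(1 for t, p in pairs if t != c and p != c)
        sen = tp / (tp + fn) * 100 if tp + fn else 0.0
        ppv = tp / (tp + fp) * 100 if tp + fp else 0.0
        out[classes[c]] = {
            "acc": (tp + tn) / len(pairs) * 100,
            "sen": sen,
            "ppv": ppv,
            "f1": 2 * ppv * sen / (ppv + sen) if ppv + sen else 0.0,
        }
    return out


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10**6))
def test_metrics_match_bruteforce_recount(seed):
    rng = np.random.default_rng(seed)
    classes = ["w", "x", "y", "z"]
    counts = rng.integers(0, 12, size=(4, 4))
    if counts.sum() == 0:
        counts[0, 0] = 1
    rep = per_class_metrics(ConfusionMatrix(counts=counts, classes=classes))
    oracle = _brute_force(counts.tolist(), classes)
    for i, c in enumerate(classes):
        for key, arr in (("acc", rep.acc), ("sen", rep.sen), ("ppv", rep.ppv), ("f1", rep.f1)):
            assert arr[i] == pytest.approx(oracle[c][key], abs=1e-9)


def test_macro_scores_are_arithmetic_means():
    rng = np.random.default_rng(0)
    cm = ConfusionMatrix(counts=rng.integers(1, 30, size=(5, 5)), classes=list("abcde"))
    rep = per_class_metrics(cm)
    ms, mp, mf = macro_scores(rep)
    assert ms == pytest.approx(np.mean(rep.sen))
    assert mp == pytest.approx(np.mean(rep.ppv))
    assert mf == pytest.approx(np.mean(rep.f1))


def test_single_class_macro_is_the_class_value():
    cm = ConfusionMatrix(counts=np.array([[7]]), classes=["only"])
    rep = per_class_metrics(cm)
    assert rep.macro_f1 == rep.f1[0]


def test_zero_denominator_flagged_not_crashed():
    # class b never occurs and is never predicted -> sen and ppv undefined
    cm = ConfusionMatrix(counts=np.array([[5, 0], [0, 0]]), classes=["a", "b"])
    rep = per_class_metrics(cm)
    assert rep.sen[1] == 0.0 and rep.ppv[1] == 0.0
    assert any("b" in f for f in rep.zero_division_flags)


def test_f1_is_harmonic_mean():
    assert f1_score(76.25, 92.42) == pytest.approx(83.5599, abs=1e-3)
    assert f1_score(0.0, 0.0) == 0.0


def test_ablation_report_rows_and_validation():
    y = ["N"] * 5 + ["V"] * 5
    rep1 = evaluate_predictions(y, y, ["N", "V"])
    rep2 = evaluate_predictions(y, ["N"] * 10, ["N", "V"])
    rows = ablation_report({"full": rep1, "no_se": rep2})
    assert [r["variant"] for r in rows] == ["full", "no_se"]
    assert rows[0]["macro_f1"] >= rows[1]["macro_f1"]
    with pytest.raises(ValueError):
        ablation_report({"only": rep1})
    rep3 = evaluate_predictions(["a", "b"], ["a", "b"], ["a", "b"])
    with pytest.raises(ValueError):
        ablation_report({"full": rep1, "other": rep3})


def test_identical_variants_identical_rows():
    y_true = ["N", "V", "N", "V"]
    y_pred = ["N", "N", "N", "V"]
    r = evaluate_predictions(y_true, y_pred, ["N", "V"])
    rows = ablation_report({"a": r, "b": r})
    assert {k: v for k, v in rows[0].items() if k != "variant"} == {
        k: v for k, v in rows[1].items() if k != "variant"
    }
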