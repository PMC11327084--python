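"""Dice loss, confusion counting, metric formulas, grouped means, overlays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bfnet.losses_metrics import (
    ConfusionCounts,
    MetricsReport,
    class_metrics,
    confusion,
    dice_coefficient,
    dice_loss,
    grouped_mean,
    image_metrics,
    overlay,
    FN_COLOR,
    FP_COLOR,
    TP_COLOR,
)


def loop_dice_loss(p, t, eps=1e-6):
    num = den = 0.0
    for pi, ti in zip(p.ravel(), t.ravel()):
        num += pi * ti
        den += pi * pi + ti * ti
    return 1.0 - (2.0 * num + eps) / (den + eps)


def loop_confusion(pred, t):
    tp = fp = fn = tn = 0
    for pi, ti in zip(pred.ravel(), t.ravel()):
        if pi and ti:
            tp += 1
        elif pi and not ti:
            fp += 1
        elif not pi and ti:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def test_dice_loss_zero_on_perfect_binary_prediction(rng):
    t = (rng.random((8, 8)) > 0.7).astype(np.float32)
    assert dice_loss(t, t).item() == pytest.approx(0.0, abs=1e-6)


def test_dice_loss_one_on_disjoint_supports():
    p = np.zeros((4, 4), np.float32)
    t = np.zeros((4, 4), np.float32)
    p[:2] = 1.0
    t[2:] = 1.0
    assert dice_loss(p, t).item() == pytest.approx(1.0, abs=1e-6)


def test_dice_loss_matches_loop_oracle(rng):
    p = rng.random((8, 8)).astype(np.float64)
    t = (rng.random((8, 8)) > 0.5).astype(np.float64)
    assert dice_loss(p, t).item() == pytest.approx(loop_dice_loss(p, t), abs=1e-7)


def test_dice_loss_rejects_bad_inputs(rng):
    with pytest.raises(ValueError, match="shape"):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError, match="binary"):
        dice_loss(np.zeros((2, 2)), np.full((2, 2), 0.5))


@settings(deadline=None, max_examples=50)
@given(
    t=arrays(np.int8, (6, 6), elements=st.integers(0, 1)),
    p=arrays(np.int8, (6, 6), elements=st.integers(0, 1)),
)
def test_dice_loss_binary_properties(p, t):
    """In [0, 1]; symmetric for binary arguments; dual to the Dice metric."""
    pf = p.astype(np.float32)
    tf = t.astype(np.float32)
    loss = dice_loss(pf, tf).item()
    assert -1e-6 <= loss <= 1.0 + 1e-6
    assert loss == pytest.approx(dice_loss(tf, pf).item(), abs=1e-6)
    assert 1.0 - loss == pytest.approx(dice_coefficient(p, t), abs=1e-5)


def test_confusion_all_ones():
    ones = np.ones((4, 4), np.uint8)
    c = confusion(ones, ones)
    assert (c.tp, c.fp, c.fn, c.tn) == (16, 0, 0, 0)


def test_confusion_complement_prediction(rng):
    t = (rng.random((5, 5)) > 0.5).astype(np.uint8)
    c = confusion(1 - t, t)
    assert c.tp == 0 and c.tn == 0
    assert c.fp + c.fn == 25


def test_confusion_matches_loop_and_conserves_pixels(rng):
    pred = (rng.random((9, 7)) > 0.4).astype(np.uint8)
    t = (rng.random((9, 7)) > 0.6).astype(np.uint8)
    c = confusion(pred, t)
    assert (c.tp, c.fp, c.fn, c.tn) == loop_confusion(pred, t)
    assert c.total == 63


def test_metrics_perfect_prediction(rng):
    t = (rng.random((8, 8)) > 0.7).astype(np.uint8)
    m = image_metrics(t, t)
    assert m == {"dice": 1.0, "miou": 100.0, "mpa": 100.0, "mprecision": 100.0}


def test_metrics_empty_prediction_on_nonempty_truth():
    t = np.zeros((4, 4), np.uint8)
    t[1, 1] = 1
    m = class_metrics(confusion(np.zeros_like(t), t))
    assert m["iou_foreground"] == 0.0


def test_metrics_hand_computed_toy_confusion():
    # tp=6, fp=2, fn=3, tn=89 on a 10x10 image
    c = ConfusionCounts(tp=6, fp=2, fn=3, tn=89)
    m = class_metrics(c)
    assert m["iou_foreground"] == pytest.approx(6 / 11)
    assert m["pa_foreground"] == pytest.approx(6 / 9)
    assert m["precision_foreground"] == pytest.approx(6 / 8)
    assert m["iou_background"] == pytest.approx(89 / 94)
    assert m["pa_background"] == pytest.approx(89 / 91)
    assert m["precision_background"] == pytest.approx(89 / 92)


def test_m_metrics_bounded_by_class_metrics(rng):
    pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    t = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    m = class_metrics(confusion(pred, t))
    full = image_metrics(pred, t)
    for key in ("iou", "pa", "precision"):
        lo = min(m[f"{key}_foreground"], m[f"{key}_background"])
        hi = max(m[f"{key}_foreground"], m[f"{key}_background"])
        name = {"iou": "miou", "pa": "mpa", "precision": "mprecision"}[key]
        assert 100 * lo - 1e-9 <= full[name] <= 100 * hi + 1e-9


def test_grouped_mean_constant_scores():
    assert grouped_mean([0.7] * 20) == pytest.approx(0.7)


def test_grouped_mean_two_groups():
    assert grouped_mean([1.0] * 10 + [0.0] * 10) == pytest.approx(0.5)


def test_grouped_mean_partial_final_group(rng):
    scores = rng.random(25).tolist()
    groups = [scores[0:10], scores[10:20], scores[20:25]]
    expected = np.mean([np.mean(g) for g in groups])
    assert grouped_mean(scores) == pytest.approx(expected, abs=1e-12)


def test_grouped_mean_equals_plain_mean_for_full_groups(rng):
    scores = rng.random(30).tolist()
    assert grouped_mean(scores) == pytest.approx(np.mean(scores), abs=1e-12)


def test_metrics_report_roundtrip(tmp_path, rng):
    per_image = [
        {"id": f"s{i}", "dice": float(rng.random()), "miou": float(rng.random()),
         "mpa": float(rng.random()), "mprecision": float(rng.random())}
        for i in range(15)
    ]
    report = MetricsReport.from_per_image(per_image, group_size=10)
    csv_path = tmp_path / "per_image.csv"
    report.to_csv(csv_path)
    import csv as csv_mod

    with open(csv_path) as fh:
        rows = list(csv_mod.DictReader(fh))
    recomputed = grouped_mean([float(r["dice"]) for r in rows], 10)
    assert recomputed == pytest.approx(report.dice, abs=1e-12)
    report.to_json(tmp_path / "metrics.json")
    import json

    assert json.loads((tmp_path / "metrics.json").read_text())["dice"] == report.dice


def test_overlay_color_rules():
    t = np.zeros((2, 2), np.uint8)
    t[0, :] = 1  # truth: top row
    pred = np.zeros((2, 2), np.uint8)
    pred[:, 0] = 1  # prediction: left column
    img = np.full((2, 2), 0.5, np.float32)
    out = overlay(pred, t, img)
    assert tuple(out[0, 0]) == TP_COLOR
    assert tuple(out[0, 1]) == FN_COLOR
    assert tuple(out[1, 0]) == FP_COLOR
    assert tuple(out[1, 1]) == (127, 127, 127)  # true negative: image shows through


def test_overlay_perfect_prediction_only_purple(rng):
    t = (rng.random((6, 6)) > 0.5).astype(np.uint8)
    out = overlay(t, t, rng.random((6, 6)).astype(np.float32))
    assert (out[t.astype(bool)] == TP_COLOR).all()
    assert (out == FN_COLOR).all(axis=2).sum() == 0
    assert (out == FP_COLOR).all(axis=2).sum() == 0


def test_overlay_empty_prediction_only_yellow(rng):
    t = (rng.random((6, 6)) > 0.5).astype(np.uint8)
    out = overlay(np.zeros_like(t), t, rng.random((6, 6)).astype(np.float32))
    assert (out[t.astype(bool)] == FN_COLOR).all()
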