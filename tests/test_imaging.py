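"""Tests of the whole-slide imaging cascade."""

import numpy as np
import pytest

from lessel import config, imaging, synthdata
from lessel.imaging import (
    BBox,
    TrainConfig,
    bce_with_logits,
    calibrate_threshold,
    detection_loss,
    dice_bce_loss,
    iou,
    nms_filter,
    qc_classify,
    remove_background,
    route_by_size,
    run_slide,
    segment_cell,
    tile_wsi,
    train_detector,
)


def _flat_slide(h, w, color=(235, 233, 228)):
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = color
    return img


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def test_tile_exact_grid():
    patches = tile_wsi(_flat_slide(1024, 2048))
    assert len(patches) == 2
    assert [p.origin for p in patches] == [(0, 0), (1024, 0)]
    assert not any(p.padded for p in patches)


def test_tile_remainder_padded_and_flagged():
    patches = tile_wsi(_flat_slide(1024, 1500))
    assert len(patches) == 2
    assert patches[1].pad == (1024 - 476, 0)
    assert patches[1].pixels.shape == (1024, 1024, 3)


def test_tile_reassembly_is_exact(rng):
    wsi = rng.integers(0, 255, (1100, 2200, 3), dtype=np.uint8)
    patches = tile_wsi(wsi)
    rebuilt = np.zeros_like(wsi)
    for p in patches:
        x, y = p.origin
        h = p.pixels.shape[0] - p.pad[1]
        w = p.pixels.shape[1] - p.pad[0]
        rebuilt[y:y + h, x:x + w] = p.pixels[:h, :w]
    assert np.array_equal(rebuilt, wsi)


# ---------------------------------------------------------------------------
# geometry and losses
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    (BBox(0, 0, 2, 2), BBox(0, 0, 2, 2), 1.0),
    (BBox(0, 0, 2, 2), BBox(5, 5, 2, 2), 0.0),
    (BBox(0, 0, 2, 2), BBox(1, 0, 2, 2), 1 / 3),
])
def test_iou_cases(a, b, expected):
    assert iou(a, b) == pytest.approx(expected)
    assert iou(b, a) == pytest.approx(expected)


def test_detection_loss_closed_forms():
    a, b = BBox(0, 0, 2, 2), BBox(1, 0, 2, 2)
    zeros = np.zeros(0)
    _, perfect, _, _ = detection_loss([a], [a], zeros, zeros, zeros, zeros)
    assert perfect == pytest.approx(0.0)
    _, disjoint, _, _ = detection_loss([a], [BBox(9, 9, 2, 2)], zeros, zeros, zeros, zeros)
    assert disjoint == pytest.approx(1.0)
    _, third, _, _ = detection_loss([a], [b], zeros, zeros, zeros, zeros)
    assert third == pytest.approx(8 / 9)
    # no foreground boxes: the IoU term vanishes by convention
    total, l_iou, _, _ = detection_loss([], [], zeros, zeros, zeros, zeros)
    assert l_iou == 0.0 and total == 0.0


def test_detection_loss_composition():
    a = BBox(0, 0, 2, 2)
    obj_logits, obj_t = np.array([0.0, 2.0]), np.array([1.0, 1.0])
    cls_logits, cls_t = np.array([-1.0]), np.array([0.0])
    total, l_iou, l_obj, l_cls = detection_loss(
        [a], [a], obj_logits, obj_t, cls_logits, cls_t, lambda_reg=0.5)
    assert l_obj == pytest.approx(bce_with_logits(obj_logits, obj_t))
    assert total == pytest.approx(0.5 * l_iou + l_obj + l_cls)


def test_dice_bce_closed_forms():
    # confident correct prediction: Dice term ~0
    truth = np.zeros((4, 4))
    truth[:2] = 1.0
    logits = np.where(truth > 0, 50.0, -50.0)
    assert dice_bce_loss(logits, truth) == pytest.approx(0.0, abs=1e-9)
    # confident complement: Dice coefficient 0, Dice term 1
    comp = np.where(truth > 0, -50.0, 50.0)
    assert dice_bce_loss(comp, truth) == pytest.approx(
        bce_with_logits(comp, truth) + 1.0, abs=1e-9)
    # uniform 0.5 prediction on a half-ones mask:
    # BCE = ln 2; Dice = 2*(0.5*N/2)/(0.5N + N/2) = 0.5
    half = dice_bce_loss(np.zeros((4, 4)), truth)
    assert half == pytest.approx(np.log(2.0) + 0.5, abs=1e-9)


# ---------------------------------------------------------------------------
# NMS
# ---------------------------------------------------------------------------

def _nms_oracle(boxes, conf_min=0.3, iou_max=0.5):
    """Independent exhaustive suppression: sort, then all-pairs checks."""
    order = sorted(range(len(boxes)),
                   key=lambda i: (-boxes[i].confidence, i))
    kept = []
    for i in order:
        b = boxes[i]
        if b.confidence <= conf_min:
            continue
        suppressed = False
        for k in kept:
            if iou(b, k) > iou_max:
                suppressed = True
                break
        if not suppressed:
            kept.append(b)
    return kept


def test_nms_simple_cases():
    solo = BBox(0, 0, 10, 10, 0.9)
    assert nms_filter([solo]) == [solo]
    dup = BBox(0, 0, 10, 10, 0.8)
    assert nms_filter([dup, solo]) == [solo]
    assert nms_filter([BBox(0, 0, 10, 10, 0.2)]) == []


def test_nms_matches_bruteforce_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(1, 26))
        boxes = [BBox(float(rng.uniform(0, 80)), float(rng.uniform(0, 80)),
                      float(rng.uniform(5, 30)), float(rng.uniform(5, 30)),
                      float(rng.uniform(0, 1))) for _ in range(n)]
        got = nms_filter(boxes)
        assert got == _nms_oracle(boxes)
        for i in range(len(got)):
            for j in range(i + 1, len(got)):
                assert iou(got[i], got[j]) <= 0.5


# ---------------------------------------------------------------------------
# trained-stage behavior (shared small models)
# ---------------------------------------------------------------------------

def test_detector_recall_on_validation(trained_models):
    assert trained_models.detector.validation_recall >= 0.85


def test_detector_empty_on_background(trained_models):
    patch = _flat_slide(1024, 1024)
    assert trained_models.detector.predict(patch) == []


def test_detector_training_deterministic():
    rng = np.random.default_rng(0)
    patches, gt = [], []
    for _ in range(3):
        spec = synthdata.SyntheticSlideSpec(n_cells=8, true_etc_fraction=25.0,
                                            junk_fraction=0.25,
                                            seed=int(rng.integers(2 ** 31)))
        wsi, ann = synthdata.render_slide(spec)
        patches.append(wsi)
        gt.append([BBox(*a["bbox"]) for a in ann])
    d1 = train_detector(patches, gt, TrainConfig(seed=5))
    d2 = train_detector(patches, gt, TrainConfig(seed=5))
    assert d1.validation_recall == d2.validation_recall
    assert d1.validation_precision == d2.validation_precision
    assert d1.fg_threshold == d2.fg_threshold


def test_qc_probabilities_and_heldout_accuracy(trained_models):
    rng = np.random.default_rng(777)
    correct = total = 0
    for cat in config.QC_CATEGORIES:
        for _ in range(5):
            label = "benign" if cat == "high_quality" else cat
            img, mask = synthdata.render_object(label, int(rng.integers(2 ** 31)))
            crop, _ = synthdata.object_crop(img, mask)
            verdict = qc_classify(crop, trained_models.qc)
            assert verdict.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(verdict.probabilities >= 0)
            total += 1
            correct += verdict.category == cat
    assert correct / total >= 0.9


def test_qc_rejects_nucleus_only(trained_models):
    img, mask = synthdata.render_object("nucleus_only", 31)
    crop, _ = synthdata.object_crop(img, mask)
    assert not qc_classify(crop, trained_models.qc).passed


def test_segmenter_dice_and_empty_flag(trained_models):
    assert trained_models.segmenter.validation_dice >= 0.85
    empty = segment_cell(_flat_slide(80, 80), trained_models.segmenter)
    assert not empty.any()


def test_remove_background_idempotent(trained_models):
    img, mask = synthdata.render_object("benign", 13)
    crop, cmask = synthdata.object_crop(img, mask)
    fill = np.array([10, 20, 30], dtype=np.uint8)
    once = remove_background(crop, cmask, fill)
    twice = remove_background(once, cmask, fill)
    assert np.array_equal(once, twice)
    assert np.all(once[~cmask] == fill)


@pytest.mark.parametrize("side,expected", [(60, "small"), (90, "small"), (200, "large")])
def test_route_by_size(side, expected):
    mask = np.zeros((300, 300), dtype=bool)
    mask[10:10 + side, 10:10 + side] = True
    assert route_by_size(mask) == expected


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def test_calibrate_threshold_separable_gap():
    scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
    labels = np.array([0, 0, 0, 1, 1])
    thr = calibrate_threshold(scores, labels, spec_min=0.99)
    assert thr == pytest.approx(0.8)   # smallest qualifying observed score


def _threshold_oracle(scores, labels, spec_min):
    benign = scores[labels == 0]
    best = None
    for t in np.sort(np.unique(scores)):
        if (benign < t).mean() >= spec_min:
            best = t
            break
    return best if best is not None else scores.max() + 1e-6


def test_calibrate_threshold_matches_sweep_oracle(rng):
    scores = rng.beta(2, 2, 1000)
    labels = (rng.random(1000) < 0.3).astype(int)
    scores[labels == 1] += 0.2
    for spec_min in (0.9, 0.99, 0.998, 1.0):
        assert calibrate_threshold(scores, labels, spec_min) == pytest.approx(
            _threshold_oracle(scores, labels, spec_min))


def test_calibrate_threshold_specificity_by_construction(rng):
    scores = rng.random(600)
    labels = (rng.random(600) < 0.4).astype(int)
    thr = calibrate_threshold(scores, labels, spec_min=0.998)
    benign = scores[labels == 0]
    assert (benign < thr).mean() >= 0.998


def test_calibrate_threshold_single_class_errors():
    with pytest.raises(ValueError):
        calibrate_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def test_run_slide_background_only(trained_models):
    slide, records, counts = run_slide(_flat_slide(1024, 1024), trained_models)
    assert slide.n_total_cells == 0 and slide.n_predicted_etc == 0
    assert not slide.call


def test_run_slide_counts_monotone(trained_models):
    spec = synthdata.SyntheticSlideSpec(n_cells=12, true_etc_fraction=25.0,
                                        junk_fraction=0.25, seed=21)
    wsi, _ = synthdata.render_slide(spec)
    slide, records, counts = run_slide(wsi, trained_models)
    assert counts["boxes"] >= counts["qc_pass"] >= counts["segmented"] \
        >= counts["classified"] >= counts["etc"]
    assert slide.n_total_cells == counts["qc_pass"]
    assert slide.etc_percent == pytest.approx(
        100 * slide.n_predicted_etc / slide.n_total_cells)
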