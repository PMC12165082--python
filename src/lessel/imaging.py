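"""Whole-slide cytology arm: tile, detect, QC, segment, route, classify.

The cascade runs in the fixed order

    tile (1024 px patches) -> detect candidate cells -> confidence filter
    (> 0.3) + NMS (IoU > 0.5 suppressed) -> 7-class QC (only high-quality
    single cells continue) -> segmentation to a uniform background ->
    size routing (longer mask side > 90 px = large channel) -> dual-channel
    malignancy classification calibrated to >= 99.8% specificity.

Models are compact seeded classical learners (scikit-learn estimators over
scikit-image features): a color-distance proposal generator with a learned
confidence model for detection, a random forest over morphometric/texture
features for QC, a pixel-wise logistic classifier for segmentation, and
regularized logistic models per size channel. The detection and
segmentation training losses used by gradient-trained detectors in this
setting — the squared-IoU loss and Dice+BCE — are provided as exact numpy
formulas (:func:`detection_loss`, :func:`dice_bce_loss`).

Pixel coordinates are 0-based, x right / y down; boxes are half-open
[x, x+w) x [y, y+h).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import config
from .diagnosis import SlideResult

log = logging.getLogger("lessel.imaging")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    """One 1024x1024 tile of a slide with its global offset."""

    pixels: np.ndarray
    origin: tuple[int, int]             # (x, y), 0-based
    pad: tuple[int, int] = (0, 0)       # (pad_x, pad_y) of padded extent

    @property
    def padded(self) -> bool:
        return self.pad != (0, 0)


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, half-open, with a detection confidence."""

    x: float
    y: float
    w: float
    h: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box must have positive width and height")

    @property
    def area(self) -> float:
        return self.w * self.h

    def shifted(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x + dx, self.y + dy, self.w, self.h, self.confidence)


@dataclass(frozen=True)
class QcVerdict:
    category: str
    probabilities: np.ndarray           # 7-vector over config.QC_CATEGORIES

    @property
    def passed(self) -> bool:
        return self.category == "high_quality"


@dataclass(frozen=True)
class CellRecord:
    """Provenance of one cell through the cascade."""

    patch_index: int
    box: BBox
    qc: QcVerdict
    channel: str | None = None          # large | small
    score: float | None = None
    call: bool | None = None


@dataclass(frozen=True)
class TrainConfig:
    split_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    epochs: int = 20
    batch_size: int = 8
    lr_schedule: str = "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def modal_border_color(img: np.ndarray) -> np.ndarray:
    """Modal (median) color of the 2-px image border; used for padding/fill."""
    border = np.concatenate([
        img[:2].reshape(-1, 3), img[-2:].reshape(-1, 3),
        img[:, :2].reshape(-1, 3), img[:, -2:].reshape(-1, 3),
    ])
    return np.median(border, axis=0)


def tile_wsi(wsi: np.ndarray, patch_size: int = config.PATCH_SIZE,
             fill: np.ndarray | None = None) -> list[Patch]:
    """Non-overlapping ceil-grid tiling, row-major.

    Right/bottom remainders are padded with the slide's modal border color
    and flagged with their pad extent; reassembling the unpadded regions
    reproduces the raster exactly.
    """
    if wsi.ndim != 3 or wsi.shape[0] < 1 or wsi.shape[1] < 1:
        raise ValueError("expected a non-empty HxWx3 raster")
    H, W = wsi.shape[:2]
    fill = modal_border_color(wsi) if fill is None else fill
    patches = []
    for y in range(0, H, patch_size):
        for x in range(0, W, patch_size):
            tile = wsi[y:y + patch_size, x:x + patch_size]
            pad_y = patch_size - tile.shape[0]
            pad_x = patch_size - tile.shape[1]
            if pad_x or pad_y:
                canvas = np.empty((patch_size, patch_size, 3), dtype=wsi.dtype)
                canvas[:] = fill.astype(wsi.dtype)
                canvas[:tile.shape[0], :tile.shape[1]] = tile
                tile = canvas
            patches.append(Patch(tile, (x, y), (pad_x, pad_y)))
    return patches


# ---------------------------------------------------------------------------
# geometry and losses
# ---------------------------------------------------------------------------

def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = max(0.0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy on logits (numerically stable form)."""
    logits = np.asarray(logits, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if logits.shape != targets.shape:
        raise ValueError("logits and targets must have the same shape")
    loss = np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    return float(loss.mean()) if loss.size else 0.0


def detection_loss(
    pred_boxes: Sequence[BBox],
    gt_boxes: Sequence[BBox],
    objectness_logits: np.ndarray,
    objectness_targets: np.ndarray,
    class_logits: np.ndarray,
    class_targets: np.ndarray,
    lambda_reg: float = config.DETECT_LAMBDA_REG,
) -> tuple[float, float, float, float]:
    """Detection training loss: lambda_reg * L_IoU + L_obj + L_cls.

    L_IoU averages 1 - IoU^2 over matched foreground box pairs (0 when
    there are none); objectness and class terms are BCE on logits.
    Returns (total, iou_term, objectness_term, class_term).
    """
    if len(pred_boxes) != len(gt_boxes):
        raise ValueError("pred and ground-truth foreground boxes must pair up")
    n_fg = len(pred_boxes)
    if n_fg:
        l_iou = float(np.mean([1.0 - iou(p, g) ** 2 for p, g in zip(pred_boxes, gt_boxes)]))
    else:
        l_iou = 0.0
    l_obj = bce_with_logits(objectness_logits, objectness_targets)
    l_cls = bce_with_logits(class_logits, class_targets)
    total = lambda_reg * l_iou + l_obj + l_cls
    return total, l_iou, l_obj, l_cls


def dice_bce_loss(mask_logits: np.ndarray, truth: np.ndarray) -> float:
    """Segmentation loss: mean BCE on logits plus (1 - Dice coefficient).

    Dice is computed on sigmoid probabilities: 2*sum(p*t) / (sum(p)+sum(t)).
    """
    mask_logits = np.asarray(mask_logits, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if mask_logits.shape != truth.shape:
        raise ValueError("shape mismatch between logits and truth mask")
    p = 1.0 / (1.0 + np.exp(-mask_logits))
    denom = p.sum() + truth.sum()
    dice = 2.0 * (p * truth).sum() / denom if denom > 0 else 1.0
    return bce_with_logits(mask_logits, truth) + (1.0 - dice)


def nms_filter(boxes: Sequence[BBox], conf_min: float = config.DETECT_CONF_MIN,
               iou_max: float = config.NMS_IOU_MAX) -> list[BBox]:
    """Confidence filter then greedy non-maximum suppression.

    Boxes with confidence <= ``conf_min`` are dropped; the rest are visited
    in descending confidence and a box is suppressed when its IoU with an
    already-kept box exceeds ``iou_max``. Ties in confidence keep input
    order. The kept set is pairwise IoU <= ``iou_max``.
    """
    cand = [b for b in boxes if b.confidence > conf_min]
    cand.sort(key=lambda b: -b.confidence)
    kept: list[BBox] = []
    for b in cand:
        if all(iou(b, k) <= iou_max for k in kept):
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# foreground / feature helpers
# ---------------------------------------------------------------------------

def _color_distance(img: np.ndarray, color: np.ndarray) -> np.ndarray:
    return np.linalg.norm(img.astype(float) - color, axis=-1)


def _grayscale(img: np.ndarray) -> np.ndarray:
    return img.astype(float).mean(axis=-1)


def _resize_crop(crop: np.ndarray, side: int) -> np.ndarray:
    return resize(crop.astype(float), (side, side, 3), order=1,
                  preserve_range=True, anti_aliasing=True)


# ---------------------------------------------------------------------------
# detector
# ---------------------------------------------------------------------------

@dataclass
class Detector:
    """Proposal-plus-confidence cell detector.

    Proposals are connected components of pixels whose color distance to the
    slide background exceeds a learned threshold; a logistic model over
    region features supplies the confidence scored against IoU-0.5 matches
    to ground truth.
    """

    bg_color: np.ndarray
    fg_threshold: float
    conf_model: object
    min_area: int = 80
    validation_recall: float | None = None
    validation_precision: float | None = None

    def propose(self, patch: np.ndarray) -> tuple[list[BBox], np.ndarray]:
        dist = _color_distance(patch, self.bg_color)
        binary = dist > self.fg_threshold
        binary = ndimage.binary_opening(binary, np.ones((3, 3)))
        lab = cc_label(binary)
        boxes, feats = [], []
        for r in regionprops(lab, intensity_image=dist):
            if r.area < self.min_area:
                continue
            y0, x0, y1, x1 = r.bbox
            boxes.append(BBox(x0, y0, x1 - x0, y1 - y0))
            feats.append(_region_features(r))
        return boxes, np.array(feats) if feats else np.empty((0, 6))

    def predict(self, patch: np.ndarray, conf_min: float = config.DETECT_CONF_MIN,
                iou_max: float = config.NMS_IOU_MAX) -> list[BBox]:
        boxes, feats = self.propose(patch)
        if not boxes:
            return []
        conf = self.conf_model.predict_proba(feats)[:, 1]
        scored = [BBox(b.x, b.y, b.w, b.h, float(c)) for b, c in zip(boxes, conf)]
        return nms_filter(scored, conf_min, iou_max)


def _region_features(r) -> list[float]:
    y0, x0, y1, x1 = r.bbox
    w, h = x1 - x0, y1 - y0
    return [
        np.log(r.area),
        float(r.intensity_mean),
        float(r.intensity_max),
        r.area / (w * h),                       # extent
        max(w, h) / min(w, h),                  # aspect
        float(r.solidity),
    ]


def train_detector(
    patches: Sequence[np.ndarray],
    gt_boxes: Sequence[Sequence[BBox]],
    cfg: TrainConfig = TrainConfig(),
    thresholds: Sequence[float] = (20.0, 30.0, 45.0, 60.0),
) -> Detector:
    """Fit the detector on annotated patches (9:1 train/validation split).

    The foreground threshold is chosen by proposal F1 against ground truth
    on the training split; the confidence model is a logistic regression on
    region features labeled by IoU >= 0.5 match to a ground-truth box.
    Validation recall/precision at the operating point are stored on the
    model.
    """
    if not patches:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(patches))
    n_val = max(1, len(patches) // 10) if len(patches) > 1 else 0
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    bg = modal_border_color(patches[train_idx[0]])

    def proposal_f1(thr: float) -> float:
        det = Detector(bg, thr, None)
        tp = fp = fn = 0
        for i in train_idx:
            boxes, _ = det.propose(patches[i])
            matched = _match_boxes(boxes, gt_boxes[i])
            tp += sum(m >= 0 for m in matched)
            fp += sum(m < 0 for m in matched)
            fn += len(gt_boxes[i]) - len({m for m in matched if m >= 0})
        denom = 2 * tp + fp + fn
        return 2 * tp / denom if denom else 0.0

    fg_thr = max(thresholds, key=proposal_f1)
    det = Detector(bg, fg_thr, None)
    X, y = [], []
    for i in train_idx:
        boxes, feats = det.propose(patches[i])
        matched = _match_boxes(boxes, gt_boxes[i])
        for f, m in zip(feats, matched):
            X.append(f)
            y.append(int(m >= 0))
    if len(set(y)) < 2:
        # degenerate but trainable: constant-probability model
        model = _ConstantProba(float(np.mean(y)) if y else 1.0)
    else:
        model = make_pipeline(StandardScaler(),
                              LogisticRegression(max_iter=1000, random_state=cfg.seed))
        model.fit(np.array(X), np.array(y))
    det.conf_model = model
    # validation metrics at the operating point
    tp = fp = fn = 0
    for i in (val_idx if len(val_idx) else train_idx):
        pred = det.predict(patches[i])
        matched = _match_boxes(pred, gt_boxes[i])
        tp += sum(m >= 0 for m in matched)
        fp += sum(m < 0 for m in matched)
        fn += len(gt_boxes[i]) - len({m for m in matched if m >= 0})
    det.validation_recall = tp / (tp + fn) if tp + fn else 1.0
    det.validation_precision = tp / (tp + fp) if tp + fp else 1.0
    return det


class _ConstantProba:
    def __init__(self, p: float):
        self.p = p

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])


def _match_boxes(pred: Sequence[BBox], gt: Sequence[BBox],
                 min_iou: float = 0.5) -> list[int]:
    """Greedy one-to-one matching; returns gt index per prediction or -1."""
    taken: set[int] = set()
    out = []
    for p in pred:
        best, best_iou = -1, min_iou
        for j, g in enumerate(gt):
            if j in taken:
                continue
            v = iou(p, g)
            if v >= best_iou:
                best, best_iou = j, v
        if best >= 0:
            taken.add(best)
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# QC model
# ---------------------------------------------------------------------------

def _qc_features(crop: np.ndarray, bg_color: np.ndarray) -> np.ndarray:
    """Morphometric/texture features of a crop resized to 224x224."""
    img = _resize_crop(crop, config.QC_INPUT_SIZE)
    dist = _color_distance(img, bg_color)
    fg = dist > 25.0
    gray = _grayscale(img)
    lap = ndimage.laplace(gray)
    area_frac = fg.mean()
    fg_any = fg.any()
    nucleus_like = _color_distance(img, np.array(config_nucleus_rgb())) < 70.0
    nuc_in_fg = (nucleus_like & fg).sum() / max(1, fg.sum())
    # distinct nucleus blobs (clump signature)
    nuc_open = ndimage.binary_opening(nucleus_like, np.ones((5, 5)))
    n_nuclei = int(cc_label(nuc_open).max())
    side_touch = [fg[0, :].mean(), fg[-1, :].mean(), fg[:, 0].mean(), fg[:, -1].mean()]
    brightness = gray[fg].mean() if fg_any else gray.mean()
    sat = img.max(axis=-1) - img.min(axis=-1)
    return np.array([
        area_frac,
        nuc_in_fg,
        float(n_nuclei),
        max(side_touch),
        float(np.mean(side_touch)),
        float(np.var(lap)),                       # blur: low variance
        float(np.abs(lap[fg]).mean()) if fg_any else 0.0,
        brightness,
        float(sat[fg].mean()) if fg_any else 0.0,
        float(gray[fg].std()) if fg_any else 0.0,
        float(dist[fg].mean()) if fg_any else 0.0,
        float(ndimage.binary_fill_holes(fg).mean() - area_frac),  # hole mass
    ])


def config_nucleus_rgb() -> tuple[int, int, int]:
    # late import keeps imaging independent of the generator's palette at
    # call sites that pass their own colors
    from .synthdata import NUCLEUS_RGB
    return NUCLEUS_RGB


@dataclass
class QcModel:
    bg_color: np.ndarray
    clf: RandomForestClassifier
    classes: tuple[str, ...]
    validation_accuracy: float | None = None


def train_qc(crops: Sequence[np.ndarray], labels: Sequence[str],
             cfg: TrainConfig = TrainConfig()) -> QcModel:
    """Fit the 7-class QC model (7:3 train/validation split)."""
    if not crops:
        raise ValueError("empty QC training set")
    bg = np.array(_most_common_border(crops))
    X = np.array([_qc_features(c, bg) for c in crops])
    y = np.array(labels)
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(X))
    n_train = max(1, int(0.7 * len(X)))
    tr, va = idx[:n_train], idx[n_train:]
    clf = RandomForestClassifier(n_estimators=200, random_state=cfg.seed)
    clf.fit(X[tr], y[tr])
    acc = float((clf.predict(X[va]) == y[va]).mean()) if len(va) else None
    return QcModel(bg, clf, tuple(clf.classes_), acc)


def _most_common_border(crops: Sequence[np.ndarray]) -> np.ndarray:
    return np.median([modal_border_color(c) for c in crops], axis=0)


def qc_classify(crop: np.ndarray, model: QcModel) -> QcVerdict:
    """Classify a crop into the seven QC categories (resized to 224 first)."""
    feats = _qc_features(crop, model.bg_color).reshape(1, -1)
    proba_model = model.clf.predict_proba(feats)[0]
    probs = np.zeros(len(config.QC_CATEGORIES))
    for p, cls in zip(proba_model, model.classes):
        cat = cls if cls in config.QC_CATEGORIES else "high_quality"
        probs[config.QC_CATEGORIES.index(cat)] += p
    probs = probs / probs.sum()
    return QcVerdict(config.QC_CATEGORIES[int(np.argmax(probs))], probs)


#: slide annotation labels mapped onto QC training categories
def qc_label_for(annotation_label: str) -> str:
    return "high_quality" if annotation_label in ("benign", "malignant") \
        else annotation_label


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class Segmenter:
    """Pixel-wise logistic cell/background classifier.

    Resolution-independent, so masks are predicted at native crop size; the
    prediction keeps the largest connected foreground component with holes
    filled. Validation Dice is stored at fit time.
    """

    clf: object
    validation_dice: float | None = None

    def predict_mask(self, crop: np.ndarray) -> np.ndarray:
        X = crop.reshape(-1, 3).astype(float)
        p = self.clf.predict_proba(X)[:, 1].reshape(crop.shape[:2])
        binary = p > 0.5
        if not binary.any():
            return binary
        lab = cc_label(binary)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        return ndimage.binary_fill_holes(lab == largest)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 1.0


def train_segmenter(crops: Sequence[np.ndarray], masks: Sequence[np.ndarray],
                    cfg: TrainConfig = TrainConfig(),
                    pixels_per_crop: int = 1500) -> Segmenter:
    """Fit the segmenter on (crop, truth mask) pairs (9:1 split)."""
    if not crops:
        raise ValueError("empty segmentation training set")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(crops))
    n_val = max(1, len(crops) // 10) if len(crops) > 1 else 0
    va, tr = idx[:n_val], idx[n_val:]
    X, y = [], []
    for i in tr:
        flat = crops[i].reshape(-1, 3).astype(float)
        lab = masks[i].ravel().astype(int)
        take = rng.choice(len(flat), size=min(pixels_per_crop, len(flat)), replace=False)
        X.append(flat[take])
        y.append(lab[take])
    clf = make_pipeline(StandardScaler(),
                        LogisticRegression(max_iter=1000, random_state=cfg.seed))
    clf.fit(np.concatenate(X), np.concatenate(y))
    seg = Segmenter(clf)
    if len(va):
        dices = [dice_coefficient(seg.predict_mask(crops[i]), masks[i].astype(bool))
                 for i in va]
        seg.validation_dice = float(np.mean(dices))
    return seg


def segment_cell(crop: np.ndarray, model: Segmenter) -> np.ndarray:
    """Predict the cell mask of a crop; an all-false mask flags failure."""
    return model.predict_mask(crop)


def remove_background(crop: np.ndarray, mask: np.ndarray,
                      fill_color: np.ndarray | Sequence[float]) -> np.ndarray:
    """Set every pixel outside the mask to the fill color (idempotent)."""
    out = crop.copy()
    out[~mask] = np.asarray(fill_color, dtype=crop.dtype)
    return out


# ---------------------------------------------------------------------------
# size routing and dual-channel classification
# ---------------------------------------------------------------------------

def route_by_size(mask: np.ndarray, boundary: int = config.SIZE_ROUTE_PX) -> str:
    """'large' when the longer bounding side of the mask exceeds the
    boundary (90 px), else 'small'; boundary-sized cells route small."""
    if not mask.any():
        raise ValueError("cannot route an empty mask")
    ys, xs = np.nonzero(mask)
    side = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    return "large" if side > boundary else "small"


def standardize_crop(crop: np.ndarray, mask: np.ndarray, channel: str,
                     fill_color: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center the masked cell on the channel's canonical canvas
    (254x254 large / 90x90 small), cropping or padding as needed."""
    side = config.LARGE_CROP if channel == "large" else config.SMALL_CROP
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = crop[y0:y1, x0:x1]
    sub_mask = mask[y0:y1, x0:x1]
    h, w = sub.shape[:2]
    if h > side or w > side:            # oversized: center crop
        cy, cx = h // 2, w // 2
        y0c = max(0, cy - side // 2)
        x0c = max(0, cx - side // 2)
        sub = sub[y0c:y0c + side, x0c:x0c + side]
        sub_mask = sub_mask[y0c:y0c + side, x0c:x0c + side]
        h, w = sub.shape[:2]
    canvas = np.empty((side, side, 3), dtype=crop.dtype)
    canvas[:] = np.asarray(fill_color, dtype=crop.dtype)
    mcanvas = np.zeros((side, side), dtype=bool)
    oy, ox = (side - h) // 2, (side - w) // 2
    canvas[oy:oy + h, ox:ox + w] = sub
    mcanvas[oy:oy + h, ox:ox + w] = sub_mask
    return canvas, mcanvas


def cell_features(crop: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Morphology features driving the malignancy classifiers.

    Nucleus pixels are the dark tail of the cell's brightness; features cover the
    nucleus-to-cell area ratio, contour irregularity (perimeter^2 / 4*pi*A),
    nucleus texture, brightness and cell size.
    """
    gray = _grayscale(crop)
    cell_px = gray[mask]
    area = int(mask.sum())
    if area == 0:
        return np.zeros(8)
    thr = cell_px.mean() - 0.5 * cell_px.std()
    nucleus = mask & (gray < thr)
    props = regionprops(mask.astype(np.uint8))[0]
    perim = props.perimeter or 1.0
    irregularity = perim ** 2 / (4 * np.pi * area)
    nuc_area = int(nucleus.sum())
    return np.array([
        nuc_area / area,                                   # ncr estimate
        irregularity,
        float(gray[nucleus].std()) if nuc_area else 0.0,   # chromatin texture
        float(gray[nucleus].mean()) if nuc_area else 0.0,
        float(cell_px.mean()),
        float(cell_px.std()),
        np.log(area),
        float(props.eccentricity),
    ])


@dataclass
class ChannelClassifier:
    channel: str
    clf: object
    threshold: float
    validation_specificity: float | None = None
    test_auc: float | None = None

    def score(self, crop: np.ndarray, mask: np.ndarray) -> float:
        return float(self.clf.predict_proba(cell_features(crop, mask).reshape(1, -1))[0, 1])

    def call(self, score: float) -> bool:
        return score >= self.threshold


def calibrate_threshold(scores: np.ndarray, labels: np.ndarray,
                        spec_min: float = config.SPEC_MIN) -> float:
    """Smallest score threshold achieving specificity >= ``spec_min``.

    A cell is called malignant when score >= threshold, so specificity is
    the fraction of benign calibration scores strictly below the threshold.
    When no observed score qualifies, max score + epsilon is returned with
    a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels)) < 2:
        raise ValueError("calibration data must contain both classes")
    benign = scores[labels == 0]
    for t in np.unique(scores):
        if (benign < t).mean() >= spec_min:
            return float(t)
    log.warning("specificity %.4f unattainable at observed scores; "
                "using max score + eps", spec_min)
    return float(scores.max() + 1e-6)


def train_channel_classifier(
    cells: Sequence[tuple[np.ndarray, np.ndarray]],
    labels: Sequence[int],
    channel: str,
    cfg: TrainConfig = TrainConfig(),
    spec_min: float = config.SPEC_MIN,
) -> ChannelClassifier:
    """Fit one size channel's malignancy classifier.

    Cells are split 7:2:1 (train/validation/test); the operating threshold
    is calibrated on the validation split to specificity >= ``spec_min``;
    held-out AUC is recorded from the test split when it contains both
    classes.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    X = np.array([cell_features(c, m) for c, m in cells])
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(X))
    n_tr = int(cfg.split_ratios[0] * len(X))
    n_va = int(cfg.split_ratios[1] * len(X))
    tr, va, te = idx[:n_tr], idx[n_tr:n_tr + n_va], idx[n_tr + n_va:]
    clf = make_pipeline(StandardScaler(),
                        LogisticRegression(max_iter=2000, random_state=cfg.seed))
    clf.fit(X[tr], y[tr])
    va_scores = clf.predict_proba(X[va])[:, 1]
    threshold = calibrate_threshold(va_scores, y[va], spec_min)
    spec = float((va_scores[y[va] == 0] < threshold).mean())
    out = ChannelClassifier(channel, clf, threshold, spec)
    if len(te) and len(set(y[te].tolist())) == 2:
        from .diagnosis import roc_auc
        out.test_auc = roc_auc(clf.predict_proba(X[te])[:, 1], y[te]).auc
    return out


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

@dataclass
class SlideModels:
    detector: Detector
    qc: QcModel
    segmenter: Segmenter
    clf_large: ChannelClassifier
    clf_small: ChannelClassifier


def run_slide(
    wsi: np.ndarray,
    models: SlideModels,
    slide_id: str = "slide",
    cfg: config.RunConfig | None = None,
) -> tuple[SlideResult, list[CellRecord], dict[str, int]]:
    """Run the full cascade on one slide raster.

    Returns the slide summary (QC-passed cell total, predicted tumor cells,
    tumor-cell percentage and binary call at the 0.2% cutoff), per-cell
    provenance records, and per-stage object counts (monotone
    non-increasing along the cascade). The denominator of the tumor-cell
    percentage is the QC-passed cell count.
    """
    cfg = cfg or config.RunConfig()
    fill = modal_border_color(wsi)
    patches = tile_wsi(wsi, cfg.patch_size, fill)
    counts = {"patches": len(patches), "boxes": 0, "qc_pass": 0,
              "segmented": 0, "classified": 0, "etc": 0}
    records: list[CellRecord] = []
    for pi, patch in enumerate(patches):
        boxes = models.detector.predict(patch.pixels, cfg.detect_conf_min,
                                        cfg.nms_iou_max)
        counts["boxes"] += len(boxes)
        for b in boxes:
            x0, y0 = int(b.x), int(b.y)
            crop = patch.pixels[y0:y0 + int(b.h), x0:x0 + int(b.w)]
            verdict = qc_classify(crop, models.qc)
            gbox = b.shifted(*patch.origin)
            if not verdict.passed:
                records.append(CellRecord(pi, gbox, verdict))
                continue
            counts["qc_pass"] += 1
            mask = segment_cell(crop, models.segmenter)
            if not mask.any():
                records.append(CellRecord(pi, gbox, verdict))
                continue
            counts["segmented"] += 1
            channel = route_by_size(mask, cfg.size_route_px)
            std_crop, std_mask = standardize_crop(
                remove_background(crop, mask, fill), mask, channel, fill)
            clf = models.clf_large if channel == "large" else models.clf_small
            score = clf.score(std_crop, std_mask)
            call = clf.call(score)
            counts["classified"] += 1
            counts["etc"] += int(call)
            records.append(CellRecord(pi, gbox, verdict, channel, score, call))
    n_total = counts["qc_pass"]
    n_etc = counts["etc"]
    pct = 100.0 * n_etc / n_total if n_total else 0.0
    result = SlideResult(slide_id, n_total, n_etc, pct,
                         call=pct >= cfg.etc_cutoff_pct if n_total else False)
    return result, records, counts
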