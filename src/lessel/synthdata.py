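"""Synthetic study data: clonal single-cell bin counts and Pap-like slides.

Two generators feed the two arms of the pipeline:

* :func:`simulate_cell_counts` draws negative-binomial read counts per
  genomic bin with a quadratic multiplicative GC bias and a planted clonal
  copy-number profile shared across tumor cells, at a controllable MAPD.
* :func:`render_cell` / :func:`render_slide` draw Pap-like single cells
  (benign vs malignant morphology encoded by nucleus-to-cytoplasm ratio,
  contour irregularity and chromatin texture; the distributions overlap so
  classifiers cannot be trivially perfect) and composite them, together
  with six kinds of junk objects mirroring the QC reject classes, into
  1024x1024-patch whole-slide rasters with ground-truth boxes, masks and
  labels.

:func:`simulate_cohort` builds per-patient slide summaries whose tumor-cell
fractions straddle the 0.2% slide-level operating point.

All randomness flows through one seeded generator per call; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from . import config
from .cna import BinCounts, GenomeBins, make_bins

log = logging.getLogger("lessel.synthdata")

# mean absolute difference of two iid draws with SD sigma is 2*sigma/sqrt(pi)
_MAPD_PER_SD = 2.0 / np.sqrt(np.pi)

# Pap-like palette (RGB), loosely cytoplasm cyan-green, nucleus dark purple
BACKGROUND_RGB = (235, 233, 228)
CYTO_RGB = (156, 196, 178)
NUCLEUS_RGB = (88, 52, 110)
IMPURITY_RGB = (70, 55, 40)


# ---------------------------------------------------------------------------
# CNA-arm specs and simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneSpec:
    """A clonal CNA profile: list of (chrom_index, start_bin, end_bin, state).

    ``state`` is the integer copy number of the event (0, 1, 3 or 4; the
    diploid baseline 2 is never an event). Bin indices are relative to the
    chromosome and half-open. Events must not overlap within a chromosome.
    """

    events: tuple[tuple[int, int, int, int], ...]
    baseline_ploidy: int = 2

    def __post_init__(self) -> None:
        per_chrom: dict[int, list[tuple[int, int]]] = {}
        for ci, s, e, state in self.events:
            if s >= e:
                raise ValueError("event needs start_bin < end_bin")
            if state not in (0, 1, 3, 4):
                raise ValueError("copy state must be in {0,1,3,4}")
            per_chrom.setdefault(ci, []).append((s, e))
        for spans in per_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
                if s2 < e1:
                    raise ValueError("events overlap within a chromosome")

    def copy_states(self, bins: GenomeBins) -> np.ndarray:
        """Per-bin integer copy number over the whole genome."""
        states = np.full(len(bins), self.baseline_ploidy, dtype=int)
        slices = bins.chrom_slices()
        for ci, s, e, state in self.events:
            if ci >= len(slices):
                raise ValueError(f"chromosome index {ci} out of range")
            sl = slices[ci][1]
            if e > sl.stop - sl.start:
                raise ValueError("event extends past chromosome end")
            states[sl.start + s:sl.start + e] = state
        return states

    def altered_autosomal_fraction(self, bins: GenomeBins) -> float:
        """Planted altered fraction of the autosomal genome, in percent."""
        states = self.copy_states(bins)
        auto = bins.autosomal
        w = bins.widths
        return 100.0 * w[auto & (states != self.baseline_ploidy)].sum() / w[auto].sum()


@dataclass(frozen=True)
class NoiseSpec:
    """Sequencing-noise model for one simulated cell.

    ``gc_bias`` are coefficients (a0, a1, a2) of a multiplicative quadratic
    curve a0 + a1*gc + a2*gc^2, normalized to mean 1 over bins.
    ``overdispersion`` is the negative-binomial alpha (variance mu +
    alpha*mu^2); 0 falls back to Poisson. When ``target_mapd`` is set the
    mean depth is derived from it (and ``mean_depth`` is ignored); a target
    unreachable at the given overdispersion raises with the floor value.
    """

    mean_depth: float = 100.0
    gc_bias: tuple[float, float, float] = (1.0, 0.0, 0.0)
    overdispersion: float = 0.0
    target_mapd: float | None = None
    seed: int = 0

    def depth_for_target(self) -> float:
        if self.target_mapd is None:
            return self.mean_depth
        sigma2 = (self.target_mapd / _MAPD_PER_SD) ** 2
        floor = _MAPD_PER_SD * np.sqrt(self.overdispersion)
        if sigma2 <= self.overdispersion:
            raise ValueError(
                f"target MAPD {self.target_mapd:.3f} unachievable: overdispersion "
                f"{self.overdispersion} alone gives MAPD >= {floor:.3f}")
        return 1.0 / (sigma2 - self.overdispersion)


def simulate_cell_counts(
    clone: CloneSpec | None,
    bins: GenomeBins,
    noise: NoiseSpec,
    cell_id: str = "cell",
    rng: np.random.Generator | None = None,
) -> BinCounts:
    """Draw one cell's binned read counts.

    Expected count per bin is depth * (copy state / ploidy) * GC-bias(gc),
    with the bias curve normalized to mean 1; ``clone=None`` gives a flat
    diploid expectation. Counts are negative-binomial (Poisson when
    overdispersion is 0).
    """
    if len(bins) == 0:
        raise ValueError("bins must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    depth = noise.depth_for_target()
    a0, a1, a2 = noise.gc_bias
    gc = bins.gc
    bias = a0 + a1 * gc + a2 * gc ** 2
    bias = np.clip(bias, 1e-3, None)
    bias = bias / bias.mean()
    if clone is None:
        rel = np.ones(len(bins))
    else:
        rel = clone.copy_states(bins) / clone.baseline_ploidy
    mu = depth * rel * bias
    if noise.overdispersion > 0:
        n = 1.0 / noise.overdispersion
        counts = rng.negative_binomial(n, n / (n + np.clip(mu, 1e-9, None)))
        counts[mu <= 0] = 0
    else:
        counts = rng.poisson(mu)
    return BinCounts(cell_id, counts)


def reference_bins(
    n_chroms: int = 4,
    chrom_length: int = 50_000_000,
    bin_width: int = config.BIN_WIDTH_BP,
    seed: int = 7,
    with_sex: bool = False,
) -> GenomeBins:
    """A small synthetic genome with smoothly varying GC per bin.

    GC fractions follow a slow sinusoid plus jitter inside [0.33, 0.62],
    the range where mammalian bins mostly live.
    """
    lengths = {str(i + 1): chrom_length for i in range(n_chroms)}
    if with_sex:
        lengths["X"] = chrom_length
    skeleton = make_bins(lengths, bin_width)
    rng = np.random.default_rng(seed)
    t = np.arange(len(skeleton))
    gc = 0.45 + 0.08 * np.sin(t / 9.0) + rng.normal(0, 0.02, len(skeleton))
    table = skeleton.table.copy()
    table["gc"] = np.clip(gc, 0.33, 0.62)
    return GenomeBins(table)


# ---------------------------------------------------------------------------
# cell rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRenderSpec:
    """Morphology of one rendered cell.

    Malignancy is encoded continuously: higher nucleus-to-cytoplasm area
    ratio, more irregular contour, stronger chromatin texture. Size class
    controls the cell radius so large cells' bounding side lands in
    (90, 254] px and small cells' within 90 px.
    """

    size_class: str = "large"            # large | small
    malignant: bool = False
    ncr: float = 0.3                     # nucleus-to-cytoplasm area ratio
    irregularity: float = 0.05
    chromatin: float = 0.05
    radius: float | None = None          # px; drawn from size class if None
    palette: tuple[tuple[int, int, int], ...] = (NUCLEUS_RGB, CYTO_RGB, BACKGROUND_RGB)

    def __post_init__(self) -> None:
        if self.size_class not in ("large", "small"):
            raise ValueError("size_class must be 'large' or 'small'")
        if not (0.0 < self.ncr < 1.0):
            raise ValueError("ncr must be in (0, 1)")
        if self.irregularity < 0 or self.chromatin < 0:
            raise ValueError("irregularity and chromatin must be >= 0")


def sample_render_spec(malignant: bool, size_class: str,
                       rng: np.random.Generator) -> CellRenderSpec:
    """Draw a morphology from the default benign/malignant distributions.

    The class-conditional distributions overlap (roughly one noise SD apart
    per feature) so the downstream classifiers face a non-trivial problem.
    """
    if malignant:
        ncr = float(np.clip(rng.normal(0.55, 0.12), 0.15, 0.9))
        irr = float(abs(rng.normal(0.13, 0.05)))
        chrom = float(abs(rng.normal(0.16, 0.05)))
    else:
        ncr = float(np.clip(rng.normal(0.30, 0.09), 0.05, 0.8))
        irr = float(abs(rng.normal(0.05, 0.03)))
        chrom = float(abs(rng.normal(0.06, 0.03)))
    return CellRenderSpec(size_class=size_class, malignant=malignant,
                          ncr=ncr, irregularity=irr, chromatin=chrom)


def _blob_mask(shape: tuple[int, int], center: tuple[float, float], radius: float,
               irregularity: float, rng: np.random.Generator,
               n_harm: int = 5) -> np.ndarray:
    """Closed irregular contour rasterized to a boolean mask."""
    theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 2 + n_harm):
        amp = irregularity * rng.normal(0, 1) / np.sqrt(n_harm)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.3, 1.7) * radius
    rr, cc = draw_polygon(center[0] + r * np.sin(theta),
                          center[1] + r * np.cos(theta), shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def render_cell(spec: CellRenderSpec, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell; returns (RGB uint8 image, boolean mask).

    The mask covers exactly the rendered cell pixels; the cell's bounding
    side fits its size class (<= 254 px large, <= 90 px small).
    """
    rng = np.random.default_rng(seed)
    side = config.LARGE_CROP if spec.size_class == "large" else config.SMALL_CROP
    if spec.radius is not None:
        radius = spec.radius
    elif spec.size_class == "large":
        radius = rng.uniform(50, 88)
    else:
        radius = rng.uniform(16, 32)
    shape = (side, side)
    center = (side / 2, side / 2)
    nuc_rgb, cyto_rgb, bg_rgb = spec.palette
    img = np.empty((*shape, 3), dtype=float)
    img[:] = bg_rgb
    img += rng.normal(0, 2.5, img.shape)

    cell = _blob_mask(shape, center, radius, spec.irregularity, rng)
    # keep the cell inside the crop even with extreme irregularity
    border = np.zeros(shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (cell & border).any():
        cell &= ~border
    img[cell] = cyto_rgb
    img[cell] += rng.normal(0, 4.0, (int(cell.sum()), 3))

    nuc_radius = radius * np.sqrt(spec.ncr)
    off = rng.uniform(-0.15, 0.15, 2) * radius
    nucleus = _blob_mask(shape, (center[0] + off[0], center[1] + off[1]),
                         nuc_radius, spec.irregularity * 0.7, rng) & cell
    img[nucleus] = nuc_rgb
    if nucleus.any():
        texture = gaussian_filter(rng.normal(0, 1, shape), 1.5)
        tex = 60.0 * spec.chromatin * texture[nucleus]
        img[nucleus] += tex[:, None]
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, cell


# ---------------------------------------------------------------------------
# slide rendering
# ---------------------------------------------------------------------------

#: junk taxonomy mirrors the six QC reject classes
JUNK_LABELS = tuple(config.QC_CATEGORIES[1:])

CELL_LABELS = ("benign", "malignant")


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Layout of one synthetic whole-slide raster."""

    n_cells: int = 50
    true_etc_fraction: float = 10.0      # percent of cells that are malignant
    patch_grid: tuple[int, int] = (1, 1)  # (rows, cols) of 1024x1024 patches
    junk_fraction: float = 0.2           # junk objects per placed cell
    small_cell_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_etc_fraction <= 100.0):
            raise ValueError("true_etc_fraction must be in [0, 100]")
        if self.patch_grid[0] < 1 or self.patch_grid[1] < 1:
            raise ValueError("patch grid must be at least 1x1")

    @property
    def n_malignant(self) -> int:
        return int(round(self.n_cells * self.true_etc_fraction / 100.0))


def _rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=np.uint8).ravel(order="C")
    change = np.flatnonzero(np.diff(flat)) + 1
    runs = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(runs).tolist()
    first = int(flat[0])
    if first == 1:                      # RLE starts with a zero-run
        counts = [0] + counts
    return {"size": list(mask.shape), "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    out = np.zeros(int(np.prod(rle["size"])), dtype=bool)
    pos, val = 0, 0
    for c in rle["counts"]:
        if val:
            out[pos:pos + c] = True
        pos += c
        val ^= 1
    return out.reshape(rle["size"])


def render_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, list[dict]]:
    """Composite cells and junk onto a multi-patch background raster.

    Returns the RGB raster and one annotation per object:
    ``{"bbox": [x, y, w, h], "label": ..., "is_cell": ..., "mask": RLE}``
    with global 0-based half-open pixel coordinates. Exactly
    ``round(n_cells * fraction / 100)`` cells carry the malignant label.
    Objects are placed on a jittered grid so masks never overlap; a cell
    count beyond the grid capacity raises.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.patch_grid
    H, W = rows * config.PATCH_SIZE, cols * config.PATCH_SIZE
    wsi = np.empty((H, W, 3), dtype=float)
    wsi[:] = BACKGROUND_RGB
    wsi += rng.normal(0, 2.0, wsi.shape)

    n_junk = int(round(spec.n_cells * spec.junk_fraction))
    n_objects = spec.n_cells + n_junk
    cell_pitch = 235  # exceeds the worst-case object extent; keeps masks apart
    gy, gx = max(1, H // cell_pitch), max(1, W // cell_pitch)
    if n_objects > gy * gx:
        raise ValueError(f"{n_objects} objects exceed slide capacity {gy * gx}")
    slots = [(r, c) for r in range(gy) for c in range(gx)]
    rng.shuffle(slots)

    labels = (["malignant"] * spec.n_malignant
              + ["benign"] * (spec.n_cells - spec.n_malignant)
              + [JUNK_LABELS[i % len(JUNK_LABELS)] for i in range(n_junk)])
    order = rng.permutation(len(labels))

    occupied = np.zeros((H, W), dtype=bool)
    annotations: list[dict] = []
    for k in order:
        label = labels[k]
        r, c = slots[k]
        cy = int((r + 0.5) * H / gy + rng.uniform(-10, 10))
        cx = int((c + 0.5) * W / gx + rng.uniform(-10, 10))
        # retry a few renders on the rare mask collision, then clip
        for _ in range(5):
            obj_img, obj_mask, is_cell = _render_object(label, rng)
            h, w = obj_mask.shape
            y0 = int(np.clip(cy - h // 2, 0, H - h))
            x0 = int(np.clip(cx - w // 2, 0, W - w))
            if not (obj_mask & occupied[y0:y0 + h, x0:x0 + w]).any():
                break
        obj_mask = obj_mask & ~occupied[y0:y0 + h, x0:x0 + w]
        if not obj_mask.any():
            continue
        occupied[y0:y0 + h, x0:x0 + w] |= obj_mask
        region = wsi[y0:y0 + h, x0:x0 + w]
        region[obj_mask] = obj_img[obj_mask]
        ys, xs = np.nonzero(obj_mask)
        bx, by = int(xs.min()), int(ys.min())
        bw, bh = int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)
        annotations.append({
            "bbox": [x0 + bx, y0 + by, bw, bh],
            "label": label,
            "is_cell": is_cell,
            "mask": _rle_encode(obj_mask[by:by + bh, bx:bx + bw]),
        })
    return np.clip(wsi, 0, 255).astype(np.uint8), annotations


def render_object(label: str, seed: int = 0,
                  size_class: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Render one object (cell or junk) composited on background.

    Standalone fixture path for the QC and segmentation models; the same
    renderer backs :func:`render_slide`. Returns (RGB uint8, mask).
    """
    rng = np.random.default_rng(seed)
    img, mask, _ = _render_object(label, rng, size_class)
    return np.clip(img, 0, 255).astype(np.uint8), mask


def _render_object(label: str, rng: np.random.Generator,
                   size_class: str | None = None) -> tuple[np.ndarray, np.ndarray, bool]:
    """Render one slide object (cell or junk) on its local background canvas."""
    img, mask, is_cell = _render_object_raw(label, rng, size_class)
    out = np.empty_like(img, dtype=float)
    out[:] = BACKGROUND_RGB
    out += rng.normal(0, 2.0, out.shape)
    out[mask] = img[mask]
    return out, mask, is_cell


def _render_object_raw(label: str, rng: np.random.Generator,
                       size_class: str | None = None) -> tuple[np.ndarray, np.ndarray, bool]:
    seed = int(rng.integers(2 ** 31))
    if size_class is None:
        size_class = "small" if rng.random() < 0.5 else "large"
    if label in CELL_LABELS:
        spec = sample_render_spec(label == "malignant", size_class, rng)
        img, mask = render_cell(spec, seed)
        return img.astype(float), mask, True
    if label == "blurry":
        spec = sample_render_spec(False, size_class, rng)
        img, mask = render_cell(spec, seed)
        blurred = gaussian_filter(img.astype(float), (3.5, 3.5, 0))
        return blurred, mask, False
    if label == "incomplete":
        spec = sample_render_spec(False, size_class, rng)
        img, mask = render_cell(spec, seed)
        cut = mask.copy()
        cut[: mask.shape[0] // 2 + int(rng.integers(-5, 6)), :] = False
        return img.astype(float), cut, False
    if label == "fragment":
        local = np.random.default_rng(seed)
        shape = (60, 60)
        mask = _blob_mask(shape, (30, 30), local.uniform(8, 15), 0.35, local)
        img = np.empty((*shape, 3));  img[:] = CYTO_RGB
        img += local.normal(0, 5, img.shape)
        return img, mask, False
    if label == "clump":
        local = np.random.default_rng(seed)
        shape = (200, 200)
        img = np.empty((*shape, 3));  img[:] = BACKGROUND_RGB
        total = np.zeros(shape, dtype=bool)
        for i in range(3):
            sub_spec = sample_render_spec(False, "small", local)
            sub_img, sub_mask = render_cell(sub_spec, seed + i + 1)
            oy, ox = int(local.uniform(40, 90)), int(local.uniform(40, 90))
            h, w = sub_mask.shape
            patch = img[oy:oy + h, ox:ox + w]
            patch[sub_mask] = sub_img[sub_mask]
            total[oy:oy + h, ox:ox + w] |= sub_mask
        return img, total, False
    if label == "impurity":
        local = np.random.default_rng(seed)
        shape = (50, 50)
        mask = _blob_mask(shape, (25, 25), local.uniform(6, 14), 0.5, local)
        img = np.empty((*shape, 3));  img[:] = IMPURITY_RGB
        img += local.normal(0, 8, img.shape)
        return img, mask, False
    if label == "nucleus_only":
        local = np.random.default_rng(seed)
        shape = (70, 70)
        mask = _blob_mask(shape, (35, 35), local.uniform(9, 18), 0.12, local)
        img = np.empty((*shape, 3));  img[:] = NUCLEUS_RGB
        img += local.normal(0, 6, img.shape)
        return img, mask, False
    raise ValueError(f"unknown object label: {label}")


def save_slide(wsi: np.ndarray, annotations: list[dict],
               png_path: str | Path, json_path: str | Path) -> None:
    Image.fromarray(wsi).save(png_path)
    Path(json_path).write_text(json.dumps(annotations))


def load_annotations(json_path: str | Path) -> list[dict]:
    return json.loads(Path(json_path).read_text())


def object_crop(img: np.ndarray, mask: np.ndarray,
                margin: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Tight bounding-box crop of an object, mimicking a detection crop."""
    ys, xs = np.nonzero(mask)
    y0 = max(0, ys.min() - margin)
    x0 = max(0, xs.min() - margin)
    y1 = min(mask.shape[0], ys.max() + 1 + margin)
    x1 = min(mask.shape[1], xs.max() + 1 + margin)
    return img[y0:y1, x0:x1], mask[y0:y1, x0:x1]


def channel_training_set(
    n_malignant: int,
    n_benign: int,
    size_class: str,
    seed: int = 0,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Rendered (crop, mask) pairs and labels for one classifier channel."""
    rng = np.random.default_rng(seed)
    cells, labels = [], []
    for malignant, n in ((True, n_malignant), (False, n_benign)):
        for _ in range(n):
            spec = sample_render_spec(malignant, size_class, rng)
            img, mask = render_cell(spec, int(rng.integers(2 ** 31)))
            cells.append(object_crop(img, mask))
            labels.append(int(malignant))
    order = rng.permutation(len(cells))
    return [cells[i] for i in order], np.array(labels)[order]


def qc_training_set(n_per_category: int, seed: int = 0
                    ) -> tuple[list[np.ndarray], list[str]]:
    """Tight crops and QC labels, balanced over the seven categories."""
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    for cat in config.QC_CATEGORIES:
        for k in range(n_per_category):
            # high-quality examples alternate benign and malignant morphology
            label = cat if cat != "high_quality" else ("benign", "malignant")[k % 2]
            img, mask = render_object(label, int(rng.integers(2 ** 31)))
            crops.append(object_crop(img, mask)[0])
            labels.append(cat)
    return crops, labels


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_malignant: int,
    n_control: int,
    seed: int = 0,
    n_cells_range: tuple[int, int] = (5_000, 30_000),
    malignant_fraction_median: float = 0.3,
    malignant_fraction_sigma: float = 1.0,
    control_fraction_mean: float = 0.04,
    cytology_sensitivity: float = 0.15,
) -> pd.DataFrame:
    """Per-patient slide summaries for diagnosis-arm experiments.

    Malignant slides draw their true tumor-cell fraction from a lognormal
    straddling the 0.2% operating point (median 0.3%); controls from an
    exponential near zero with rare borderline tails — mirroring discovery
    cohorts where case and control distributions overlap. A low-sensitivity,
    perfectly specific conventional-cytology call is included for the
    comparison statistics.

    Columns: patient_id, truth (1 malignant), n_cells, etc_fraction (%),
    n_etc, etc_percent (observed), cytology_result (0/1), slide_seed.
    """
    if n_malignant < 1 or n_control < 1:
        raise ValueError("need at least one patient per arm")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_malignant + n_control):
        truth = int(i < n_malignant)
        n_cells = int(rng.integers(*n_cells_range))
        if truth:
            frac = float(rng.lognormal(np.log(malignant_fraction_median),
                                       malignant_fraction_sigma))
            frac = min(frac, 5.0)
            cyto = int(rng.random() < cytology_sensitivity)
        else:
            frac = float(rng.exponential(control_fraction_mean))
            cyto = 0
        n_etc = int(round(n_cells * frac / 100.0))
        rows.append({
            "patient_id": f"P{i + 1:03d}",
            "truth": truth,
            "n_cells": n_cells,
            "etc_fraction": frac,
            "n_etc": n_etc,
            "etc_percent": 100.0 * n_etc / n_cells,
            "cytology_result": cyto,
            "slide_seed": int(rng.integers(2 ** 31)),
        })
    return pd.DataFrame(rows)
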