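"""Run configuration shared across the pipeline.

Every numeric pipeline setting lives here as a named default so a run can be
reproduced from its manifest alone. :class:`RunConfig` round-trips through
YAML/JSON without loss.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

log = logging.getLogger("lessel")

#: Mean genomic bin width for read counting (bp).
BIN_WIDTH_BP = 500_000
#: Per-cell noise gate: cells with MAPD above this fail QC.
MAPD_MAX = 0.45
#: Significance level of the CBS permutation test.
CBS_ALPHA = 1e-4
#: Maximum permutations per CBS split test.
CBS_MAX_PERM = 10_000
#: Merge adjacent segments whose mean log2 difference is below this many
#: noise SDs (the "undo" step after segmentation).
CBS_UNDO_SD = 1.0
#: log2-ratio thresholds for calling a segment gained / lost.
GAIN_LOG2 = 0.25
LOSS_LOG2 = -0.25
#: Lowess span for the GC-bias fit.
LOWESS_FRAC = 0.3
#: Pairwise concordance (Pearson) threshold for clonal clustering.
CONCORDANCE_MIN = 0.8
#: Minimum clone size: at least this many concordant cells to call malignancy.
MIN_CLUSTER = 2

#: Whole-slide images are tiled into non-overlapping patches of this side (px).
PATCH_SIZE = 1024
#: Detection boxes below this confidence are dropped before NMS.
DETECT_CONF_MIN = 0.3
#: NMS suppresses a box overlapping a kept box above this IoU.
NMS_IOU_MAX = 0.5
#: Weight of the IoU term in the detection loss.
DETECT_LAMBDA_REG = 0.5
#: QC-model input side (px): crops are resized to this before classification.
QC_INPUT_SIZE = 224
#: Canonical crop sides of the two classifier channels (px).
LARGE_CROP = 254
SMALL_CROP = 90
#: Routing boundary: cells whose longer mask side exceeds this go to the
#: large channel (ties go small).
SIZE_ROUTE_PX = 90
#: Minimum specificity the channel classifiers are calibrated to.
SPEC_MIN = 0.998

#: Slide-level operating point: a slide is positive when the predicted
#: tumor-cell percentage reaches this cutoff.
ETC_CUTOFF_PCT = 0.2

#: The seven QC categories; the first is the only one passed downstream.
QC_CATEGORIES = (
    "high_quality",
    "blurry",
    "incomplete",
    "fragment",
    "clump",
    "impurity",
    "nucleus_only",
)


@dataclass
class RunConfig:
    """All tunables of an end-to-end run, serializable to YAML/JSON."""

    seed: int = 0
    # CNA arm
    bin_width_bp: int = BIN_WIDTH_BP
    mapd_max: float = MAPD_MAX
    cbs_alpha: float = CBS_ALPHA
    cbs_max_perm: int = CBS_MAX_PERM
    cbs_undo_sd: float = CBS_UNDO_SD
    gain_log2: float = GAIN_LOG2
    loss_log2: float = LOSS_LOG2
    lowess_frac: float = LOWESS_FRAC
    concordance_min: float = CONCORDANCE_MIN
    min_cluster: int = MIN_CLUSTER
    # imaging arm
    patch_size: int = PATCH_SIZE
    detect_conf_min: float = DETECT_CONF_MIN
    nms_iou_max: float = NMS_IOU_MAX
    detect_lambda_reg: float = DETECT_LAMBDA_REG
    qc_input_size: int = QC_INPUT_SIZE
    large_crop: int = LARGE_CROP
    small_crop: int = SMALL_CROP
    size_route_px: int = SIZE_ROUTE_PX
    spec_min: float = SPEC_MIN
    # diagnosis
    etc_cutoff_pct: float = ETC_CUTOFF_PCT
    ci_method: str = "clopper-pearson"
    # bookkeeping
    paths: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls(**data)
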