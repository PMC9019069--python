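"""Shared domain objects: frames, masks, boxes, calls.

Pixel conventions used throughout the package: the grid is 0-based and
row-major; boxes are axis-aligned and half-open, ``[x0, x1) x [y0, y1)`` in
pixel units, so a box covering one pixel at the origin is (0, 0, 1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# label codes of the atrium mask
BACKGROUND, LA, RA, LV, RV = 0, 1, 2, 3, 4
LABEL_NAMES = {BACKGROUND: "background", LA: "LA", RA: "RA", LV: "LV", RV: "RV"}

# the five view classes, fixed integer codes (alphabetical, "other" last)
VIEW_CLASSES = ("A4C", "LPS4C", "sax_basal", "subAS", "other")
VIEW_CODES = {name: code for code, name in enumerate(VIEW_CLASSES)}
TARGET_VIEWS = ("A4C", "LPS4C", "sax_basal", "subAS")


@dataclass
class EchoFrame:
    """One 2-D RGB echocardiographic frame."""

    image: np.ndarray  # (H, W, 3) uint8
    case_id: str = "case0"
    frame_index: int = 0
    view_label: str | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("frame image must be (H, W, 3)")


@dataclass
class AtriaMask:
    """Per-pixel label map over {background, LA, RA} (optionally LV, RV)."""

    labels: np.ndarray  # (H, W) uint8

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        bad = set(np.unique(self.labels)) - {BACKGROUND, LA, RA, LV, RV}
        if bad:
            raise ValueError(f"unknown mask label codes: {sorted(bad)}")

    @property
    def shape(self):
        return self.labels.shape

    def region(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass(frozen=True)
class CandidateBox:
    """Axis-aligned defect candidate with detection confidence."""

    x0: float
    y0: float
    x1: float
    y1: float
    confidence: float = 1.0

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("box must satisfy x0 < x1 and y0 < y1")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def iou(self, other: "CandidateBox") -> float:
        ix = max(0.0, min(self.x1, other.x1) - max(self.x0, other.x0))
        iy = max(0.0, min(self.y1, other.y1) - max(self.y0, other.y0))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def as_list(self) -> list[float]:
        return [self.x0, self.y0, self.x1, self.y1, self.confidence]


@dataclass
class SeptumRegion:
    """Binary mask of the (dilated) inter-atrial band."""

    mask: np.ndarray  # (H, W) bool
    dilation_radius: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ImageCall:
    """Frame-level positive/negative decision."""

    positive: bool
    max_confidence: float  # 0.0 when no candidate survived refinement
    cutoff: float


@dataclass(frozen=True)
class CaseCall:
    """Case-level decision aggregated over frame calls."""

    positive: bool
    positive_fraction: float
    threshold: float


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN tallies feeding the classification metrics."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)
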