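"""Anchor-free single-stage defect-candidate detector.

Per-location prediction in the FCOS style: a convolutional backbone feeds a
feature pyramid (default P3-P5); at every pyramid location three shared
heads emit a class score, a centerness score and four non-negative distances
(left, top, right, bottom) to the box edges.  A ground-truth box is assigned
to the locations that fall inside it, at the pyramid level whose size range
contains the largest of the four distances — large defects are regressed on
coarse maps with large receptive fields, small defects on fine maps.
Detection confidence is classification times centerness; overlapping
detections are merged by IoU-threshold non-maximum suppression.

Training uses focal classification loss over all locations, an IoU loss on
positive-location boxes, and binary cross-entropy on centerness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, concat
from .types import CandidateBox

__all__ = ["DetConfig", "FcosDetector", "build_detector", "encode_targets",
           "decode_boxes", "nms", "detect", "train_detector", "LEVEL_RANGES"]

# published size ranges for P3..P7; the top level of a truncated pyramid
# is open-ended
_FULL_RANGES = {3: (0, 64), 4: (64, 128), 5: (128, 256), 6: (256, 512), 7: (512, np.inf)}


def LEVEL_RANGES(levels: tuple[int, ...]) -> list[tuple[float, float]]:
    ranges = [_FULL_RANGES[p] for p in levels]
    lo, _ = ranges[-1]
    ranges[-1] = (lo, np.inf)
    return ranges


@dataclass
class DetConfig:
    levels: tuple = (3, 4, 5)        # pyramid levels, strides 2**p
    backbone_width: int = 8          # stem width; stages double it
    fpn_channels: int = 32
    head_convs: int = 1
    score_threshold: float = 0.05    # pre-refinement; the clinical cut-off
                                     # (0.95) is applied at image-call time
    nms_threshold: float = 0.4
    epochs: int = 10
    learning_rate: float = 2e-3
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if not set(self.levels) <= set(range(3, 8)):
            raise ValueError("pyramid levels must be within P3..P7")
        if list(self.levels) != list(range(self.levels[0], self.levels[-1] + 1)):
            raise ValueError("levels must be consecutive and ascending")


class Scale(nn.Module):
    """Learnable per-level scalar applied to the regression output."""

    def __init__(self, init: float = 1.0):
        super().__init__()
        self.scale = nn.Parameter(np.array([init]))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.scale


class FcosDetector(nn.Module):
    def __init__(self, config: DetConfig):
        super().__init__()
        self.config = config
        w = config.backbone_width
        self.widths = [w, 2 * w, 4 * w, 6 * w, 8 * w]

        def conv_block(cin, cout, stride):
            return nn.Sequential(
                nn.Conv2d(cin, cout, 3, stride, 1, bias=False),
                nn.BatchNorm2d(cout), nn.ReLU(),
                nn.Conv2d(cout, cout, 3, 1, 1, bias=False),
                nn.BatchNorm2d(cout), nn.ReLU(),
            )

        # strides 2, 4, 8, 16, 32 -> feature maps C1..C5
        self.stem = conv_block(3, self.widths[0], 2)
        self.stages = [conv_block(self.widths[i], self.widths[i + 1], 2)
                       for i in range(4)]
        c = config.fpn_channels
        self.laterals = [nn.Conv2d(self.widths[p - 1], c, 1) for p in config.levels]
        self.smooth = [nn.Conv2d(c, c, 3, padding=1) for _ in config.levels]
        # heads are shared across pyramid levels
        def tower():
            layers = []
            for _ in range(config.head_convs):
                layers += [nn.Conv2d(c, c, 3, padding=1), nn.ReLU()]
            return nn.Sequential(*layers)

        self.cls_tower = tower()
        self.reg_tower = tower()
        self.cls_head = nn.Conv2d(c, 1, 3, padding=1)
        self.ctr_head = nn.Conv2d(c, 1, 3, padding=1)
        self.reg_head = nn.Conv2d(c, 4, 3, padding=1)
        self.scales = [Scale() for _ in config.levels]
        # bias the classifier toward background so early training is stable
        self.cls_head.bias.data[:] = -2.0

    @property
    def strides(self) -> list[int]:
        return [2**p for p in self.config.levels]

    def forward(self, x: Tensor) -> list[dict]:
        """Per-level dicts with 'cls', 'ctr' logits and 'reg' distances (in
        image pixels, non-negative by construction)."""
        feats = []
        out = self.stem(x)
        for stage in self.stages:
            out = stage(out)
            feats.append(out)
        # feats: C2..C5 at strides 4..32
        selected = [feats[p - 2] for p in self.config.levels]
        laterals = [lat(f) for lat, f in zip(self.laterals, selected)]
        merged = [laterals[-1]]
        for lower in reversed(laterals[:-1]):
            merged.append(lower + nn.functional.upsample_nearest2x(merged[-1]))
        merged = merged[::-1]
        outputs = []
        for p, feat, smooth, scale, stride in zip(
                self.config.levels, merged, self.smooth, self.scales, self.strides):
            feat = smooth(feat)
            ct = self.cls_tower(feat)
            rt = self.reg_tower(feat)
            reg = scale(self.reg_head(rt)).exp() * float(stride)
            outputs.append({"level": p, "stride": stride,
                            "cls": self.cls_head(ct), "ctr": self.ctr_head(rt),
                            "reg": reg})
        return outputs


def build_detector(backbone_width: int = 8, levels: tuple = (3, 4, 5),
                   config: DetConfig | None = None) -> FcosDetector:
    if config is None:
        config = DetConfig(levels=tuple(levels), backbone_width=backbone_width)
    return FcosDetector(config)


def level_locations(hw: int, stride: int) -> np.ndarray:
    """(P, 2) array of (x, y) image coordinates of a level's grid centers."""
    n = hw // stride
    coords = stride / 2.0 + stride * np.arange(n)
    xx, yy = np.meshgrid(coords, coords)
    return np.stack([xx.ravel(), yy.ravel()], axis=1)


def encode_targets(boxes: list[CandidateBox], hw: int, levels: tuple[int, ...]):
    """Per-level training targets for one image.

    Returns a list of dicts per level with 'cls' (P,), 'reg' (P, 4) distance
    targets (l, t, r, b) and 'ctr' (P,) centerness, with non-positive
    locations zeroed.  A location is positive when it lies strictly inside a
    box and the largest distance falls in the level's size range
    (lo, hi]; among several such boxes the smallest-area one wins.
    """
    ranges = LEVEL_RANGES(tuple(levels))
    out = []
    for p, (lo, hi) in zip(levels, ranges):
        locs = level_locations(hw, 2**p)
        n = len(locs)
        cls = np.zeros(n, dtype=np.float32)
        reg = np.zeros((n, 4), dtype=np.float32)
        ctr = np.zeros(n, dtype=np.float32)
        best_area = np.full(n, np.inf)
        for box in boxes:
            l = locs[:, 0] - box.x0
            t = locs[:, 1] - box.y0
            r = box.x1 - locs[:, 0]
            b = box.y1 - locs[:, 1]
            dist = np.stack([l, t, r, b], axis=1)
            inside = dist.min(axis=1) > 0
            m = dist.max(axis=1)
            assigned = inside & (m > lo) & (m <= hi) & (box.area < best_area)
            if not assigned.any():
                continue
            best_area[assigned] = box.area
            cls[assigned] = 1.0
            reg[assigned] = dist[assigned]
            la, ra_ = l[assigned], r[assigned]
            ta, ba = t[assigned], b[assigned]
            ctr[assigned] = np.sqrt(
                (np.minimum(la, ra_) / np.maximum(la, ra_))
                * (np.minimum(ta, ba) / np.maximum(ta, ba))
            )
        out.append({"level": p, "cls": cls, "reg": reg, "ctr": ctr, "locations": locs})
    return out


def decode_boxes(locations: np.ndarray, distances: np.ndarray,
                 scores: np.ndarray | None = None) -> list[CandidateBox]:
    """Invert the distance encoding: box = (x-l, y-t, x+r, y+b)."""
    x, y = locations[:, 0], locations[:, 1]
    l, t, r, b = distances.T
    boxes = []
    for i in range(len(locations)):
        conf = 1.0 if scores is None else float(np.clip(scores[i], 0.0, 1.0))
        boxes.append(CandidateBox(float(x[i] - l[i]), float(y[i] - t[i]),
                                  float(x[i] + r[i]), float(y[i] + b[i]), conf))
    return boxes


def nms(boxes: list[CandidateBox], iou_threshold: float = 0.4) -> list[CandidateBox]:
    """Greedy non-maximum suppression; survivors are pairwise IoU-separated
    and sorted by descending confidence. Output is a subset of the input."""
    remaining = sorted(boxes, key=lambda b: -b.confidence)
    kept: list[CandidateBox] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [b for b in remaining if best.iou(b) < iou_threshold]
    return kept


def detect(model: FcosDetector, image: np.ndarray,
           score_threshold: float | None = None,
           nms_threshold: float | None = None) -> list[CandidateBox]:
    """Run the detector on one HWC uint8 (or CHW float) frame.

    Confidence is classification probability times centerness; boxes under
    the score threshold are dropped, the rest NMS-merged and returned sorted
    by descending confidence.  An empty list means "no defect candidate".
    """
    cfg = model.config
    score_threshold = cfg.score_threshold if score_threshold is None else score_threshold
    nms_threshold = cfg.nms_threshold if nms_threshold is None else nms_threshold
    if image.ndim == 3 and image.shape[2] == 3:
        x = (image.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]
    else:
        x = np.asarray(image, dtype=np.float32)[None] if image.ndim == 3 else image
    hw = x.shape[-1]
    model.eval()
    outputs = model(Tensor(x))
    candidates: list[CandidateBox] = []
    for out in outputs:
        n = out["cls"].shape[-1] * out["cls"].shape[-2]
        cls = 1.0 / (1.0 + np.exp(-out["cls"].data.reshape(n)))
        ctr = 1.0 / (1.0 + np.exp(-out["ctr"].data.reshape(n)))
        scores = cls * ctr
        keep = scores >= score_threshold
        if not keep.any():
            continue
        locs = level_locations(hw, out["stride"])[keep]
        dists = out["reg"].data.reshape(4, n).T[keep]
        for box in decode_boxes(locs, dists, scores[keep]):
            x0, y0 = max(0.0, box.x0), max(0.0, box.y0)
            x1, y1 = min(float(hw), box.x1), min(float(hw), box.y1)
            if x1 - x0 >= 1 and y1 - y0 >= 1:
                candidates.append(CandidateBox(x0, y0, x1, y1, box.confidence))
    return nms(candidates, nms_threshold)


def _iou_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean -log IoU between predicted and target (l, t, r, b) distances of
    boxes anchored at the same location; both sets of distances positive."""
    eps = 1e-6
    tgt = Tensor(np.asarray(target, dtype=np.float32))
    pl, pt, pr, pb = (pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3])
    tl, tt, tr, tb = (tgt[:, 0], tgt[:, 1], tgt[:, 2], tgt[:, 3])
    inter_w = nn.minimum(pl, tl) + nn.minimum(pr, tr)
    inter_h = nn.minimum(pt, tt) + nn.minimum(pb, tb)
    inter = inter_w * inter_h
    area_p = (pl + pr) * (pt + pb)
    area_t = (tl + tr) * (tt + tb)
    union = area_p + area_t - inter
    iou = (inter + eps) / (union + eps)
    return -(iou.log().mean())


def _detection_loss(outputs: list[dict], targets_batch: list[list[dict]]) -> Tensor:
    """Focal classification + IoU regression + centerness loss for a batch.

    The focal term runs over every location; the IoU and centerness terms
    only over positive locations, so a box-free batch exercises the
    classification-only path with zero regression contribution.
    """
    cls_terms = []
    reg_loss = Tensor(0.0)
    ctr_loss = Tensor(0.0)
    total_pos = 0
    for li, out in enumerate(outputs):
        nb = out["cls"].shape[0]
        p = out["cls"].shape[2] * out["cls"].shape[3]
        cls_logits = out["cls"].reshape(nb, p)
        ctr_logits = out["ctr"].reshape(nb, p)
        reg = out["reg"].reshape(nb, 4, p).transpose(0, 2, 1)  # (N, P, 4)
        cls_t = np.stack([targets_batch[i][li]["cls"] for i in range(nb)])
        reg_t = np.stack([targets_batch[i][li]["reg"] for i in range(nb)])
        ctr_t = np.stack([targets_batch[i][li]["ctr"] for i in range(nb)])
        cls_terms.append(nn.sigmoid_focal_loss(cls_logits, cls_t))
        pos = cls_t > 0
        n_pos = int(pos.sum())
        if n_pos:
            total_pos += n_pos
            reg_loss = reg_loss + _iou_loss(reg[pos], reg_t[pos]) * n_pos
            ctr_loss = ctr_loss + nn.binary_cross_entropy_with_logits(
                ctr_logits[pos], ctr_t[pos], reduction="sum")
    denom = float(max(total_pos, 1))
    cls_loss = cls_terms[0]
    for term in cls_terms[1:]:
        cls_loss = cls_loss + term
    return cls_loss * (1.0 / denom) + reg_loss * (1.0 / denom) + ctr_loss * (1.0 / denom)


def train_detector(model: FcosDetector, images: np.ndarray,
                   boxes_per_image: list[list[CandidateBox]],
                   config: DetConfig | None = None) -> dict:
    """Train on (N, 3, H, W) float32 images with per-image ground-truth boxes.

    Returns a history dict with per-epoch mean loss. Deterministic for a
    fixed config seed and pre-seeded model build; ``epochs=0`` leaves the
    weights untouched.
    """
    config = config or model.config
    if len(images) == 0:
        raise ValueError("empty training set")
    hw = images.shape[-1]
    targets = [encode_targets(b, hw, config.levels) for b in boxes_per_image]
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = {"loss": []}
    for _ in range(config.epochs):
        model.train()
        order = rng.permutation(len(images))
        total = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            outputs = model(Tensor(images[idx]))
            loss = _detection_loss(outputs, [targets[j] for j in idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        history["loss"].append(total / len(images))
    return history
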