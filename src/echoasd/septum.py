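"""Stage-3 refinement: septum-region extraction and candidate filtering.

The inter-atrial septum is the only anatomically plausible site for a
secundum defect, so candidates outside it are false positives by
construction.  The region is computed deterministically from the atrium
mask: convex hull of LA union RA, minus the chambers themselves, then a
morphological dilation to allow a decision margin.

The hull is computed on pixel centers with exact integer arithmetic (monotone
chain + half-plane rasterization, boundary pixels included), so its pixel set
is reproducible bit-for-bit across platforms.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import dilation, disk

from .types import LA, RA, AtriaMask, CandidateBox, CaseCall, ImageCall, SeptumRegion

__all__ = [
    "convex_hull_mask",
    "extract_septum",
    "filter_candidates",
    "image_call",
    "case_call",
    "MissingChamberError",
]


class MissingChamberError(ValueError):
    """The atrium mask lacks a chamber needed for septum extraction —
    usually a sign of segmentation failure upstream."""


def _hull_vertices(points: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Convex hull (Andrew's monotone chain) of integer (x, y) points.

    Exact integer arithmetic; returns vertices in counter-clockwise order in
    image coordinates (y grows downward). Collinear inputs come back as a
    1- or 2-point chain (the extreme points).
    """
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _pixel_grid(shape: tuple[int, int]):
    if shape not in _GRID_CACHE:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        _GRID_CACHE[shape] = (yy, xx)
    return _GRID_CACHE[shape]


def convex_hull_mask(region: np.ndarray) -> np.ndarray:
    """Filled rasterization of the convex hull of a binary region.

    A pixel belongs to the output iff its center lies inside or on the
    boundary of the convex hull of the foreground pixel centers.  The result
    is a superset of the input.  Raises on an empty region.
    """
    region = np.asarray(region, dtype=bool)
    ys, xs = np.nonzero(region)
    if len(xs) == 0:
        raise ValueError("cannot take the convex hull of an empty region")
    verts = _hull_vertices(list(zip(xs.tolist(), ys.tolist())))
    h, w = region.shape
    yy, xx = _pixel_grid((h, w))

    if len(verts) == 1:
        return (xx == verts[0][0]) & (yy == verts[0][1])
    if len(verts) == 2:
        (x0, y0), (x1, y1) = verts
        # on-segment test: collinear and within the bounding box
        collinear = (x1 - x0) * (yy - y0) - (y1 - y0) * (xx - x0) == 0
        inside = (
            (xx >= min(x0, x1)) & (xx <= max(x0, x1))
            & (yy >= min(y0, y1)) & (yy <= max(y0, y1))
        )
        return collinear & inside

    out = np.ones((h, w), dtype=bool)
    for i in range(len(verts)):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % len(verts)]
        # half-plane to the left of each CCW edge (y axis points down)
        out &= (x1 - x0) * (yy - y0) - (y1 - y0) * (xx - x0) >= 0
    return out


def extract_septum(mask: AtriaMask, dilation_radius: int = 5) -> SeptumRegion:
    """Septum band: hull(LA union RA) minus the chambers, dilated by a disk.

    Raises :class:`MissingChamberError` naming the absent chamber when the
    mask lacks LA or RA (upstream segmentation failure).
    """
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be non-negative")
    labels = mask.labels if isinstance(mask, AtriaMask) else np.asarray(mask)
    la, ra = labels == LA, labels == RA
    for name, m in (("LA", la), ("RA", ra)):
        if not m.any():
            raise MissingChamberError(f"mask has no {name} region")
    atria = la | ra
    band = convex_hull_mask(atria) & ~atria
    if dilation_radius > 0:
        band = dilation(band, disk(dilation_radius))
    return SeptumRegion(band, dilation_radius)


def _box_pixel_slice(box: CandidateBox, shape) -> tuple[slice, slice] | None:
    """Integer pixel rows/cols covered by a half-open box, clipped to the grid."""
    x0 = max(0, int(np.floor(box.x0)))
    y0 = max(0, int(np.floor(box.y0)))
    x1 = min(shape[1], int(np.ceil(box.x1)))
    y1 = min(shape[0], int(np.ceil(box.y1)))
    if x0 >= x1 or y0 >= y1:
        return None
    return slice(y0, y1), slice(x0, x1)


def filter_candidates(
    candidates: list[CandidateBox],
    septum: SeptumRegion,
    min_overlap_frac: float = 0.2,
) -> list[CandidateBox]:
    """Keep candidates whose overlap with the septum band covers at least
    ``min_overlap_frac`` of the box's own pixel area.

    Order and confidences are preserved; the output is always a subset of the
    input.
    """
    if not 0.0 <= min_overlap_frac <= 1.0:
        raise ValueError("min_overlap_frac must lie in [0, 1]")
    kept = []
    for box in candidates:
        sl = _box_pixel_slice(box, septum.mask.shape)
        if sl is None:
            continue
        patch = septum.mask[sl]
        frac = patch.sum() / patch.size
        if frac >= min_overlap_frac:
            kept.append(box)
    return kept


def image_call(candidates: list[CandidateBox], cutoff: float = 0.95) -> ImageCall:
    """Frame-level decision: positive iff the best surviving candidate's
    confidence is >= cutoff; an empty candidate list is a negative call."""
    if not candidates:
        return ImageCall(False, 0.0, cutoff)
    best = max(c.confidence for c in candidates)
    return ImageCall(best >= cutoff, best, cutoff)


def case_call(image_calls: list[ImageCall], case_threshold: float = 0.6) -> CaseCall:
    """Case-level decision: positive iff the fraction of positive frame calls
    is >= case_threshold (default 0.6)."""
    if not image_calls:
        raise ValueError("case_call requires at least one image call")
    frac = sum(c.positive for c in image_calls) / len(image_calls)
    return CaseCall(frac >= case_threshold, frac, case_threshold)
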