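"""Septum geometry: hull rasterization, band extraction, filtering, calls."""

import numpy as np
import pytest

from echoasd.septum import (MissingChamberError, case_call, convex_hull_mask,
                            extract_septum, filter_candidates, image_call)
from echoasd.types import LA, RA, AtriaMask, CandidateBox, ImageCall


def hull_oracle(mask: np.ndarray) -> np.ndarray:
    """Brute-force half-plane test: a pixel center is in the hull iff it is
    on some segment or inside some triangle of foreground centers."""
    ys, xs = np.nonzero(mask)
    pts = list(zip(xs.tolist(), ys.tolist()))
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    import itertools

    for y in range(h):
        for x in range(w):
            p = (x, y)
            hit = p in pts
            if not hit:
                for a, b in itertools.combinations(pts, 2):
                    cross = (b[0] - a[0]) * (y - a[1]) - (b[1] - a[1]) * (x - a[0])
                    if cross == 0 and min(a[0], b[0]) <= x <= max(a[0], b[0]) \
                            and min(a[1], b[1]) <= y <= max(a[1], b[1]):
                        hit = True
                        break
            if not hit:
                for a, b, c in itertools.combinations(pts, 3):
                    area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                    if area2 == 0:
                        continue  # degenerate triangle: covered by segments
                    d1 = (b[0] - a[0]) * (y - a[1]) - (b[1] - a[1]) * (x - a[0])
                    d2 = (c[0] - b[0]) * (y - b[1]) - (c[1] - b[1]) * (x - b[0])
                    d3 = (a[0] - c[0]) * (y - c[1]) - (a[1] - c[1]) * (x - c[0])
                    if (d1 >= 0 and d2 >= 0 and d3 >= 0) or \
                       (d1 <= 0 and d2 <= 0 and d3 <= 0):
                        hit = True
                        break
            out[y, x] = hit
    return out


def test_hull_of_single_pixel_is_that_pixel():
    m = np.zeros((8, 8), bool)
    m[3, 5] = True
    hull = convex_hull_mask(m)
    assert hull.sum() == 1 and hull[3, 5]


def test_hull_of_rectangle_is_fixed_point():
    m = np.zeros((12, 12), bool)
    m[2:7, 3:9] = True
    assert np.array_equal(convex_hull_mask(m), m)


def test_hull_triangle_matches_half_plane_oracle():
    m = np.zeros((10, 10), bool)
    m[0, 0] = m[8, 0] = m[0, 8] = True
    hull = convex_hull_mask(m)
    assert np.array_equal(hull, hull_oracle(m))
    assert hull.sum() == 45  # lattice points with x + y <= 8


def test_hull_random_small_masks_match_oracle():
    rng = np.random.default_rng(17)
    for _ in range(150):
        m = np.zeros((8, 8), bool)
        k = int(rng.integers(1, 6))
        idx = rng.choice(64, size=k, replace=False)
        m[np.unravel_index(idx, (8, 8))] = True
        assert np.array_equal(convex_hull_mask(m), hull_oracle(m)), m.nonzero()


def test_hull_empty_region_raises():
    with pytest.raises(ValueError):
        convex_hull_mask(np.zeros((4, 4), bool))


def _rect_mask():
    labels = np.zeros((40, 40), np.uint8)
    labels[0:10, 0:10] = LA
    labels[0:10, 20:30] = RA
    return AtriaMask(labels)


def test_rectangle_fixture_septum_is_exactly_the_gap():
    """LA [0,10)x[0,10) and RA [20,30)x[0,10): hull minus chambers is the
    100-pixel band [10,20)x[0,10)."""
    region = extract_septum(_rect_mask(), 0)
    assert region.area == 100
    expected = np.zeros((40, 40), bool)
    expected[0:10, 10:20] = True
    assert np.array_equal(region.mask, expected)


def test_septum_disjoint_from_chambers_at_radius_zero():
    mask = _rect_mask()
    band = extract_septum(mask, 0).mask
    assert not (band & ((mask.labels == LA) | (mask.labels == RA))).any()


def test_dilation_monotone_in_radius():
    mask = _rect_mask()
    areas = [extract_septum(mask, r).area for r in (0, 1, 3, 6)]
    assert areas == sorted(areas)


def test_missing_chamber_raises_naming_it():
    labels = np.zeros((20, 20), np.uint8)
    labels[2:8, 2:8] = LA
    with pytest.raises(MissingChamberError, match="RA"):
        extract_septum(AtriaMask(labels), 0)
    labels[:] = 0
    labels[2:8, 2:8] = RA
    with pytest.raises(MissingChamberError, match="LA"):
        extract_septum(AtriaMask(labels), 0)


def test_filter_candidates_against_pixel_count_oracle():
    """Five boxes on the rectangle fixture: survivors must equal the
    per-box septum-pixel-fraction decisions."""
    septum = extract_septum(_rect_mask(), 0)
    boxes = [
        CandidateBox(12, 2, 18, 8, 0.9),    # fully inside the band
        CandidateBox(32, 2, 38, 8, 0.8),    # disjoint
        CandidateBox(8, 0, 12, 10, 0.7),    # half in  (20/40)
        CandidateBox(18, 0, 30, 10, 0.6),   # 20/120 in
        CandidateBox(0, 20, 10, 30, 0.5),   # disjoint, below the anatomy
    ]
    for frac in (0.0, 0.2, 0.5, 1.0):
        kept = filter_candidates(boxes, septum, frac)
        expected = []
        for b in boxes:
            patch = septum.mask[int(b.y0):int(b.y1), int(b.x0):int(b.x1)]
            if patch.sum() / patch.size >= frac:
                expected.append(b)
        assert kept == expected
        assert set(kept) <= set(boxes)
    assert filter_candidates([], septum, 0.2) == []


def test_box_fully_inside_always_retained_disjoint_always_removed():
    septum = extract_septum(_rect_mask(), 0)
    inside = CandidateBox(12, 2, 18, 8, 1.0)
    outside = CandidateBox(32, 12, 38, 18, 1.0)
    assert filter_candidates([inside], septum, 1.0) == [inside]
    assert filter_candidates([outside], septum, 1e-9) == []


def test_image_call_cutoff_boundaries():
    assert image_call([], 0.95).positive is False
    low = [CandidateBox(0, 0, 5, 5, 0.9432)]
    assert image_call(low, 0.95).positive is False      # 0.9432 < 0.95
    at = [CandidateBox(0, 0, 5, 5, 0.95)]
    assert image_call(at, 0.95).positive is True        # >= is positive


def test_case_call_fraction_rule():
    pos = ImageCall(True, 0.99, 0.95)
    neg = ImageCall(False, 0.1, 0.95)
    assert case_call([pos] * 4, 0.6).positive is True
    assert case_call([neg] * 4, 0.6).positive is False
    # 3 of 5 positive at threshold 0.6: 0.6 >= 0.6 -> positive
    assert case_call([pos, pos, pos, neg, neg], 0.6).positive is True
    assert case_call([pos, pos, neg, neg, neg], 0.6).positive is False
    with pytest.raises(ValueError):
        case_call([], 0.6)
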