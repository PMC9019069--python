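"""Phantom generator: determinism, ground-truth consistency, dataset rules."""

from collections import Counter

import numpy as np
import pytest

from echoasd.phantom import (PhantomGeometryError, PhantomSpec, generate_dataset,
                             generate_frame, load_dataset, save_dataset)
from echoasd.septum import extract_septum
from echoasd.types import BACKGROUND, LA, LV, RA, RV, TARGET_VIEWS, VIEW_CLASSES


def test_same_spec_same_seed_is_bit_identical():
    spec = PhantomSpec(view_class="A4C", asd_positive=True, seed=5)
    a, b = generate_frame(spec), generate_frame(spec)
    assert np.array_equal(a.frame.image, b.frame.image)
    assert np.array_equal(a.mask.labels, b.mask.labels)
    assert a.boxes == b.boxes


def test_negative_frames_have_no_boxes():
    sample = generate_frame(PhantomSpec(view_class="subAS", asd_positive=False, seed=0))
    assert sample.boxes == []


@pytest.mark.parametrize("view", TARGET_VIEWS)
def test_jet_box_straddles_own_septum_band(view):
    """Ground-truth jet boxes must intersect the septum region recovered
    from the sample's own mask (radius 0)."""
    for seed in range(25):
        sample = generate_frame(PhantomSpec(view_class=view, asd_positive=True,
                                            seed=seed, image_size=128))
        band = extract_septum(sample.mask, 0).mask
        assert len(sample.boxes) >= 1
        for box in sample.boxes:
            patch = band[int(box.y0):int(box.y1), int(box.x0):int(box.x1)]
            assert patch.any(), f"{view} seed {seed}: jet box off the septum band"


def test_jet_septum_consistency_across_random_specs():
    """The jet/septum invariant over a large randomized family of specs."""
    rng = np.random.default_rng(99)
    for _ in range(250):
        spec = PhantomSpec(
            image_size=int(rng.choice([64, 96, 128])),
            view_class=str(rng.choice(TARGET_VIEWS)),
            asd_positive=True,
            septum_thickness=int(rng.integers(2, 6)),
            jet_length=int(rng.integers(10, 16)),
            jet_width=int(rng.integers(5, 9)),
            jet_polarity=str(rng.choice(["red", "blue"])),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sample = generate_frame(spec)
        band = extract_septum(sample.mask, 0).mask
        for box in sample.boxes:
            assert band[int(box.y0):int(box.y1), int(box.x0):int(box.x1)].any()


def test_mask_labels_within_code_set():
    for view in VIEW_CLASSES:
        sample = generate_frame(PhantomSpec(view_class=view, seed=3))
        assert set(np.unique(sample.mask.labels)) <= {BACKGROUND, LA, RA, LV, RV}


def test_parameter_validation():
    with pytest.raises(PhantomGeometryError):
        generate_frame(PhantomSpec(image_size=32))
    with pytest.raises(PhantomGeometryError):
        generate_frame(PhantomSpec(septum_thickness=0))
    with pytest.raises(PhantomGeometryError):
        generate_frame(PhantomSpec(jet_length=100, image_size=256))
    with pytest.raises(PhantomGeometryError):
        generate_frame(PhantomSpec(view_class="other", asd_positive=True))
    with pytest.raises(PhantomGeometryError):
        # chambers demonstrably cannot fit: enormous axes
        generate_frame(PhantomSpec(view_class="subAS",
                                   atrium_axes={"LA": (200, 200), "RA": (200, 200)}))


def test_dataset_single_class_mix():
    mix = {v: 0.0 for v in VIEW_CLASSES}
    mix["other"] = 1.0
    samples = generate_dataset(10, class_mix=mix, positive_rate=0.0, seed=0,
                               image_size=64)
    assert all(s.view_label == "other" for s in samples)


def test_dataset_positive_count_is_exact_not_bernoulli():
    samples = generate_dataset(100, positive_rate=0.3, seed=4, image_size=64)
    assert sum(bool(s.boxes) for s in samples) == 30


def test_dataset_class_counts_within_one_of_quota():
    mix = {"A4C": 0.35, "LPS4C": 0.15, "sax_basal": 0.1, "subAS": 0.3, "other": 0.1}
    samples = generate_dataset(57, class_mix=mix, positive_rate=0.2, seed=8,
                               image_size=64)
    counts = Counter(s.view_label for s in samples)
    for view, p in mix.items():
        assert abs(counts[view] - 57 * p) <= 1


def test_dataset_roundtrip_and_manifest_determinism(tmp_path):
    samples = generate_dataset(12, positive_rate=0.5, seed=6, image_size=64,
                               out_dir=tmp_path / "a")
    generate_dataset(12, positive_rate=0.5, seed=6, image_size=64,
                     out_dir=tmp_path / "b")
    assert ((tmp_path / "a" / "manifest.json").read_text()
            == (tmp_path / "b" / "manifest.json").read_text())
    reloaded = load_dataset(tmp_path / "a" / "manifest.json")
    for orig, back in zip(samples, reloaded):
        assert np.array_equal(orig.mask.labels, back.mask.labels)
        assert np.array_equal(orig.frame.image, back.frame.image)
        assert orig.boxes == back.boxes


def _mask_features(labels: np.ndarray) -> np.ndarray:
    """Hand-crafted geometry features: chamber count and relative centroids."""
    feats = [0.0] * 7
    present = 0
    h, w = labels.shape
    cents = {}
    for i, code in enumerate((LA, RA, LV, RV)):
        region = labels == code
        if region.any():
            present += 1
            ys, xs = np.nonzero(region)
            cents[code] = (xs.mean() / w, ys.mean() / h)
    feats[0] = present
    if LA in cents and RA in cents:
        dx = cents[LA][0] - cents[RA][0]
        dy = cents[LA][1] - cents[RA][1]
        feats[1] = dx
        # unsigned tilt of the inter-atrial axis: the oblique views rotate
        # either way, so the signed angle would average out per class
        feats[2] = abs(np.arctan2(dy, abs(dx) + 1e-9))
        feats[3] = (cents[LA][1] + cents[RA][1]) / 2
    feats[4] = float(LV in cents)
    feats[5] = float(RV in cents)
    if LV in cents and RV in cents:
        feats[6] = cents[LV][1] - cents[RV][1]
    return np.array(feats)


def test_view_classes_separable_by_trivial_centroid_classifier():
    """Sanity bound on learnability: a nearest-centroid classifier over
    chamber-centroid features tells the five views apart (> 90 %)."""
    train = generate_dataset(250, positive_rate=0.0, seed=41, image_size=64)
    test = generate_dataset(250, positive_rate=0.0, seed=42, image_size=64)
    xt = np.stack([_mask_features(s.mask.labels) for s in train])
    yt = np.array([VIEW_CLASSES.index(s.view_label) for s in train])
    xv = np.stack([_mask_features(s.mask.labels) for s in test])
    yv = np.array([VIEW_CLASSES.index(s.view_label) for s in test])
    centroids = np.stack([xt[yt == k].mean(axis=0) for k in range(5)])
    pred = np.argmin(((xv[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1)
    assert (pred == yv).mean() > 0.9
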