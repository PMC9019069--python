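"""Synthetic cardiac-phantom frames with ground truth.

Clinical color-Doppler data cannot be redistributed, so every stage of the
pipeline is exercised on phantoms: a fan-shaped bright ultrasound sector on a
black background, dark elliptical atria separated by a thin echogenic septum,
optional ventricles, and — on defect-positive frames — a color-saturated jet
crossing the septum, mimicking transseptal shunt flow on Doppler. Each of the
four target views has a distinct chamber layout; "other" frames carry
randomized distractor geometry.

Layout templates (fractions of the image side, before per-sample jitter):

* ``subAS``     — LA and RA side by side at mid depth, vertical septum.
* ``A4C``       — four chambers, atria deep, ventricles shallow.
* ``LPS4C``     — the four-chamber layout rotated by a marked oblique angle.
* ``sax_basal`` — circular chamber wrapped by a crescent.
* ``other``     — one to three random ellipses, no chamber labels.

Everything is deterministic given the ``PhantomSpec`` seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk

from .types import (
    BACKGROUND,
    LA,
    LV,
    RA,
    RV,
    TARGET_VIEWS,
    VIEW_CLASSES,
    AtriaMask,
    CandidateBox,
    EchoFrame,
)

__all__ = ["PhantomSpec", "PhantomSample", "generate_frame", "generate_dataset",
           "load_dataset", "PhantomGeometryError"]

SECTOR_LEVEL = 110      # mean tissue gray inside the sector
CHAMBER_LEVEL = 28      # blood pools are near-anechoic
WALL_LEVEL = 185        # echogenic chamber walls


class PhantomGeometryError(ValueError):
    """Requested chamber geometry cannot be drawn on the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom frame.

    ``atrium_axes`` maps chamber names ("LA", "RA", optionally "LV", "RV") to
    (semi-axis-x, semi-axis-y) in pixels; unspecified chambers use defaults
    scaled to ``image_size``.  ``septum_thickness`` is the gap, in pixels,
    between the facing atrial walls. Jet dimensions are the full length
    (across the septum) and width of the color blob.  ``None`` for the
    septum/jet dimensions means "scale the 256 px defaults (6 / 24 / 12) to
    the requested image size".
    """

    image_size: int = 256
    view_class: str = "subAS"
    asd_positive: bool = False
    atrium_axes: dict | None = None
    septum_thickness: int | None = None
    jet_length: int | None = None
    jet_width: int | None = None
    jet_polarity: str = "red"
    speckle_noise_sd: float = 10.0
    seed: int = 0

    def resolved(self) -> "PhantomSpec":
        """Fill size-scaled defaults for unspecified septum/jet dimensions."""
        f = self.image_size / 256.0
        return replace(
            self,
            septum_thickness=(self.septum_thickness if self.septum_thickness is not None
                              else max(2, int(6 * f))),
            jet_length=(self.jet_length if self.jet_length is not None
                        else max(6, int(24 * f))),
            jet_width=(self.jet_width if self.jet_width is not None
                       else max(3, int(12 * f))),
        )

    def validate(self) -> None:
        if self.image_size < 64:
            raise PhantomGeometryError("image_size must be at least 64")
        if self.septum_thickness is not None and self.septum_thickness < 1:
            raise PhantomGeometryError("septum_thickness must be at least 1")
        jet = max(self.jet_length or 0, self.jet_width or 0)
        if jet > self.image_size / 4:
            raise PhantomGeometryError("jet dimensions must not exceed image_size/4")
        if self.view_class not in VIEW_CLASSES:
            raise PhantomGeometryError(f"unknown view class {self.view_class!r}")
        if self.jet_polarity not in ("red", "blue"):
            raise PhantomGeometryError("jet_polarity must be 'red' or 'blue'")
        if self.asd_positive and self.view_class not in TARGET_VIEWS:
            raise PhantomGeometryError(
                "ASD-positive frames require a target view with atrial chambers"
            )


@dataclass
class PhantomSample:
    frame: EchoFrame
    mask: AtriaMask
    boxes: list[CandidateBox]
    view_label: str
    content_group: str = "A2C"  # which chambers appear: A2C, A2C-V2C, A2C-LV, A2C-RV


# ---------------------------------------------------------------------------
# geometry helpers

def _rot(point, center, angle_deg):
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    dx, dy = point[0] - center[0], point[1] - center[1]
    return (center[0] + c * dx - s * dy, center[1] + s * dx + c * dy)


def _ellipse_mask(shape, center_xy, axes_xy, rotation_deg=0.0):
    m = np.zeros(shape, dtype=bool)
    # skimage's rotation runs opposite to a (x, y)-plane rotation with y down
    rr, cc = draw_ellipse(center_xy[1], center_xy[0], axes_xy[1], axes_xy[0],
                          shape=shape, rotation=np.deg2rad(-rotation_deg))
    m[rr, cc] = True
    return m


def _default_axes(s: float) -> dict:
    f = s / 256.0
    return {
        "LA": (30 * f, 36 * f),
        "RA": (30 * f, 36 * f),
        "LV": (34 * f, 46 * f),
        "RV": (34 * f, 46 * f),
    }


def _sector_mask(s: int) -> np.ndarray:
    """Fan-shaped sector: apex near the top center, opening downward."""
    apex = (s / 2.0, 0.04 * s)
    radius = 0.92 * s
    half_angle = np.deg2rad(40.0)
    yy, xx = np.mgrid[0:s, 0:s]
    dx, dy = xx - apex[0], yy - apex[1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dx, dy)  # angle from the downward axis
    return (r <= radius) & (dy >= 0) & (np.abs(theta) <= half_angle)


def _chamber_layout(spec: PhantomSpec, rng: np.random.Generator):
    """Return (list of (label, center_xy, axes_xy, rotation), septum axis info).

    The septum axis info is (midpoint_xy, unit vector LA->RA) used to place
    the jet; None for views without a defined septum.
    """
    s = float(spec.image_size)
    axes = dict(_default_axes(s))
    if spec.atrium_axes:
        axes.update({k: tuple(v) for k, v in spec.atrium_axes.items()})
    gap = float(spec.septum_thickness)
    jitter = rng.uniform(-0.02, 0.02, size=2) * s
    tilt = rng.uniform(-6.0, 6.0)
    chambers, septum = [], None
    view = spec.view_class

    if view == "subAS":
        yc = 0.56 * s + jitter[1]
        cx = 0.5 * s + jitter[0]
        la_c = (cx - gap / 2 - axes["LA"][0], yc)
        ra_c = (cx + gap / 2 + axes["RA"][0], yc)
        chambers = [(LA, la_c, axes["LA"], tilt), (RA, ra_c, axes["RA"], tilt)]
        septum = ((cx, yc), (1.0, 0.0))

    elif view in ("A4C", "LPS4C"):
        rot = tilt if view == "A4C" else rng.uniform(20.0, 30.0) * rng.choice([-1.0, 1.0])
        cx = 0.5 * s + jitter[0]
        y_at = 0.70 * s + jitter[1]
        y_vent = 0.34 * s + jitter[1]
        pts = {
            LA: (cx + gap / 2 + axes["LA"][0], y_at),
            RA: (cx - gap / 2 - axes["RA"][0], y_at),
            LV: (cx + gap / 2 + axes["LV"][0], y_vent),
            RV: (cx - gap / 2 - axes["RV"][0], y_vent),
        }
        centre = (cx, 0.5 * s)
        u = rng.uniform()
        present = [LA, RA, LV, RV] if u < 0.7 else ([LA, RA, LV] if u < 0.85 else [LA, RA, RV])
        name = {LA: "LA", RA: "RA", LV: "LV", RV: "RV"}
        chambers = [(lab, _rot(pts[lab], centre, rot), axes[name[lab]], rot)
                    for lab in present]
        mid = _rot(((pts[LA][0] + pts[RA][0]) / 2, y_at), centre, rot)
        direction = np.deg2rad(rot)
        septum = (mid, (np.cos(direction), np.sin(direction)))

    elif view == "sax_basal":
        # circular chamber wrapped by a crescent
        r_la = axes["LA"][0]
        la_c = (0.5 * s + jitter[0], 0.46 * s + jitter[1])
        ra_c = (la_c[0], la_c[1] + r_la + gap + 0.35 * axes["RA"][1])
        chambers = [(LA, la_c, (r_la, r_la), 0.0),
                    ("crescent", ra_c, (2.2 * r_la, 1.1 * axes["RA"][1]), tilt / 2)]
        septum = ((la_c[0], la_c[1] + r_la + gap / 2), (0.0, 1.0))

    elif view == "other":
        n_blobs = int(rng.integers(1, 4))
        for _ in range(n_blobs):
            c = (rng.uniform(0.25, 0.75) * s, rng.uniform(0.3, 0.8) * s)
            ax = (rng.uniform(0.05, 0.16) * s, rng.uniform(0.05, 0.16) * s)
            chambers.append((BACKGROUND, c, ax, rng.uniform(0, 180)))
    return chambers, septum


# ---------------------------------------------------------------------------
# public operations

def generate_frame(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom frame with its mask and ground-truth jet boxes.

    Deterministic: the same spec (including seed) yields bit-identical output.
    Raises :class:`PhantomGeometryError` when the requested chambers cannot be
    drawn disjointly inside the image.
    """
    spec.validate()
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    shape = (s, s)

    sector = _sector_mask(s)
    chambers, septum = _chamber_layout(spec, rng)

    labels = np.zeros(shape, dtype=np.uint8)
    chamber_union = np.zeros(shape, dtype=bool)
    crescent_cut = None
    for entry in chambers:
        lab, centre, ax, rot = entry
        if min(ax) < 2:
            raise PhantomGeometryError(f"chamber axes too small: {ax}")
        if not (0 <= centre[0] < s and 0 <= centre[1] < s):
            raise PhantomGeometryError("chamber centre outside the image")
        m = _ellipse_mask(shape, centre, ax, rot)
        if lab == "crescent":
            # carve the circular chamber (plus the septal gap) out of the ellipse
            circle_lab, circle_c, circle_ax, _ = chambers[0]
            hole = _ellipse_mask(shape, circle_c,
                                 (circle_ax[0] + spec.septum_thickness,
                                  circle_ax[1] + spec.septum_thickness))
            m &= ~hole
            lab = RA
        if m.sum() < 16:
            raise PhantomGeometryError("chamber does not fit inside the image")
        if lab != BACKGROUND and (m & chamber_union).any():
            raise PhantomGeometryError("chambers overlap; reduce axes or widen septum")
        if lab != BACKGROUND:
            labels[m] = lab
        chamber_union |= m

    # grayscale composition: sector tissue, echogenic walls, dark blood pools
    img = np.zeros(shape, dtype=np.float64)
    img[sector] = SECTOR_LEVEL
    walls = dilation(chamber_union, disk(3)) & ~chamber_union
    img[walls] = WALL_LEVEL
    img[chamber_union] = CHAMBER_LEVEL

    # multiplicative speckle, sd in gray levels at mid-gray
    noise = 1.0 + (spec.speckle_noise_sd / 128.0) * rng.standard_normal(shape)
    img = np.clip(img * noise, 0, 255)
    rgb = np.repeat(img[:, :, None], 3, axis=2).astype(np.uint8)

    boxes: list[CandidateBox] = []
    if spec.asd_positive:
        if septum is None:
            raise PhantomGeometryError("no septum in this view; cannot place a jet")
        (mx, my), (ux, uy) = septum
        # jet long axis along the LA->RA direction, crossing the septal gap
        off = rng.uniform(-0.15, 0.15) * spec.jet_length
        cx, cy = mx + off * ux, my + off * uy
        angle = np.degrees(np.arctan2(uy, ux))
        jet = _ellipse_mask(shape, (cx, cy),
                            (spec.jet_length / 2.0, spec.jet_width / 2.0), angle)
        if not jet.any():
            raise PhantomGeometryError("jet fell outside the image")
        channel = 0 if spec.jet_polarity == "red" else 2
        sat = rng.integers(225, 256)
        rgb[jet] = 0
        rgb[jet, channel] = sat
        ys, xs = np.nonzero(jet)
        boxes.append(CandidateBox(float(xs.min()), float(ys.min()),
                                  float(xs.max() + 1), float(ys.max() + 1), 1.0))

    frame = EchoFrame(rgb, view_label=spec.view_class)
    return PhantomSample(frame, AtriaMask(labels), boxes, spec.view_class,
                         _content_group(labels))


def _content_group(labels: np.ndarray) -> str:
    has_lv, has_rv = (labels == LV).any(), (labels == RV).any()
    if has_lv and has_rv:
        return "A2C-V2C"
    if has_lv:
        return "A2C-LV"
    if has_rv:
        return "A2C-RV"
    return "A2C"


def _class_counts(n: int, class_mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment; each count within +/-1 of n*p."""
    quotas = {v: n * class_mix.get(v, 0.0) for v in VIEW_CLASSES}
    counts = {v: int(np.floor(q)) for v, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(VIEW_CLASSES, key=lambda v: (counts[v] - quotas[v], v))
    for v in by_remainder[:short]:
        counts[v] += 1
    return counts


def generate_dataset(
    n: int,
    class_mix: dict[str, float] | None = None,
    positive_rate: float = 0.5,
    seed: int = 0,
    out_dir: str | Path | None = None,
    image_size: int = 256,
    speckle_noise_sd: float = 10.0,
) -> list[PhantomSample]:
    """Generate a reproducible phantom dataset.

    Exactly ``floor(n * positive_rate)`` samples are ASD-positive; positives
    are allocated to the first indices of a seeded shuffle of the
    jet-eligible (target-view) samples, so the count is deterministic rather
    than Bernoulli.  When ``out_dir`` is given, frames (PNG), masks (PNG
    label maps) and a JSON manifest are written there.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= positive_rate <= 1.0:
        raise ValueError("positive_rate must lie in [0, 1]")
    if class_mix is None:
        class_mix = {v: 0.2 for v in VIEW_CLASSES}
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"class proportions must sum to 1 (got {total})")

    counts = _class_counts(n, class_mix)
    views = [v for v in VIEW_CLASSES for _ in range(counts[v])]
    rng = np.random.default_rng(seed)
    rng.shuffle(views)

    n_pos = int(np.floor(n * positive_rate))
    eligible = [i for i, v in enumerate(views) if v in TARGET_VIEWS]
    if n_pos > len(eligible):
        raise ValueError(
            f"cannot place {n_pos} positives: only {len(eligible)} target-view samples"
        )
    order = rng.permutation(len(eligible))
    positive_idx = {eligible[j] for j in order[:n_pos]}

    samples = []
    for i, view in enumerate(views):
        polarity = "red" if rng.uniform() < 0.5 else "blue"
        spec = PhantomSpec(
            image_size=image_size,
            view_class=view,
            asd_positive=i in positive_idx,
            jet_polarity=polarity,
            speckle_noise_sd=speckle_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sample = generate_frame(spec)
        sample.frame.frame_index = i
        samples.append(sample)

    if out_dir is not None:
        save_dataset(samples, out_dir)
    return samples


def save_dataset(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, sample in enumerate(samples):
        img_name = f"frame_{i:05d}.png"
        iio.imwrite(out / "frames" / img_name, sample.frame.image)
        iio.imwrite(out / "masks" / img_name, sample.mask.labels)
        manifest.append({
            "image": f"frames/{img_name}",
            "mask": f"masks/{img_name}",
            "view": sample.view_label,
            "content_group": sample.content_group,
            "positive": bool(sample.boxes),
            "boxes": [b.as_list() for b in sample.boxes],
        })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out / "manifest.json"


def load_dataset(manifest_path: str | Path) -> list[PhantomSample]:
    import imageio.v3 as iio

    root = Path(manifest_path).parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    samples = []
    for i, rec in enumerate(manifest):
        frame = EchoFrame(iio.imread(root / rec["image"]), frame_index=i,
                          view_label=rec["view"])
        mask = AtriaMask(iio.imread(root / rec["mask"]))
        boxes = [CandidateBox(*b) for b in rec["boxes"]]
        samples.append(PhantomSample(frame, mask, boxes, rec["view"],
                                     rec.get("content_group", "A2C")))
    return samples
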