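"""Standard desk-scale phantom benchmarks.

These fix the conditions under which the package's learning behaviour is
assessed on a single CPU: dataset sizes, epochs and thresholds are part of
the benchmark definition, so tests, the command line and the acceptance
script all measure the same thing.  Problem sizes:

* view identification — 5 classes x 200 training / 50 validation frames at
  64 px, proxy teacher, reduced student, 10 distillation epochs;
* atrium segmentation — 200 training / 50 held-out target-view frames at
  64 px, reduced dense-dual-attention U-Net, 20 epochs;
* defect detection — 300 positive training / 50 held-out frames at 256 px
  (the native phantom resolution, so jet sizes sit inside the P3 range),
  10 epochs, recall at IoU 0.3;
* refinement — 200 target-view frames with ground-truth masks, true jet
  boxes and injected off-septum false candidates at confidence 0.99.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .detnet import DetConfig, build_detector, detect, train_detector
from .metrics import classification_metrics, dsc
from .phantom import generate_dataset
from .resnet import small_resnet
from .segnet import SEG_VARIANTS, SegConfig, build_segmentor, segment, train_segmentor
from .septum import extract_septum, filter_candidates, image_call
from .types import LA, RA, TARGET_VIEWS, CandidateBox, ConfusionCounts, VIEW_CODES
from .views import DistillConfig, build_proxy_teacher, frames_to_batch, train_distilled

__all__ = ["view_benchmark", "seg_benchmark", "det_benchmark",
           "refinement_benchmark", "seg_ablation"]

_TARGET_MIX = {v: 0.25 for v in TARGET_VIEWS}


def _view_data(n_per_class: int, seed: int, hw: int):
    mix = {v: 0.2 for v in VIEW_CODES}
    samples = generate_dataset(5 * n_per_class, class_mix=mix, positive_rate=0.3,
                               seed=seed, image_size=hw)
    x = frames_to_batch([s.frame.image for s in samples], hw)
    y = np.array([VIEW_CODES[s.view_label] for s in samples])
    return x, y


def view_benchmark(seed: int = 0, n_train_per_class: int = 200,
                   n_val_per_class: int = 50, epochs: int = 10, hw: int = 64) -> dict:
    """Train the distilled desk-scale view classifier and report accuracy.

    Returns {'val_accuracy', 'history', 'student'}.
    """
    xt, yt = _view_data(n_train_per_class, seed, hw)
    xv, yv = _view_data(n_val_per_class, seed + 1, hw)
    nn.manual_seed(seed)
    teacher = build_proxy_teacher(5, width=24)
    student = small_resnet(5, width=16)
    config = DistillConfig(epochs=epochs, seed=seed)
    history = train_distilled(teacher, student, (xt, yt), (xv, yv), config,
                              train_teacher_epochs=4)
    return {"val_accuracy": history["val_accuracy"], "history": history,
            "student": student}


def _seg_data(n: int, seed: int, hw: int):
    samples = generate_dataset(n, class_mix=_TARGET_MIX, positive_rate=0.0,
                               seed=seed, image_size=hw)
    x = np.stack([(s.frame.image.astype(np.float32) / 255.0).transpose(2, 0, 1)
                  for s in samples])
    # ventricle labels collapse to background in 3-class mode
    y = np.stack([np.where(s.mask.labels > RA, 0, s.mask.labels)
                  for s in samples]).astype(np.int64)
    return samples, x, y


def _desk_seg_config(variant: str, seed: int, epochs: int) -> SegConfig:
    return SegConfig(variant=variant, base_width=8, depth=4, growth_rate=8,
                     add_coords=True, epochs=epochs, seed=seed)


def seg_benchmark(seed: int = 0, n_train: int = 200, n_test: int = 50,
                  epochs: int = 20, hw: int = 64,
                  variant: str = "dense_dual_attention") -> dict:
    """Train the desk-scale segmentor; report held-out mean LA/RA Dice."""
    _, xt, yt = _seg_data(n_train, seed + 100, hw)
    test_samples, _, yv = _seg_data(n_test, seed + 200, hw)
    nn.manual_seed(seed)
    config = _desk_seg_config(variant, seed, epochs)
    model = build_segmentor(config=config)
    history = train_segmentor(model, xt, yt, config)
    scores = []
    for sample, gt in zip(test_samples, yv):
        pred = segment(model, sample.frame, hw)
        for code in (LA, RA):
            d = dsc(pred.labels == code, gt == code)
            if d is not None:
                scores.append(d)
    return {"mean_dsc": float(np.mean(scores)), "history": history, "model": model}


def seg_ablation(seeds=(0, 1, 2), n_train: int = 60, n_test: int = 16,
                 epochs: int = 6, hw: int = 64) -> dict:
    """Mean held-out Dice for all four segmentor variants across seeds."""
    table: dict[str, dict[int, float]] = {v: {} for v in SEG_VARIANTS}
    for seed in seeds:
        for variant in SEG_VARIANTS:
            result = seg_benchmark(seed=seed, n_train=n_train, n_test=n_test,
                                   epochs=epochs, hw=hw, variant=variant)
            table[variant][seed] = result["mean_dsc"]
    return table


def det_benchmark(seed: int = 0, n_train: int = 300, n_test: int = 50,
                  epochs: int = 10, hw: int = 256, iou_threshold: float = 0.3) -> dict:
    """Train the desk-scale detector on positive phantoms; report the
    fraction of held-out jets recovered at the IoU threshold."""
    train = generate_dataset(n_train, class_mix=_TARGET_MIX, positive_rate=1.0,
                             seed=seed + 300, image_size=hw)
    test = generate_dataset(n_test, class_mix=_TARGET_MIX, positive_rate=1.0,
                            seed=seed + 400, image_size=hw)
    x = np.stack([(s.frame.image.astype(np.float32) / 255.0).transpose(2, 0, 1)
                  for s in train])
    boxes = [s.boxes for s in train]
    nn.manual_seed(seed)
    config = DetConfig(epochs=epochs, learning_rate=3e-3, seed=seed)
    model = build_detector(config=config)
    history = train_detector(model, x, boxes, config)
    hits = 0
    for sample in test:
        dets = detect(model, sample.frame.image)
        if any(d.iou(sample.boxes[0]) >= iou_threshold for d in dets[:5]):
            hits += 1
    return {"recall": hits / len(test), "history": history, "model": model}


def refinement_benchmark(seed: int = 0, n_frames: int = 200, hw: int = 256,
                         fp_confidence: float = 0.99, cutoff: float = 0.95,
                         dilation_radius: int = 5, min_overlap_frac: float = 0.2) -> dict:
    """Frame-call precision/recall before vs after septum filtering.

    Half the frames carry a true jet (kept as a confident candidate), and
    every frame receives one or two injected off-septum false candidates at
    ``fp_confidence``; ground-truth masks drive the refinement, isolating
    the geometry stage from detector quality.
    """
    samples = generate_dataset(n_frames, class_mix=_TARGET_MIX, positive_rate=0.5,
                               seed=seed + 500, image_size=hw)
    rng = np.random.default_rng(seed + 501)
    rows = []
    for sample in samples:
        band = extract_septum(sample.mask, dilation_radius)
        candidates = [CandidateBox(b.x0, b.y0, b.x1, b.y1, fp_confidence)
                      for b in sample.boxes]
        for _ in range(int(rng.integers(1, 3))):
            candidates.append(_off_septum_box(band.mask, rng, fp_confidence))
        refined = filter_candidates(candidates, band, min_overlap_frac)
        assert set(refined) <= set(candidates)
        rows.append({
            "truth": bool(sample.boxes),
            "before": image_call(candidates, cutoff).positive,
            "after": image_call(refined, cutoff).positive,
        })

    out = {}
    for stage in ("before", "after"):
        c = ConfusionCounts()
        for row in rows:
            pred, gt = row[stage], row["truth"]
            if pred and gt:
                c.tp += 1
            elif pred:
                c.fp += 1
            elif gt:
                c.fn += 1
            else:
                c.tn += 1
        out[stage] = classification_metrics(c)
    out["precision_gain"] = out["after"]["precision"] - out["before"]["precision"]
    out["recall_drop"] = out["before"]["recall"] - out["after"]["recall"]
    return out


def _off_septum_box(band: np.ndarray, rng: np.random.Generator,
                    confidence: float, size: int = 20) -> CandidateBox:
    """A random box with zero septum overlap (an anatomically implausible
    candidate, as a failed detection would produce)."""
    h, w = band.shape
    for _ in range(200):
        x0 = int(rng.integers(0, w - size))
        y0 = int(rng.integers(0, h - size))
        if not band[y0 : y0 + size, x0 : x0 + size].any():
            return CandidateBox(float(x0), float(y0), float(x0 + size),
                                float(y0 + size), confidence)
    raise RuntimeError("could not place an off-septum box")
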