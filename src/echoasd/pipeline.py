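"""End-to-end orchestration: view routing, segmentation + detection,
refinement, frame- and case-level calls, reporting, and DICOM splitting.

Stage 1 classifies each frame's view; only frames in one of the four target
views proceed.  Stage 2 runs atrium segmentation and defect-candidate
detection for each routed frame; the two are independent per frame, so their
contract is order-free (they may run concurrently) and the resulting bundle
is identical either way.  Stage 3 extracts the septum band from the
segmentation, drops candidates outside it, and issues frame calls at the
confidence cut-off (default 0.95) and a case call at the positive-fraction
threshold (default 0.6).

Frames whose segmentation lacks a chamber cannot be refined; they keep their
unrefined candidates and are flagged, so downstream readers can see that a
positive call there rests on an unrefined detection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import classification_metrics
from .septum import MissingChamberError, extract_septum, filter_candidates, image_call, case_call
from .types import (TARGET_VIEWS, AtriaMask, CandidateBox, CaseCall, ConfusionCounts,
                    EchoFrame, ImageCall)

logger = logging.getLogger("echoasd")

__all__ = ["PipelineConfig", "FrameRecord", "CaseBundle", "run_case", "report",
           "split_dicom"]


@dataclass
class PipelineConfig:
    view_hw: int = 64             # classifier input resolution
    seg_hw: int = 64              # segmentor input resolution
    cutoff: float = 0.95          # frame-level confidence cut-off
    case_threshold: float = 0.6   # fraction of positive frames for a positive case
    dilation_radius: int = 5      # septum margin at 256 px; scales with image size
    min_overlap_frac: float = 0.2
    score_threshold: float = 0.05
    use_ground_truth_views: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dict(self.__dict__), fh)


@dataclass
class FrameRecord:
    frame_index: int
    view: str                      # routed view (predicted, or ground truth if configured)
    predicted_view: str
    is_target: bool
    mask: AtriaMask | None = None
    candidates: list[CandidateBox] = field(default_factory=list)
    refined: list[CandidateBox] = field(default_factory=list)
    call: ImageCall | None = None
    segmentation_failed: bool = False


@dataclass
class CaseBundle:
    case_id: str
    frames: list[FrameRecord]
    case_call: CaseCall | None
    flags: list[str] = field(default_factory=list)


def _scaled_radius(radius: int, hw: int) -> int:
    return max(1, int(round(radius * hw / 256)))


def run_case(frames: list[EchoFrame], models: dict, config: PipelineConfig | None = None) -> CaseBundle:
    """Run the three stages over one case's frames.

    ``models`` must provide 'view', 'seg' and 'det'.  Every input frame
    appears exactly once in the bundle with its view prediction; only
    target-view frames carry masks, candidates and calls.  Output is
    deterministic for fixed models and config.
    """
    from .detnet import detect
    from .segnet import segment
    from .views import predict_views

    config = config or PipelineConfig()
    for key in ("view", "seg", "det"):
        if key not in models:
            raise ValueError(f"missing model {key!r}")
    if not frames:
        raise ValueError("run_case requires at least one frame")
    case_id = frames[0].case_id

    predicted, _ = predict_views(models["view"], [f.image for f in frames],
                                 hw=config.view_hw)
    records: list[FrameRecord] = []
    flags: list[str] = []
    for frame, pred_view in zip(frames, predicted):
        routed = frame.view_label if (config.use_ground_truth_views
                                      and frame.view_label) else pred_view
        rec = FrameRecord(frame.frame_index, routed, pred_view,
                          routed in TARGET_VIEWS)
        if rec.is_target:
            # segmentation and detection are independent given the frame;
            # order of the two calls does not affect the bundle
            rec.mask = segment(models["seg"], frame, hw=config.seg_hw)
            rec.candidates = detect(models["det"], frame.image,
                                    score_threshold=config.score_threshold)
            hw = frame.image.shape[0]
            try:
                band = extract_septum(rec.mask, _scaled_radius(config.dilation_radius, hw))
                rec.refined = filter_candidates(rec.candidates, band,
                                                config.min_overlap_frac)
            except MissingChamberError as err:
                rec.segmentation_failed = True
                rec.refined = list(rec.candidates)
                flags.append(f"frame {frame.frame_index}: {err}")
                logger.warning("case %s frame %d: refinement skipped (%s)",
                               case_id, frame.frame_index, err)
            rec.call = image_call(rec.refined, config.cutoff)
        logger.info("case %s frame %d: view=%s target=%s candidates=%d refined=%d",
                    case_id, frame.frame_index, rec.view, rec.is_target,
                    len(rec.candidates), len(rec.refined))
        records.append(rec)

    target_calls = [r.call for r in records if r.call is not None]
    if target_calls:
        call = case_call(target_calls, config.case_threshold)
    else:
        call = CaseCall(False, 0.0, config.case_threshold)
        flags.append("no target-view frames; case defaults to negative")
        logger.warning("case %s: no target-view frames", case_id)
    return CaseBundle(case_id, records, call, flags)


def _tally(calls: list[bool], truth: list[bool]) -> ConfusionCounts:
    c = ConfusionCounts()
    for pred, gt in zip(calls, truth):
        if pred and gt:
            c.tp += 1
        elif pred and not gt:
            c.fp += 1
        elif not pred and gt:
            c.fn += 1
        else:
            c.tn += 1
    return c


def report(bundles: list[CaseBundle], truth: dict, config: PipelineConfig | None = None) -> dict:
    """Per-view and mean frame-level metrics before vs after refinement,
    plus a case-level row.

    ``truth`` maps case id -> {frame_index -> bool positive}; the case truth
    is "any positive frame".  "Before" applies the confidence cut-off to the
    unrefined candidates, "after" to the refined ones, on the same frames.
    """
    config = config or PipelineConfig()
    per_view: dict[str, dict[str, list]] = {
        v: {"before": [], "after": [], "truth": []} for v in TARGET_VIEWS}
    case_calls, case_truth = [], []
    for bundle in bundles:
        frame_truth = truth.get(bundle.case_id, {})
        any_pos = any(frame_truth.values()) if frame_truth else False
        case_calls.append(bundle.case_call.positive if bundle.case_call else False)
        case_truth.append(any_pos)
        for rec in bundle.frames:
            if not rec.is_target or rec.view not in per_view:
                continue
            gt = bool(frame_truth.get(rec.frame_index, False))
            before = image_call(rec.candidates, config.cutoff).positive
            after = (rec.call.positive if rec.call is not None
                     else image_call(rec.refined, config.cutoff).positive)
            per_view[rec.view]["before"].append(before)
            per_view[rec.view]["after"].append(after)
            per_view[rec.view]["truth"].append(gt)

    table: dict[str, dict] = {}
    sums = {"before": ConfusionCounts(), "after": ConfusionCounts()}
    for view, rows in per_view.items():
        if not rows["truth"]:
            continue
        entry = {}
        for stage in ("before", "after"):
            counts = _tally(rows[stage], rows["truth"])
            sums[stage] = sums[stage] + counts
            entry[stage] = {"counts": counts.__dict__,
                            **classification_metrics(counts)}
        table[view] = entry
    if sums["before"].total:
        table["all_views"] = {
            stage: {"counts": sums[stage].__dict__,
                    **classification_metrics(sums[stage])}
            for stage in ("before", "after")
        }
    if case_truth:
        counts = _tally(case_calls, case_truth)
        table["case_level"] = {"counts": counts.__dict__,
                               **classification_metrics(counts)}
    return table


def split_dicom(path) -> list[EchoFrame]:
    """Split a multi-frame ultrasound DICOM into RGB frames in acquisition
    order, carrying case and frame metadata. Raises on single-frame or
    unreadable files."""
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as err:  # unreadable, missing pixel data, ...
        raise ValueError(f"cannot read DICOM file {path}: {err}") from err
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames < 2 or arr.ndim < 3:
        raise ValueError(f"{path} is not a multi-frame DICOM")
    case_id = str(getattr(ds, "PatientID", None) or Path(path).stem)
    frames = []
    for k in range(n_frames):
        frame = arr[k]
        if frame.ndim == 2:
            frame = np.repeat(frame[:, :, None], 3, axis=2)
        frames.append(EchoFrame(frame.astype(np.uint8), case_id=case_id, frame_index=k))
    return frames


def bundle_to_json(bundle: CaseBundle) -> dict:
    return {
        "case_id": bundle.case_id,
        "flags": bundle.flags,
        "case_call": None if bundle.case_call is None else {
            "positive": bundle.case_call.positive,
            "positive_fraction": bundle.case_call.positive_fraction,
            "threshold": bundle.case_call.threshold,
        },
        "frames": [
            {
                "frame_index": r.frame_index,
                "view": r.view,
                "predicted_view": r.predicted_view,
                "is_target": r.is_target,
                "segmentation_failed": r.segmentation_failed,
                "candidates": [b.as_list() for b in r.candidates],
                "refined": [b.as_list() for b in r.refined],
                "call": None if r.call is None else {
                    "positive": r.call.positive,
                    "max_confidence": r.call.max_confidence,
                    "cutoff": r.call.cutoff,
                },
            }
            for r in bundle.frames
        ],
    }
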