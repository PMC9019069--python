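"""Shared fixtures: small trained models and phantom cases.

Training fixtures are session-scoped so the cost is paid once; every run is
seeded, so the suite is deterministic end to end.
"""

from __future__ import annotations

import numpy as np
import pytest

from echoasd import nn
from echoasd.detnet import DetConfig, build_detector, train_detector
from echoasd.phantom import generate_dataset
from echoasd.resnet import small_resnet
from echoasd.segnet import SegConfig, build_segmentor, train_segmentor
from echoasd.types import RA, TARGET_VIEWS, VIEW_CODES
from echoasd.views import DistillConfig, build_proxy_teacher, frames_to_batch, train_distilled

TARGET_MIX = {v: 0.25 for v in TARGET_VIEWS}


@pytest.fixture(scope="session")
def view_model():
    samples = generate_dataset(150, positive_rate=0.3, seed=1001, image_size=64)
    x = frames_to_batch([s.frame.image for s in samples], 64)
    y = np.array([VIEW_CODES[s.view_label] for s in samples])
    nn.manual_seed(1001)
    teacher = build_proxy_teacher(5, width=16)
    student = small_resnet(5, width=12)
    config = DistillConfig(epochs=5, seed=1001)
    train_distilled(teacher, student, (x, y), None, config, train_teacher_epochs=2)
    return student


@pytest.fixture(scope="session")
def seg_model():
    samples = generate_dataset(60, class_mix=TARGET_MIX, positive_rate=0.0,
                               seed=1002, image_size=64)
    x = np.stack([(s.frame.image.astype(np.float32) / 255).transpose(2, 0, 1)
                  for s in samples])
    y = np.stack([np.where(s.mask.labels > RA, 0, s.mask.labels)
                  for s in samples]).astype(np.int64)
    nn.manual_seed(1002)
    config = SegConfig(variant="dense_dual_attention", base_width=8, depth=4,
                       growth_rate=8, add_coords=True, epochs=6, seed=1002)
    model = build_segmentor(config=config)
    train_segmentor(model, x, y, config)
    return model


@pytest.fixture(scope="session")
def det_model():
    samples = generate_dataset(80, class_mix=TARGET_MIX, positive_rate=1.0,
                               seed=1003, image_size=256)
    x = np.stack([(s.frame.image.astype(np.float32) / 255).transpose(2, 0, 1)
                  for s in samples])
    boxes = [s.boxes for s in samples]
    nn.manual_seed(1003)
    config = DetConfig(epochs=5, learning_rate=3e-3, seed=1003)
    model = build_detector(config=config)
    train_detector(model, x, boxes, config)
    return model


@pytest.fixture(scope="session")
def phantom_case():
    """A 20-frame case at 256 px: 12 target-view frames (6 with jets) + 8 other."""
    mix = {"A4C": 0.15, "LPS4C": 0.15, "sax_basal": 0.15, "subAS": 0.15, "other": 0.4}
    return generate_dataset(20, class_mix=mix, positive_rate=0.3, seed=1004,
                            image_size=256)
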