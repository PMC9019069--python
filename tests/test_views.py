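"""View classifier: distillation loss oracles, augmentation, training contract."""

import numpy as np
import pytest

from echoasd import nn
from echoasd.nn import Tensor
from echoasd.phantom import PhantomSpec, generate_frame
from echoasd.resnet import small_resnet
from echoasd.views import (DistillConfig, apply_augment, augment, build_proxy_teacher,
                           build_student, distill_loss, frames_to_batch, train_distilled)


def test_student_parameter_count_head_arithmetic():
    """The 5- and 4-class student heads differ by exactly one 512-wide
    output unit (512 weights + 1 bias)."""
    nn.manual_seed(0)
    n5 = nn.count_parameters(build_student(5))
    n4 = nn.count_parameters(build_student(4))
    assert n5 - n4 == 512 + 1
    with pytest.raises(ValueError):
        build_student(1)


def test_student_probabilities_normalized():
    nn.manual_seed(0)
    model = build_student(5).eval()
    x = Tensor(np.random.default_rng(0).normal(size=(2, 3, 64, 64)).astype(np.float32))
    p = model.predict_proba(x).data
    assert p.shape == (2, 5)
    assert np.abs(p.sum(axis=1) - 1).max() < 1e-5


def test_distill_loss_kl_zero_when_logits_match():
    cfg = DistillConfig(temperature=2.0, kd_weight=1.0)
    logits = Tensor(np.random.default_rng(1).normal(size=(3, 5)))
    labels = np.array([0, 1, 2])
    assert abs(distill_loss(logits, logits, labels, cfg).item()) < 1e-6


def test_distill_loss_reduces_to_cross_entropy_without_kd():
    cfg = DistillConfig(kd_weight=0.0)
    rng = np.random.default_rng(2)
    s = Tensor(rng.normal(size=(4, 5)))
    t = Tensor(rng.normal(size=(4, 5)))
    labels = np.array([0, 4, 2, 1])
    assert abs(distill_loss(s, t, labels, cfg).item()
               - nn.cross_entropy(s, labels).item()) < 1e-6


def test_distill_loss_matches_hand_arithmetic():
    """Uniform teacher over 5 classes vs student logits (1,0,0,0,0) at T=1:
    KL computed by direct summation of p*log(p/q)."""
    teacher = Tensor(np.zeros((1, 5)))          # softmax -> uniform
    student = Tensor(np.array([[1.0, 0, 0, 0, 0]]))
    q = np.exp(student.data[0]) / np.exp(student.data[0]).sum()
    expected_kl = sum(0.2 * np.log(0.2 / q[i]) for i in range(5))
    cfg = DistillConfig(temperature=1.0, kd_weight=1.0)
    got = distill_loss(student, teacher, np.array([0]), cfg).item()
    assert abs(got - expected_kl) < 1e-6


def test_temperature_must_be_positive():
    with pytest.raises(ValueError):
        DistillConfig(temperature=-1.0)


def test_augment_identity_and_involution():
    img = generate_frame(PhantomSpec(view_class="subAS", seed=0, image_size=64)).frame.image
    assert np.array_equal(apply_augment(img), img)
    twice = apply_augment(apply_augment(img, flip_h=True), flip_h=True)
    assert np.array_equal(twice, img)
    a1 = augment(generate_frame(PhantomSpec(view_class="subAS", seed=0,
                                            image_size=64)).frame, seed=7)
    a2 = augment(generate_frame(PhantomSpec(view_class="subAS", seed=0,
                                            image_size=64)).frame, seed=7)
    assert np.array_equal(a1.image, a2.image)


def test_polar_rotation_preserves_sector_area():
    """Apex-centered rotation should keep the bright-sector pixel count
    within 2 % (interpolation loss only).  Measured inside the apex-centered
    disk that stays within the image under the rotation, so boundary
    clipping does not enter."""
    img = generate_frame(PhantomSpec(view_class="subAS", seed=1,
                                     speckle_noise_sd=0.0)).frame.image
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    in_disk = np.hypot(xx - w / 2.0, yy - 0.04 * h) <= w / 2.0 - 2
    before = ((img[:, :, 0] > 40) & in_disk).sum()
    rotated = apply_augment(img, angle=10.0)
    after = ((rotated[:, :, 0] > 40) & in_disk).sum()
    assert abs(after - before) / before < 0.02


def _tiny_view_data(n=40, hw=32, seed=0):
    rng = np.random.default_rng(seed)
    images, labels = [], []
    from echoasd.types import VIEW_CLASSES, VIEW_CODES
    for i in range(n):
        view = VIEW_CLASSES[i % 5]
        s = generate_frame(PhantomSpec(view_class=view, seed=int(rng.integers(1 << 30)),
                                       image_size=64))
        images.append(s.frame.image)
        labels.append(VIEW_CODES[view])
    return frames_to_batch(images, hw), np.array(labels)


def test_zero_epochs_leaves_student_unchanged():
    x, y = _tiny_view_data()
    nn.manual_seed(3)
    teacher = build_proxy_teacher(5, width=8)
    student = small_resnet(5, width=8)
    before = [p.data.copy() for p in student.parameters()]
    train_distilled(teacher, student, (x, y), None,
                    DistillConfig(epochs=0, seed=3))
    for old, p in zip(before, student.parameters()):
        assert np.array_equal(old, p.data)


def test_missing_class_raises():
    x, y = _tiny_view_data()
    keep = y != 2
    nn.manual_seed(3)
    teacher = build_proxy_teacher(5, width=8)
    student = small_resnet(5, width=8)
    with pytest.raises(ValueError, match="absent"):
        train_distilled(teacher, student, (x[keep], y[keep]), None,
                        DistillConfig(epochs=1, seed=3))
    with pytest.raises(ValueError, match="empty"):
        train_distilled(teacher, student, (x[:0], y[:0]), None,
                        DistillConfig(epochs=1, seed=3))


def test_training_is_deterministic_given_seed():
    x, y = _tiny_view_data()

    def run():
        nn.manual_seed(11)
        teacher = build_proxy_teacher(5, width=8)
        student = small_resnet(5, width=8)
        h = train_distilled(teacher, student, (x, y), (x, y),
                            DistillConfig(epochs=2, seed=11),
                            train_teacher_epochs=1)
        return h["val_accuracy"], h["kd_loss"]

    assert run() == run()
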