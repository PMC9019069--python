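"""Standard-view identification with knowledge distillation.

A five-way classifier (A4C, LPS4C, sax_basal, subAS, other) routes frames to
the downstream stages.  Training follows the teacher-student recipe: a large
split-attention teacher is trained first; the student is then trained jointly
on a KL term that matches the teacher's softened output distribution plus a
cross-entropy term, and finally fine-tuned on cross-entropy alone.  The
teacher plays no part at inference.

Model roles:

* student — ResNet-34 (about 21.3 M parameters at 5 classes);
* teacher — ResNeSt-200 (about 70.2 M parameters with the canonical
  1000-way head), constructible for parameter/MAC accounting;
* proxy teacher — a reduced residual net standing in for the full teacher in
  CPU-scale training runs, so the distillation code path is exercised
  end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, rotate

from . import nn
from .nn import Tensor
from .resnet import ResNet, resnet34, small_resnet
from .resnest import ResNeSt, resnest200
from .types import VIEW_CLASSES, VIEW_CODES, EchoFrame

__all__ = [
    "DistillConfig",
    "build_student",
    "build_teacher",
    "build_proxy_teacher",
    "distill_loss",
    "augment",
    "apply_augment",
    "train_distilled",
    "predict_views",
    "frames_to_batch",
]


@dataclass
class DistillConfig:
    temperature: float = 4.0
    kd_weight: float = 0.5     # weight of the KL term during joint training
    epochs: int = 10           # total; split between joint and fine-tune phases
    kd_fraction: float = 0.6   # fraction of epochs spent in the joint phase
    learning_rate: float = 2e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.kd_weight <= 1.0:
            raise ValueError("kd_weight must lie in [0, 1]")


def build_student(num_classes: int = 5) -> ResNet:
    """The 34-layer residual student (21,287,237 parameters at 5 classes)."""
    return resnet34(num_classes)


def build_teacher(num_classes: int = 1000) -> ResNeSt:
    """The 200-layer split-attention teacher (about 70.2 M parameters at the
    canonical 1000-class head)."""
    if num_classes < 2:
        raise ValueError("num_classes must be at least 2")
    return resnest200(num_classes)


def build_proxy_teacher(num_classes: int = 5, width: int = 24) -> ResNet:
    return small_resnet(num_classes, width=width)


def distill_loss(student_logits: Tensor, teacher_logits: Tensor,
                 labels: np.ndarray, config: DistillConfig) -> Tensor:
    """Joint distillation objective.

    kd_weight * T^2 * KL(softmax(teacher/T) || softmax(student/T))
    + (1 - kd_weight) * cross_entropy(student, labels)

    The T^2 factor keeps the KL gradient magnitude comparable across
    temperatures. The KL term is non-negative and vanishes iff the softened
    distributions coincide.
    """
    if student_logits.shape != teacher_logits.shape:
        raise ValueError("student and teacher logits must have the same shape")
    t = config.temperature
    kl = nn.kl_divergence(teacher_logits, student_logits, temperature=t)
    ce = nn.cross_entropy(student_logits, labels)
    return config.kd_weight * (t * t) * kl + (1.0 - config.kd_weight) * ce


# ---------------------------------------------------------------------------
# augmentation

def apply_augment(image: np.ndarray, flip_h: bool = False, flip_v: bool = False,
                  angle: float = 0.0) -> np.ndarray:
    """Apply the three view-training transforms with explicit switches.

    The polar rotation pivots about the fan apex — taken as (W/2, 0.04*H),
    the apex convention of this package's sector rendering — so the bright
    sector sweeps around its own origin as a transducer rotation would.
    """
    out = image
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    if angle != 0.0:
        h, w = out.shape[:2]
        out = rotate(out.astype(np.float64), angle, center=(w / 2.0, 0.04 * h),
                     preserve_range=True)
        out = np.clip(out, 0, 255)
    return np.ascontiguousarray(out.astype(image.dtype))


def augment(frame: EchoFrame, seed: int, max_angle: float = 15.0) -> EchoFrame:
    """Randomized augmentation: each flip independently with probability 0.5,
    plus an apex-centered rotation with angle uniform in [-max_angle, max_angle].
    Deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    flip_h = bool(rng.uniform() < 0.5)
    flip_v = bool(rng.uniform() < 0.5)
    angle = float(rng.uniform(-max_angle, max_angle))
    return EchoFrame(apply_augment(frame.image, flip_h, flip_v, angle),
                     frame.case_id, frame.frame_index, frame.view_label)


# ---------------------------------------------------------------------------
# training

def frames_to_batch(images: list[np.ndarray], hw: int) -> np.ndarray:
    """Resize HWC uint8 frames to (N, 3, hw, hw) float32 in [0, 1]."""
    out = np.empty((len(images), 3, hw, hw), dtype=np.float32)
    for i, img in enumerate(images):
        small = img if img.shape[:2] == (hw, hw) else resize(
            img, (hw, hw), preserve_range=True, anti_aliasing=True)
        out[i] = (small.astype(np.float32) / 255.0).transpose(2, 0, 1)
    return out


def _accuracy(model: nn.Module, x: np.ndarray, y: np.ndarray, batch: int = 64) -> float:
    model.eval()
    correct = 0
    for i in range(0, len(x), batch):
        logits = model(Tensor(x[i : i + batch])).data
        # argmax with ties broken toward the lowest class code
        correct += (logits.argmax(axis=1) == y[i : i + batch]).sum()
    return float(correct) / len(x)


def _train_epochs(model, x, y, epochs, config, loss_fn, rng):
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    losses = []
    for _ in range(epochs):
        model.train()
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            loss = loss_fn(model, Tensor(x[idx]), y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        losses.append(epoch_loss / len(x))
    return losses


def train_distilled(
    teacher: nn.Module,
    student: nn.Module,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None = None,
    config: DistillConfig | None = None,
    train_teacher_epochs: int = 0,
) -> dict:
    """Two-phase knowledge distillation; returns a history dict.

    Phase 1 trains the student jointly on the KL + CE objective against the
    (frozen) teacher's logits; phase 2 fine-tunes the student on CE alone.
    If ``train_teacher_epochs`` > 0 the teacher is first trained on CE.  The
    teacher is not needed at inference.
    """
    config = config or DistillConfig()
    x, y = train_set
    if len(x) == 0:
        raise ValueError("empty training set")
    n_classes = student.num_classes
    present = np.unique(y)
    if len(present) < n_classes:
        missing = sorted(set(range(n_classes)) - set(present.tolist()))
        raise ValueError(f"classes absent from the training split: {missing}")

    rng = np.random.default_rng(config.seed)
    history: dict = {"teacher_loss": [], "kd_loss": [], "ce_loss": []}

    def ce_only(model, xb, yb):
        return nn.cross_entropy(model(xb), yb)

    if train_teacher_epochs > 0:
        history["teacher_loss"] = _train_epochs(
            teacher, x, y, train_teacher_epochs, config, ce_only, rng)
    teacher.eval()

    kd_epochs = int(round(config.epochs * config.kd_fraction))
    ft_epochs = config.epochs - kd_epochs

    def kd_loss(model, xb, yb):
        t_logits = Tensor(teacher(xb).data)  # frozen: no gradient to teacher
        return distill_loss(model(xb), t_logits, yb, config)

    history["kd_loss"] = _train_epochs(student, x, y, kd_epochs, config, kd_loss, rng)
    history["ce_loss"] = _train_epochs(student, x, y, ft_epochs, config, ce_only, rng)

    history["train_accuracy"] = _accuracy(student, x, y)
    if val_set is not None:
        history["val_accuracy"] = _accuracy(student, val_set[0], val_set[1])
    return history


def predict_views(model: nn.Module, images: list[np.ndarray], hw: int = 64,
                  batch: int = 64) -> tuple[list[str], np.ndarray]:
    """Predict view classes for HWC uint8 frames; returns (names, probabilities)."""
    x = frames_to_batch(images, hw)
    model.eval()
    probs = []
    for i in range(0, len(x), batch):
        probs.append(model(Tensor(x[i : i + batch])).softmax(axis=1).data)
    probs = np.concatenate(probs, axis=0)
    codes = probs.argmax(axis=1)
    return [VIEW_CLASSES[c] for c in codes], probs
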