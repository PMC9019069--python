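"""Residual-network classifiers.

:func:`resnet34` is the standard 34-layer topology (7x7 stem, four stages of
basic blocks [3, 4, 6, 3], widths 64-512, global average pool, affine head)
used as the view-identification student.  :func:`small_resnet` is a
width/depth-reduced variant of the same design used for desk-scale training
benchmarks and as a proxy distillation teacher.
"""

from __future__ import annotations

from . import nn
from .nn import Tensor


def _conv_bn(cin: int, cout: int, k: int, stride: int = 1) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, padding=k // 2, bias=False),
        nn.BatchNorm2d(cout),
    )


class BasicBlock(nn.Module):
    def __init__(self, cin: int, cout: int, stride: int = 1):
        super().__init__()
        self.conv1 = _conv_bn(cin, cout, 3, stride)
        self.conv2 = _conv_bn(cout, cout, 3)
        self.downsample = _conv_bn(cin, cout, 1, stride) if (stride != 1 or cin != cout) else None

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.downsample is None else self.downsample(x)
        out = self.conv2(self.conv1(x).relu())
        return (out + identity).relu()


class ResNet(nn.Module):
    """Basic-block residual classifier; emits logits of length ``num_classes``."""

    def __init__(self, blocks_per_stage, widths, num_classes: int, stem_width: int = 64,
                 stem_kernel: int = 7, stem_pool: bool = True):
        super().__init__()
        self.num_classes = num_classes
        self.stem = _conv_bn(3, stem_width, stem_kernel, stride=2)
        self.stem_pool = nn.MaxPool2d(3, 2, 1) if stem_pool else nn.Identity()
        stages = []
        cin = stem_width
        for i, (n_blocks, width) in enumerate(zip(blocks_per_stage, widths)):
            layers = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and i > 0) else 1
                layers.append(BasicBlock(cin, width, stride))
                cin = width
            stages.append(nn.Sequential(*layers))
        self.stages = stages
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(cin, num_classes)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_pool(self.stem(x).relu())
        for stage in self.stages:
            x = stage(x)
        return self.fc(self.pool(x))

    def predict_proba(self, x: Tensor) -> Tensor:
        return self.forward(x).softmax(axis=1)


def resnet34(num_classes: int) -> ResNet:
    if num_classes < 2:
        raise ValueError("num_classes must be at least 2")
    return ResNet([3, 4, 6, 3], [64, 128, 256, 512], num_classes)


def small_resnet(num_classes: int, width: int = 16) -> ResNet:
    """Three-stage reduced classifier (~100x fewer parameters than the
    34-layer model) for CPU-scale training runs."""
    return ResNet([1, 1, 1], [width, width * 2, width * 4], num_classes,
                  stem_width=width, stem_kernel=3, stem_pool=True)
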