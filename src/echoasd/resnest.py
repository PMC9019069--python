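"""ResNeSt split-attention classifier, used as the distillation teacher.

The 200-layer configuration (deep 3x3 stem of width 64, stages [3, 24, 36, 3]
of bottleneck blocks with radix-2 split attention, average-pool downsampling)
matches the published topology; with the canonical 1000-way head it carries
about 70.2 M parameters.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor


class SplitAttentionConv(nn.Module):
    """Radix-wise grouped convolution with learned soft assignment.

    The 3x3 convolution produces ``radix`` groups of ``channels`` maps; a
    squeeze (global pool + two 1x1 convs) yields per-radix attention weights,
    softmax-normalised across the radix dimension, that recombine the groups.
    """

    def __init__(self, in_channels: int, channels: int, kernel_size: int = 3,
                 padding: int = 1, groups: int = 1, radix: int = 2,
                 reduction_factor: int = 4):
        super().__init__()
        self.radix = radix
        self.channels = channels
        self.cardinality = groups
        inter = max(in_channels * radix // reduction_factor, 32)
        self.conv = nn.Conv2d(in_channels, channels * radix, kernel_size,
                              padding=padding, groups=groups * radix, bias=False)
        self.bn0 = nn.BatchNorm2d(channels * radix)
        self.fc1 = nn.Conv2d(channels, inter, 1, groups=groups)
        self.bn1 = nn.BatchNorm2d(inter)
        self.fc2 = nn.Conv2d(inter, channels * radix, 1, groups=groups)

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        out = self.bn0(self.conv(x)).relu()
        h, w = out.shape[2], out.shape[3]
        splits = out.reshape(n, self.radix, self.channels, h, w)
        gap = splits.sum(axis=1).mean(axis=(2, 3)).reshape(n, self.channels, 1, 1)
        att = self.fc2(self.bn1(self.fc1(gap)).relu())
        # softmax over the radix axis, per (cardinal group, channel)
        att = att.reshape(n, self.cardinality, self.radix,
                          self.channels // self.cardinality, 1, 1)
        att = att.softmax(axis=2).reshape(n, self.radix, self.channels, 1, 1)
        return (splits * att).sum(axis=1)


class SplitAttentionBottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_channels: int, planes: int, stride: int = 1, radix: int = 2):
        super().__init__()
        group_width = planes
        self.conv1 = nn.Conv2d(in_channels, group_width, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(group_width)
        self.conv2 = SplitAttentionConv(group_width, group_width, radix=radix)
        # stride is taken by an average pool after the split-attention conv
        self.avd = nn.AvgPool2d(3, stride, 1) if stride > 1 else None
        self.conv3 = nn.Conv2d(group_width, planes * self.expansion, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(planes * self.expansion)
        if stride != 1 or in_channels != planes * self.expansion:
            pool = nn.AvgPool2d(stride, stride) if stride > 1 else nn.Identity()
            self.downsample = nn.Sequential(
                pool,
                nn.Conv2d(in_channels, planes * self.expansion, 1, bias=False),
                nn.BatchNorm2d(planes * self.expansion),
            )
        else:
            self.downsample = None

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.downsample is None else self.downsample(x)
        out = self.bn1(self.conv1(x)).relu()
        out = self.conv2(out)
        if self.avd is not None:
            out = self.avd(out)
        out = self.bn3(self.conv3(out))
        return (out + identity).relu()


class ResNeSt(nn.Module):
    def __init__(self, blocks_per_stage, num_classes: int, stem_width: int = 64,
                 radix: int = 2):
        super().__init__()
        self.num_classes = num_classes
        self.stem = nn.Sequential(
            nn.Conv2d(3, stem_width, 3, 2, 1, bias=False),
            nn.BatchNorm2d(stem_width), nn.ReLU(),
            nn.Conv2d(stem_width, stem_width, 3, 1, 1, bias=False),
            nn.BatchNorm2d(stem_width), nn.ReLU(),
            nn.Conv2d(stem_width, stem_width * 2, 3, 1, 1, bias=False),
            nn.BatchNorm2d(stem_width * 2), nn.ReLU(),
        )
        self.stem_pool = nn.MaxPool2d(3, 2, 1)
        stages = []
        cin = stem_width * 2
        for i, n_blocks in enumerate(blocks_per_stage):
            planes = 64 * 2**i
            layers = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and i > 0) else 1
                layers.append(SplitAttentionBottleneck(cin, planes, stride, radix))
                cin = planes * SplitAttentionBottleneck.expansion
            stages.append(nn.Sequential(*layers))
        self.stages = stages
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(cin, num_classes)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_pool(self.stem(x))
        for stage in self.stages:
            x = stage(x)
        return self.fc(self.pool(x))

    def predict_proba(self, x: Tensor) -> Tensor:
        return self.forward(x).softmax(axis=1)


def resnest200(num_classes: int = 1000) -> ResNeSt:
    return ResNeSt([3, 24, 36, 3], num_classes)
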