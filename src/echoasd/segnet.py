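"""Atrium segmentation: Dense Dual Attention U-Net and its ablations.

The segmentor is a U-Net style encoder-decoder. Relative to the plain
variant, the dense variants replace the convolution blocks at encoder levels
2-4 with dense blocks of 2, 4 and 8 dense layers (growth rate 32 at full
scale); the attention variants insert a dual-attention block — parallel
position (spatial) and channel self-attention branches fused by addition —
at the encoder bottleneck.  Four variants are exposed for ablation:

    plain_unet, unet_dense, unet_dual_attention, dense_dual_attention

Default classes are {background, LA, RA}; a 5-class mode adds LV/RV
supervision.  Training inputs may carry two extra normalized coordinate
channels (``add_coords``), which desk-scale models need to tell the left
from the right atrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .nn import Tensor, concat
from .metrics import dsc
from .types import LA, RA, AtriaMask, EchoFrame

SEG_VARIANTS = ("plain_unet", "unet_dense", "unet_dual_attention", "dense_dual_attention")

__all__ = ["SegConfig", "SEG_VARIANTS", "DenseBlock", "DualAttention", "UNet",
           "build_segmentor", "train_segmentor", "segment", "evaluate_by_group",
           "add_coord_channels"]


@dataclass
class SegConfig:
    variant: str = "dense_dual_attention"
    num_classes: int = 3
    base_width: int = 64
    depth: int = 5                  # encoder levels; bottleneck at the last
    growth_rate: int = 32
    dense_layers: tuple = (2, 4, 8)  # at encoder levels 2..4
    add_coords: bool = False
    epochs: int = 20
    learning_rate: float = 2e-3
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.variant not in SEG_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {SEG_VARIANTS}")
        if self.num_classes not in (3, 5):
            raise ValueError("num_classes must be 3 (LA/RA) or 5 (adding LV/RV)")

    @property
    def in_channels(self) -> int:
        return 5 if self.add_coords else 3


def _double_conv(cin: int, cout: int) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, padding=1, bias=False), nn.BatchNorm2d(cout), nn.ReLU(),
        nn.Conv2d(cout, cout, 3, padding=1, bias=False), nn.BatchNorm2d(cout), nn.ReLU(),
    )


class DenseLayer(nn.Module):
    def __init__(self, cin: int, growth: int):
        super().__init__()
        self.bn = nn.BatchNorm2d(cin)
        self.conv = nn.Conv2d(cin, growth, 3, padding=1, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(self.bn(x).relu())


class DenseBlock(nn.Module):
    """Each layer sees the concatenation of the block input and all previous
    layers' outputs; ``growth`` channels are appended per layer."""

    def __init__(self, cin: int, num_layers: int, growth: int):
        super().__init__()
        self.num_layers = num_layers
        self.growth = growth
        self.layers = [DenseLayer(cin + i * growth, growth) for i in range(num_layers)]
        self.out_channels = cin + num_layers * growth

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = concat([x, layer(x)], axis=1)
        return x


class DualAttention(nn.Module):
    """Parallel position and channel self-attention, fused by addition.

    With input x of shape (N, C, H, W), flattened over P = H*W positions:

    * position branch: queries/keys are 1x1-conv projections to C//8
      channels, values a 1x1-conv projection to C channels; the attention
      weight of position i for position j is softmax_i(q_j . k_i), the output
      at j is the attention-weighted sum of values, and the branch returns
      ``gamma * out + x`` with gamma learned from 0.
    * channel branch: the affinity of channels u, v is the inner product of
      their feature maps; weights are softmax over v; the output at u is the
      weighted sum of the original channel maps, returned as
      ``gamma_c * out + x``.

    ``forward`` is the elementwise sum of the two branch outputs.
    """

    def __init__(self, channels: int):
        super().__init__()
        reduced = max(1, channels // 8)
        self.query = nn.Conv2d(channels, reduced, 1)
        self.key = nn.Conv2d(channels, reduced, 1)
        self.value = nn.Conv2d(channels, channels, 1)
        self.gamma = nn.Parameter(np.zeros(1))
        self.gamma_c = nn.Parameter(np.zeros(1))

    def position_attention(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        p = h * w
        q = self.query(x).reshape(n, -1, p).transpose(0, 2, 1)   # (N, P, C')
        k = self.key(x).reshape(n, -1, p)                        # (N, C', P)
        v = self.value(x).reshape(n, c, p)                       # (N, C, P)
        attn = (q @ k).softmax(axis=2)                           # (N, P, P) rows=j
        out = (v @ attn.transpose(0, 2, 1)).reshape(n, c, h, w)
        return self.gamma.reshape(1, 1, 1, 1) * out + x

    def channel_attention(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        p = h * w
        flat = x.reshape(n, c, p)
        affinity = flat @ flat.transpose(0, 2, 1)                # (N, C, C)
        attn = affinity.softmax(axis=2)
        out = (attn @ flat).reshape(n, c, h, w)
        return self.gamma_c.reshape(1, 1, 1, 1) * out + x

    def forward(self, x: Tensor) -> Tensor:
        return self.position_attention(x) + self.channel_attention(x)


class UNet(nn.Module):
    """Encoder-decoder segmentor; see the module docstring for the variants."""

    def __init__(self, config: SegConfig):
        super().__init__()
        self.config = config
        w = [config.base_width * 2**i for i in range(config.depth)]
        use_dense = config.variant in ("unet_dense", "dense_dual_attention")
        use_attention = config.variant in ("unet_dual_attention", "dense_dual_attention")

        self.encoder = []
        self.dense_blocks: list[DenseBlock | None] = []
        cin = config.in_channels
        for level in range(config.depth):
            entry = _double_conv(cin, w[level])
            dense = None
            # dense blocks sit at encoder levels 2-4 (1-based)
            if use_dense and 1 <= level <= 3 and level - 1 < len(config.dense_layers):
                n_layers = config.dense_layers[level - 1]
                dense = DenseBlock(w[level], n_layers, config.growth_rate)
                block = nn.Sequential(
                    entry, dense,
                    nn.Conv2d(dense.out_channels, w[level], 1, bias=False),
                    nn.BatchNorm2d(w[level]), nn.ReLU(),
                )
            else:
                block = entry
            self.encoder.append(block)
            self.dense_blocks.append(dense)
            cin = w[level]
        self.pool = nn.MaxPool2d(2)
        self.attention = DualAttention(w[-1]) if use_attention else None

        self.up_convs = []
        self.dec_blocks = []
        for level in range(config.depth - 2, -1, -1):
            self.up_convs.append(nn.Conv2d(w[level + 1], w[level], 1, bias=False))
            self.dec_blocks.append(_double_conv(2 * w[level], w[level]))
        self.head = nn.Conv2d(w[0], config.num_classes, 1)

    @property
    def dense_layer_counts(self) -> tuple:
        """Dense-layer counts at encoder levels 2-4 of the built model."""
        return tuple(b.num_layers for b in self.dense_blocks if b is not None)

    @property
    def num_classes(self) -> int:
        return self.config.num_classes

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for level, block in enumerate(self.encoder):
            if level > 0:
                x = self.pool(x)
            x = block(x)
            skips.append(x)
        if self.attention is not None:
            x = self.attention(x)
        for up, dec, skip in zip(self.up_convs, self.dec_blocks, skips[-2::-1]):
            x = up(nn.functional.upsample_nearest2x(x))
            x = dec(concat([skip, x], axis=1))
        return self.head(x)


def build_segmentor(variant: str = "dense_dual_attention", num_classes: int = 3,
                    config: SegConfig | None = None) -> UNet:
    """Build a segmentor variant. A ``config`` overrides width/depth defaults
    (used for desk-scale training); variant/num_classes arguments win."""
    if config is None:
        config = SegConfig(variant=variant, num_classes=num_classes)
    else:
        config = SegConfig(**{**config.__dict__, "variant": variant,
                              "num_classes": num_classes})
    return UNet(config)


def add_coord_channels(x: np.ndarray) -> np.ndarray:
    """Append normalized x/y coordinate channels to a (N, 3, H, W) batch."""
    n, _, h, w = x.shape
    ys = np.linspace(-1, 1, h, dtype=np.float32)[None, None, :, None]
    xs = np.linspace(-1, 1, w, dtype=np.float32)[None, None, None, :]
    coords = np.concatenate([
        np.broadcast_to(xs, (n, 1, h, w)),
        np.broadcast_to(ys, (n, 1, h, w)),
    ], axis=1)
    return np.concatenate([x, coords.astype(np.float32)], axis=1)


def _prepare_batch(x: np.ndarray, config: SegConfig) -> np.ndarray:
    return add_coord_channels(x) if config.add_coords else x


def train_segmentor(model: UNet, images: np.ndarray, labels: np.ndarray,
                    config: SegConfig | None = None) -> dict:
    """Train on (N, 3, H, W) float32 images and (N, H, W) integer label maps.

    Loss is cross-entropy plus per-class soft Dice. Deterministic for a
    fixed config seed and pre-seeded model build.
    """
    config = config or model.config
    if len(images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = {"loss": []}
    for _ in range(config.epochs):
        model.train()
        order = rng.permutation(len(images))
        total = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = Tensor(_prepare_batch(images[idx], config))
            yb = labels[idx]
            logits = model(xb)
            loss = nn.cross_entropy(logits, yb) + nn.soft_dice_loss(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        history["loss"].append(total / len(images))
    return history


def segment(model: UNet, frame: EchoFrame | np.ndarray, hw: int | None = None) -> AtriaMask:
    """Per-pixel argmax labels for one frame; deterministic in eval mode.

    The frame is resized to ``hw`` for the network and the label map is
    resized back to the frame grid with nearest-neighbour interpolation.
    """
    image = frame.image if isinstance(frame, EchoFrame) else np.asarray(frame)
    h0, w0 = image.shape[:2]
    hw = hw or h0
    small = image if (h0, w0) == (hw, hw) else resize(
        image, (hw, hw), preserve_range=True, anti_aliasing=True)
    x = (small.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]
    model.eval()
    logits = model(Tensor(_prepare_batch(x, model.config))).data[0]
    labels = logits.argmax(axis=0).astype(np.uint8)
    if (h0, w0) != (hw, hw):
        labels = resize(labels, (h0, w0), order=0, preserve_range=True,
                        anti_aliasing=False).astype(np.uint8)
    return AtriaMask(labels)


def evaluate_by_group(pairs: list[tuple[AtriaMask, AtriaMask, str]]) -> dict:
    """Mean LA/RA Dice per content group and in total.

    ``pairs`` holds (predicted, ground-truth, group-tag) triples; groups tag
    which chambers the frame contains (e.g. "A2C" for atria only,
    "A2C-V2C" for all four). Only LA and RA Dice are scored. Groups without
    pairs are omitted.
    """
    table: dict[str, dict] = {}
    buckets: dict[str, list] = {}
    for pred, gt, group in pairs:
        buckets.setdefault(group, []).append((pred, gt))
    all_la, all_ra = [], []
    for group in sorted(buckets):
        la_scores, ra_scores = [], []
        for pred, gt in buckets[group]:
            d_la = dsc(pred.region(LA), gt.region(LA))
            d_ra = dsc(pred.region(RA), gt.region(RA))
            if d_la is not None:
                la_scores.append(d_la)
            if d_ra is not None:
                ra_scores.append(d_ra)
        all_la += la_scores
        all_ra += ra_scores
        row = {
            "n": len(buckets[group]),
            "LA": float(np.mean(la_scores)) if la_scores else None,
            "RA": float(np.mean(ra_scores)) if ra_scores else None,
        }
        both = [v for v in (row["LA"], row["RA"]) if v is not None]
        row["mean"] = float(np.mean(both)) if both else None
        table[group] = row
    total = {
        "n": len(pairs),
        "LA": float(np.mean(all_la)) if all_la else None,
        "RA": float(np.mean(all_ra)) if all_ra else None,
    }
    both = [v for v in (total["LA"], total["RA"]) if v is not None]
    total["mean"] = float(np.mean(both)) if both else None
    table["total"] = total
    return table
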