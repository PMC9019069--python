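"""Autograd and layer correctness: numeric gradient checks and accounting."""

import numpy as np
import pytest

from echoasd import nn
from echoasd.nn import Tensor
from echoasd.nn import functional as F

rng = np.random.default_rng(42)


def numeric_grad(fn, x, eps=1e-2):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = fn()
        x[i] = old - eps
        fm = fn()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_matches(analytic, numeric, rtol=2e-3):
    scale = np.abs(numeric).max() + 1e-8
    assert np.abs(analytic - numeric).max() / scale < rtol


@pytest.mark.parametrize("groups,stride,padding", [(1, 1, 1), (2, 2, 1), (1, 2, 0)])
def test_conv2d_gradients(groups, stride, padding):
    x = Tensor(rng.normal(size=(2, 4, 6, 6)), requires_grad=True)
    w = Tensor(rng.normal(size=(6, 4 // groups, 3, 3)), requires_grad=True)
    b = Tensor(rng.normal(size=6), requires_grad=True)

    def loss():
        out = F.conv2d(Tensor(x.data), Tensor(w.data), Tensor(b.data),
                       stride=stride, padding=padding, groups=groups)
        return float((out.data.astype(np.float64) ** 2).sum() / 2)

    out = F.conv2d(x, w, b, stride=stride, padding=padding, groups=groups)
    ((out * out).sum() * 0.5).backward()
    for t in (x, w, b):
        assert_grad_matches(t.grad, numeric_grad(loss, t.data))


@pytest.mark.parametrize("op,kwargs,rtol", [
    # max-pool is only piecewise smooth; central differences near an argmax
    # switch are inexact, hence the looser tolerance
    (F.max_pool2d, {"kernel": 3, "stride": 2, "padding": 1}, 5e-2),
    (F.avg_pool2d, {"kernel": 2, "stride": 2, "padding": 0}, 2e-3),
    (F.upsample_nearest2x, {}, 2e-3),
])
def test_spatial_op_gradients(op, kwargs, rtol):
    x = Tensor(rng.normal(size=(2, 3, 6, 6)), requires_grad=True)

    def loss():
        return float((op(Tensor(x.data), **kwargs).data.astype(np.float64) ** 2).sum() / 2)

    ((op(x, **kwargs) ** 2).sum() * 0.5).backward()
    assert_grad_matches(x.grad, numeric_grad(loss, x.data), rtol)


def test_softmax_rows_normalized_and_grad():
    x = Tensor(rng.normal(size=(5, 7)) * 3, requires_grad=True)
    s = x.softmax(axis=1)
    assert np.abs(s.data.sum(axis=1) - 1).max() < 1e-5

    w = rng.normal(size=(5, 7)).astype(np.float32)

    def loss():
        return float((Tensor(x.data).softmax(axis=1).data * w).sum())

    (x.softmax(axis=1) * Tensor(w)).sum().backward()
    assert_grad_matches(x.grad, numeric_grad(loss, x.data))


def test_cross_entropy_matches_manual():
    logits = Tensor(np.array([[2.0, 0.0, -1.0], [0.5, 0.5, 0.5]]), requires_grad=True)
    labels = np.array([0, 2])
    loss = nn.cross_entropy(logits, labels)
    p = np.exp(logits.data) / np.exp(logits.data).sum(axis=1, keepdims=True)
    expected = -(np.log(p[0, 0]) + np.log(p[1, 2])) / 2
    assert abs(loss.item() - expected) < 1e-6


def test_kl_divergence_properties():
    a = Tensor(rng.normal(size=(4, 5)))
    assert abs(nn.kl_divergence(a, a).item()) < 1e-6
    b = Tensor(rng.normal(size=(4, 5)))
    assert nn.kl_divergence(a, b).item() >= 0
    with pytest.raises(ValueError):
        nn.kl_divergence(a, b, temperature=0.0)


def test_batchnorm_normalizes_in_training_mode():
    nn.manual_seed(0)
    bn = nn.BatchNorm2d(4)
    x = Tensor(rng.normal(loc=3.0, scale=2.0, size=(8, 4, 5, 5)))
    out = bn(x).data
    assert np.abs(out.mean(axis=(0, 2, 3))).max() < 1e-4
    assert np.abs(out.std(axis=(0, 2, 3)) - 1).max() < 1e-2


def test_parameters_deduplicated_across_aliases():
    nn.manual_seed(0)

    class Shared(nn.Module):
        def __init__(self):
            super().__init__()
            self.conv = nn.Conv2d(3, 4, 3)
            self.alias = self.conv  # same module reachable twice

        def forward(self, x):
            return self.conv(x)

    m = Shared()
    assert len(m.parameters()) == 2  # weight and bias, once each


def test_training_reduces_loss_on_toy_problem():
    nn.manual_seed(7)
    net = nn.Sequential(nn.Linear(4, 16), nn.ReLU(), nn.Linear(16, 3))
    x = rng.normal(size=(64, 4)).astype(np.float32)
    y = (x[:, 0] > 0).astype(int) + (x[:, 1] > 0).astype(int)
    opt = nn.Adam(net.parameters(), lr=1e-2)
    losses = []
    for _ in range(60):
        loss = nn.cross_entropy(net(Tensor(x)), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    assert losses[-1] < 0.5 * losses[0]


def test_state_arrays_roundtrip(tmp_path):
    nn.manual_seed(1)
    a = nn.Sequential(nn.Conv2d(3, 4, 3, padding=1), nn.BatchNorm2d(4), nn.Linear(4, 2))
    a.save(tmp_path / "ckpt.pkl", {"note": "test"})
    nn.manual_seed(2)
    b = nn.Sequential(nn.Conv2d(3, 4, 3, padding=1), nn.BatchNorm2d(4), nn.Linear(4, 2))
    config, arrays = nn.Module.load_checkpoint(tmp_path / "ckpt.pkl")
    b.load_state_arrays(arrays)
    assert config == {"note": "test"}
    for pa, pb in zip(a.parameters(), b.parameters()):
        assert np.array_equal(pa.data, pb.data)


def test_count_parameters_single_affine():
    nn.manual_seed(0)
    assert nn.count_parameters(nn.Linear(10, 5)) == 55  # 10*5 + 5


def test_count_macs_single_conv():
    nn.manual_seed(0)
    # 1x1 convolution, 3 -> 8 channels, on a 4x4 input: 3*8*16 products
    conv = nn.Conv2d(3, 8, 1)
    assert nn.count_macs(conv, 4) == 3 * 8 * 16


def test_count_macs_rejects_unknown_parametric_layer():
    class Odd(nn.Module):
        def __init__(self):
            super().__init__()
            self.w = nn.Parameter(np.ones(3))

        def forward(self, x):
            return x * self.w.reshape(1, 3, 1, 1)

    with pytest.raises(TypeError, match="Odd"):
        nn.count_macs(Odd(), 4)
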