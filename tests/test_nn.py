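"""The numpy NN engine: every primitive's backward vs numerical differentiation."""

import numpy as np
import pytest

from ghdcnet import nn
from ghdcnet.nn import Tensor, concat
from ghdcnet.nn import functional as F


def numerical_grad(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(make_out, tensors, tol=1e-4):
    """Backprop a quadratic readout and compare each input's gradient."""
    out = make_out()
    (out * out).sum().backward()
    for t in tensors:
        analytic = t.grad.copy()
        t.zero_grad()
        numeric = numerical_grad(lambda: float((make_out().data ** 2).sum()), t.data)
        scale = max(np.abs(numeric).max(), 1e-8)
        np.testing.assert_allclose(analytic, numeric, atol=tol * scale)


@pytest.fixture
def g():
    return np.random.default_rng(7)


class TestConv2d:
    @pytest.mark.parametrize("stride,padding,dilation", [(1, 0, 1), (1, 2, 2), (2, 1, 1), (2, 3, 3)])
    def test_gradients(self, g, stride, padding, dilation):
        x = Tensor(g.standard_normal((2, 3, 9, 9)), requires_grad=True)
        w = Tensor(g.standard_normal((4, 3, 3, 3)), requires_grad=True)
        b = Tensor(g.standard_normal(4), requires_grad=True)
        assert_grads_match(lambda: F.conv2d(x, w, b, stride, padding, dilation), [x, w, b])

    def test_dilated_conv_matches_inserted_zeros(self, g):
        # dilation-2 3x3 kernel == 5x5 kernel with zeros at the even taps
        x = Tensor(g.standard_normal((1, 1, 8, 8)))
        w3 = g.standard_normal((1, 1, 3, 3))
        w5 = np.zeros((1, 1, 5, 5))
        w5[:, :, ::2, ::2] = w3
        a = F.conv2d(x, Tensor(w3), dilation=2).data
        b = F.conv2d(x, Tensor(w5), dilation=1).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_channel_mismatch_rejected(self, g):
        with pytest.raises(ValueError):
            F.conv2d(Tensor(np.zeros((1, 2, 4, 4))), Tensor(np.zeros((1, 3, 3, 3))))


class TestConvTranspose2d:
    def test_gradients(self, g):
        x = Tensor(g.standard_normal((2, 3, 5, 5)), requires_grad=True)
        w = Tensor(g.standard_normal((3, 4, 3, 3)), requires_grad=True)
        b = Tensor(g.standard_normal(4), requires_grad=True)
        assert_grads_match(
            lambda: F.conv_transpose2d(x, w, b, stride=2, padding=1, output_padding=1),
            [x, w, b],
        )

    def test_doubles_spatial_size(self, g):
        x = Tensor(g.standard_normal((1, 2, 7, 5)))
        w = Tensor(g.standard_normal((2, 2, 3, 3)))
        out = F.conv_transpose2d(x, w, stride=2, padding=1, output_padding=1)
        assert out.shape == (1, 2, 14, 10)

    def test_adjoint_of_conv(self, g):
        # <conv(x), y> == <x, conv_transpose(y)> for matching geometry
        x = g.standard_normal((1, 2, 8, 8))
        y = g.standard_normal((1, 3, 4, 4))
        w = g.standard_normal((3, 2, 3, 3))
        lhs = (F.conv2d(Tensor(x), Tensor(w), stride=2, padding=1).data * y).sum()
        rhs = (
            F.conv_transpose2d(Tensor(y), Tensor(w), stride=2, padding=1,
                               output_padding=1).data * x
        ).sum()
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestPooling:
    def test_maxpool_gradients(self, g):
        # distinct values avoid argmax ties, keeping the subgradient unique
        vals = g.permutation(2 * 2 * 8 * 8).astype(float).reshape(2, 2, 8, 8)
        x = Tensor(vals, requires_grad=True)
        assert_grads_match(lambda: F.max_pool2d(x, 7, 2, 3), [x])

    def test_maxpool_values(self):
        x = Tensor(np.arange(16.0).reshape(1, 1, 4, 4))
        out = F.max_pool2d(x, 2, 2)
        np.testing.assert_array_equal(out.data[0, 0], [[5, 7], [13, 15]])

    def test_avgpool_gradients(self, g):
        x = Tensor(g.standard_normal((2, 3, 6, 6)), requires_grad=True)
        assert_grads_match(lambda: F.avg_pool2d(x), [x])

    def test_avgpool_rejects_odd(self):
        with pytest.raises(ValueError):
            F.avg_pool2d(Tensor(np.zeros((1, 1, 5, 6))))


class TestUpsample:
    @pytest.mark.parametrize("scale", [2, 4])
    def test_gradients(self, g, scale):
        x = Tensor(g.standard_normal((2, 3, 4, 5)), requires_grad=True)
        assert_grads_match(lambda: F.upsample_bilinear(x, scale), [x])

    def test_constant_field_preserved(self):
        x = Tensor(np.full((1, 1, 3, 3), 2.5))
        out = F.upsample_bilinear(x, 2)
        assert out.shape == (1, 1, 6, 6)
        np.testing.assert_allclose(out.data, 2.5)


class TestBatchNorm:
    def test_gradients_training_and_eval(self, g):
        x = Tensor(g.standard_normal((3, 4, 5, 5)), requires_grad=True)
        gamma = Tensor(g.standard_normal(4) + 1, requires_grad=True)
        beta = Tensor(g.standard_normal(4), requires_grad=True)

        def train_mode():
            return F.batch_norm(x, gamma, beta, np.zeros(4), np.ones(4), training=True)

        rm, rv = np.zeros(4), np.ones(4)

        def eval_mode():
            return F.batch_norm(x, gamma, beta, rm, rv, training=False)

        assert_grads_match(train_mode, [x, gamma, beta], tol=5e-4)
        assert_grads_match(eval_mode, [x, gamma, beta])

    def test_normalizes_batch_statistics(self, g):
        x = Tensor(g.standard_normal((8, 2, 6, 6)) * 3 + 5)
        out = F.batch_norm(x, Tensor(np.ones(2)), Tensor(np.zeros(2)),
                           np.zeros(2), np.ones(2), training=True)
        assert np.abs(out.data.mean(axis=(0, 2, 3))).max() < 1e-6
        assert np.abs(out.data.std(axis=(0, 2, 3)) - 1).max() < 1e-3


class TestLossesAndOps:
    def test_bce_with_logits_gradient(self, g):
        z = Tensor(g.standard_normal((2, 1, 4, 4)), requires_grad=True)
        t = (g.uniform(size=(2, 1, 4, 4)) > 0.5).astype(float)
        F.bce_with_logits(z, t).backward()
        analytic = z.grad.copy()
        numeric = numerical_grad(lambda: float(F.bce_with_logits(z, t).data), z.data)
        np.testing.assert_allclose(analytic, numeric, atol=1e-7)

    def test_bce_with_logits_matches_probability_form(self, g):
        from ghdcnet.metrics import bce_loss

        z = g.standard_normal((5, 5))
        t = (g.uniform(size=(5, 5)) > 0.5).astype(float)
        p = 1 / (1 + np.exp(-z))
        assert float(F.bce_with_logits(Tensor(z), t).data) == pytest.approx(
            bce_loss(p, t), rel=1e-6
        )

    def test_composite_elementwise_gradients(self, g):
        x = Tensor(g.standard_normal((4, 4)), requires_grad=True)
        assert_grads_match(
            lambda: x.sigmoid() * 2 + x.relu() / 3 - (x * x).mean() + (x.exp() + 1).log(),
            [x],
        )

    def test_concat_splits_gradient(self, g):
        a = Tensor(g.standard_normal((2, 2, 3, 3)), requires_grad=True)
        b = Tensor(g.standard_normal((2, 5, 3, 3)), requires_grad=True)
        assert_grads_match(lambda: concat([a, b], axis=1), [a, b])

    def test_backward_requires_scalar(self):
        x = Tensor(np.zeros((2, 2)), requires_grad=True)
        with pytest.raises(ValueError):
            (x * 2).backward()


class TestModulesAndOptim:
    def test_state_dict_round_trip(self, g):
        net = nn.Sequential(
            nn.Conv2d(2, 3, 3, rng=g, padding=1), nn.BatchNorm2d(3), nn.ReLU()
        )
        x = Tensor(g.standard_normal((2, 2, 6, 6)).astype(np.float32))
        net(x)  # populate running stats
        state = net.state_dict()
        net2 = nn.Sequential(
            nn.Conv2d(2, 3, 3, rng=np.random.default_rng(99), padding=1),
            nn.BatchNorm2d(3),
            nn.ReLU(),
        )
        net2.load_state_dict(state)
        net.eval(), net2.eval()
        np.testing.assert_array_equal(net(x).data, net2(x).data)

    def test_load_state_dict_rejects_mismatch(self, g):
        net = nn.Sequential(nn.Conv2d(1, 1, 3, rng=g))
        with pytest.raises(KeyError):
            net.load_state_dict({"bogus": np.zeros(1)})

    def test_adam_minimizes_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(200):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_adam_weight_decay_shrinks_unused_parameter(self):
        p = nn.Parameter(np.array([1.0]))
        opt = nn.Adam([p], lr=0.01, weight_decay=1.0)
        for _ in range(50):
            loss = (p * 0.0).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert abs(float(p.data[0])) < 1.0
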