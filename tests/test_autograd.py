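"""Numeric gradient checks for the autograd core (run in float64)."""

import numpy as np
import pytest

from mfafuse.nn import Tensor, batch_norm2d, concat, conv2d, conv_transpose2x, softmax


def numeric_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def check(fn_tensor, fn_value, x, atol=1e-6):
    t = Tensor(x.copy(), requires_grad=True)
    out = fn_tensor(t)
    out.backward()
    np.testing.assert_allclose(t.grad, numeric_grad(fn_value, x.copy()), atol=atol)


class TestElementwise:
    def test_mul_add(self, rng):
        x = rng.normal(size=(3, 4))
        check(lambda t: ((t * 2.0 + 1.0) * t).sum(), lambda a: ((a * 2 + 1) * a).sum(), x)

    def test_div(self, rng):
        x = rng.normal(size=(5,)) + 3.0
        check(lambda t: (t / (t + 1.0)).sum(), lambda a: (a / (a + 1)).sum(), x)

    def test_sigmoid_gelu_exp_log_abs(self, rng):
        x = rng.normal(size=(4, 4)) + 2.5  # keep log positive, abs away from 0
        check(lambda t: t.sigmoid().sum(), lambda a: (1 / (1 + np.exp(-a))).sum(), x)
        check(lambda t: t.log().sum(), lambda a: np.log(a).sum(), x)
        check(lambda t: t.exp().mean(), lambda a: np.exp(a).mean(), x)
        check(lambda t: t.abs().sum(), lambda a: np.abs(a).sum(), x)
        from scipy.special import erf

        check(
            lambda t: t.gelu().sum(),
            lambda a: (a * 0.5 * (1 + erf(a / np.sqrt(2)))).sum(),
            x,
        )

    def test_clip(self, rng):
        x = rng.normal(size=(6,)) * 2
        check(lambda t: t.clip(-1.0, 1.0).sum(), lambda a: np.clip(a, -1, 1).sum(), x)


class TestShapeOps:
    def test_getitem_strided(self, rng):
        x = rng.normal(size=(6, 3))
        check(lambda t: (t[1::2] * t[0::2]).sum(), lambda a: (a[1::2] * a[0::2]).sum(), x)

    def test_reshape_and_sum_axis(self, rng):
        x = rng.normal(size=(2, 3, 4))
        def tensor_fn(t):
            s = t.reshape(6, 4).sum(axis=1)
            return (s * s).sum()

        check(tensor_fn, lambda a: (a.reshape(6, 4).sum(axis=1) ** 2).sum(), x)

    def test_concat(self, rng):
        x = rng.normal(size=(4, 2))

        def tensor_fn(t):
            return (concat([t, t * 2.0], axis=1) * 1.5).sum()

        check(tensor_fn, lambda a: (np.concatenate([a, a * 2], axis=1) * 1.5).sum(), x)

    def test_mean_broadcast(self, rng):
        x = rng.normal(size=(3, 4))
        check(
            lambda t: ((t - t.mean(axis=1, keepdims=True)) * t).sum(),
            lambda a: ((a - a.mean(axis=1, keepdims=True)) * a).sum(),
            x,
        )


class TestSoftmax:
    def test_softmax_grad(self, rng):
        x = rng.normal(size=(3, 5))
        coef = rng.normal(size=(3, 5))

        def tensor_fn(t):
            return (softmax(t, axis=1) * Tensor(coef)).sum()

        def value_fn(a):
            e = np.exp(a - a.max(axis=1, keepdims=True))
            s = e / e.sum(axis=1, keepdims=True)
            return (s * coef).sum()

        check(tensor_fn, value_fn, x)


class TestConv:
    def test_conv2d_grads(self, rng):
        x = rng.normal(size=(2, 3, 5, 5))
        w = rng.normal(size=(4, 3, 3, 3))
        b = rng.normal(size=(4,))
        coef = rng.normal(size=(2, 4, 5, 5))

        def forward(xa, wa, ba):
            xt = Tensor(xa, requires_grad=True)
            wt = Tensor(wa, requires_grad=True)
            bt = Tensor(ba, requires_grad=True)
            out = (conv2d(xt, wt, bt, stride=1, pad=1) * Tensor(coef)).sum()
            return xt, wt, bt, out

        xt, wt, bt, out = forward(x, w, b)
        out.backward()
        for var, grad, idx in ((x, xt.grad, 0), (w, wt.grad, 1), (b, bt.grad, 2)):
            def value_fn(a, idx=idx):
                args = [x.copy(), w.copy(), b.copy()]
                args[idx] = a
                _, _, _, o = forward(*args)
                return float(o.data)

            np.testing.assert_allclose(grad, numeric_grad(value_fn, var.copy()), atol=1e-5)

    def test_conv2d_stride2(self, rng):
        x = rng.normal(size=(1, 2, 6, 6))
        w = rng.normal(size=(3, 2, 3, 3))
        xt = Tensor(x.copy(), requires_grad=True)
        wt = Tensor(w.copy(), requires_grad=True)
        out = conv2d(xt, wt, None, stride=2, pad=1)
        assert out.shape == (1, 3, 3, 3)
        out.sum().backward()

        def value_fn(a):
            return float(conv2d(Tensor(a), Tensor(w), None, stride=2, pad=1).sum().data)

        np.testing.assert_allclose(xt.grad, numeric_grad(value_fn, x.copy()), atol=1e-5)

    def test_conv_transpose2x(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        w = rng.normal(size=(3, 2, 2, 2))
        xt = Tensor(x.copy(), requires_grad=True)
        wt = Tensor(w.copy(), requires_grad=True)
        out = conv_transpose2x(xt, wt)
        assert out.shape == (2, 2, 8, 8)
        (out * out).sum().backward()

        def value_fn(a):
            o = conv_transpose2x(Tensor(a), Tensor(w))
            return float((o * o).sum().data)

        np.testing.assert_allclose(xt.grad, numeric_grad(value_fn, x.copy()), atol=1e-4)

        def value_fn_w(a):
            o = conv_transpose2x(Tensor(x), Tensor(a))
            return float((o * o).sum().data)

        np.testing.assert_allclose(wt.grad, numeric_grad(value_fn_w, w.copy()), atol=1e-4)


class TestBatchNorm:
    def test_train_mode_grads(self, rng):
        x = rng.normal(size=(3, 2, 4, 4))
        gamma = rng.normal(size=(2,)) + 1.0
        beta = rng.normal(size=(2,))
        coef = rng.normal(size=(3, 2, 4, 4))

        def forward(xa, ga, ba):
            xt = Tensor(xa, requires_grad=True)
            gt = Tensor(ga, requires_grad=True)
            bt = Tensor(ba, requires_grad=True)
            out = batch_norm2d(
                xt, gt, bt, np.zeros(2), np.ones(2), training=True
            )
            return xt, gt, bt, (out * Tensor(coef)).sum()

        xt, gt, bt, out = forward(x, gamma, beta)
        out.backward()
        for var, grad, idx in ((x, xt.grad, 0), (gamma, gt.grad, 1), (beta, bt.grad, 2)):
            def value_fn(a, idx=idx):
                args = [x.copy(), gamma.copy(), beta.copy()]
                args[idx] = a
                return float(forward(*args)[3].data)

            np.testing.assert_allclose(grad, numeric_grad(value_fn, var.copy()), atol=1e-4)

    def test_eval_mode_uses_running_stats(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        rm, rv = rng.normal(size=3), rng.random(3) + 0.5
        out = batch_norm2d(
            Tensor(x), Tensor(np.ones(3)), Tensor(np.zeros(3)), rm.copy(), rv.copy(),
            training=False,
        )
        expected = (x - rm[None, :, None, None]) / np.sqrt(rv + 1e-5)[None, :, None, None]
        np.testing.assert_allclose(out.data, expected, atol=1e-12)
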