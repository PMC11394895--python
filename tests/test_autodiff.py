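"""Gradient checks for every autodiff primitive the layers rely on.

Each test builds a scalar loss through the op under test and compares
the analytic gradient against central finite differences.
"""

import numpy as np
import pytest

from peppersort import autodiff as ad
from peppersort.autodiff import Tensor

from conftest import numgrad


def _check_grad(build_loss, x0, tol=1e-6):
    t = Tensor(x0.copy(), requires_grad=True)
    loss = build_loss(t)
    loss.backward()
    num = numgrad(lambda a: build_loss(Tensor(a)).item(), x0.copy())
    np.testing.assert_allclose(t.grad, num, rtol=tol, atol=tol)


@pytest.mark.parametrize("op", [
    lambda t: (t * t + 2.0 * t).sum(),
    lambda t: (t.exp() + (t * t + 1.0).log()).sum(),
    lambda t: ((t * t + 0.5).sqrt() * t.sin() + t.cos()).sum(),
    lambda t: (t.sigmoid() * t.erf()).sum(),
    lambda t: t.relu().sum() + t.clip(-0.5, 0.5).sum(),
    lambda t: (t.mean(axis=1, keepdims=True) * t).sum(),
    lambda t: t.reshape(-1).sum() + t.transpose(1, 0).sum(),
    lambda t: t[1:3, ::2].sum() * 2.0,
])
def test_elementwise_and_shape_ops(rng, op):
    x0 = rng.normal(size=(4, 6))
    _check_grad(op, x0, tol=1e-5)


def test_matmul_and_broadcast_grad(rng):
    w = rng.normal(size=(6, 3))
    b = rng.normal(size=(3,))
    _check_grad(lambda t: ((t @ Tensor(w) + Tensor(b)) ** 2.0).sum(),
                rng.normal(size=(5, 6)))


def test_concat_grad(rng):
    x0 = rng.normal(size=(2, 3))

    def loss(t):
        c = ad.concat([t, t * 2.0], axis=1)
        return (c * c).sum()

    _check_grad(loss, x0)


@pytest.mark.parametrize("groups,stride,kernel", [
    (1, 1, (3, 3)),
    (1, 2, (3, 3)),
    (4, 1, (1, 5)),      # depthwise strip
    (2, 1, (3, 1)),
])
def test_conv2d_grads(rng, groups, stride, kernel):
    cin, cout = 4, 4
    x0 = rng.normal(size=(2, cin, 6, 6))
    w0 = rng.normal(size=(cout, cin // groups, *kernel))
    b0 = rng.normal(size=(cout,))

    def loss_x(a):
        return (ad.conv2d(Tensor(a), Tensor(w0), Tensor(b0), stride=stride,
                          padding=(kernel[0] // 2, kernel[1] // 2),
                          groups=groups) ** 2.0).sum().item()

    t, w, b = Tensor(x0, True), Tensor(w0, True), Tensor(b0, True)
    out = (ad.conv2d(t, w, b, stride=stride,
                     padding=(kernel[0] // 2, kernel[1] // 2),
                     groups=groups) ** 2.0).sum()
    out.backward()
    np.testing.assert_allclose(t.grad, numgrad(loss_x, x0.copy()),
                               rtol=1e-5, atol=1e-6)

    def loss_w(a):
        return (ad.conv2d(Tensor(x0), Tensor(a), Tensor(b0), stride=stride,
                          padding=(kernel[0] // 2, kernel[1] // 2),
                          groups=groups) ** 2.0).sum().item()

    np.testing.assert_allclose(w.grad, numgrad(loss_w, w0.copy()),
                               rtol=1e-5, atol=1e-6)

    def loss_b(a):
        return (ad.conv2d(Tensor(x0), Tensor(w0), Tensor(a), stride=stride,
                          padding=(kernel[0] // 2, kernel[1] // 2),
                          groups=groups) ** 2.0).sum().item()

    np.testing.assert_allclose(b.grad, numgrad(loss_b, b0.copy()),
                               rtol=1e-5, atol=1e-6)


def test_conv2d_channel_mismatch_raises(rng):
    x = Tensor(rng.normal(size=(1, 3, 4, 4)))
    w = Tensor(rng.normal(size=(2, 4, 3, 3)))
    with pytest.raises(ValueError, match="channel mismatch"):
        ad.conv2d(x, w, padding=1)


@pytest.mark.parametrize("pool,kwargs", [
    (ad.maxpool2d, dict(kernel=2, stride=2)),
    (ad.maxpool2d, dict(kernel=3, stride=1, padding=1)),
    (ad.avgpool2d, dict(kernel=2, stride=1)),
    (ad.avgpool2d, dict(kernel=2, stride=2)),
])
def test_pooling_grads(rng, pool, kwargs):
    # distinct values so maxpool argmaxes are stable under the fd step
    x0 = rng.permutation(np.arange(2 * 3 * 6 * 6)).reshape(2, 3, 6, 6) * 0.1
    _check_grad(lambda t: (pool(t, **kwargs) ** 2.0).sum(), x0, tol=1e-5)


def test_fft_primitive_grads(rng):
    x0 = rng.normal(size=(2, 5, 4))
    _check_grad(lambda t: (ad.fft2_re(t) ** 2.0).sum()
                + (ad.fft2_im(t) * 0.3).sum(), x0, tol=1e-5)


def test_ifft_primitive_grads(rng):
    re0 = rng.normal(size=(3, 4))
    im0 = rng.normal(size=(3, 4))
    re, im = Tensor(re0, True), Tensor(im0, True)
    loss = (ad.ifft2_real(re, im) ** 2.0).sum()
    loss.backward()
    num_re = numgrad(lambda a: (ad.ifft2_real(Tensor(a), Tensor(im0)) ** 2.0)
                     .sum().item(), re0.copy())
    num_im = numgrad(lambda a: (ad.ifft2_real(Tensor(re0), Tensor(a)) ** 2.0)
                     .sum().item(), im0.copy())
    np.testing.assert_allclose(re.grad, num_re, rtol=1e-5, atol=1e-7)
    np.testing.assert_allclose(im.grad, num_im, rtol=1e-5, atol=1e-7)


def test_polar_primitive_grads(rng):
    a0 = rng.normal(size=(4, 4)) + 2.0   # keep away from the origin
    b0 = rng.normal(size=(4, 4))
    for prim in (ad.hypot, ad.atan2):
        a, b = Tensor(a0, True), Tensor(b0, True)
        (prim(a, b) ** 2.0).sum().backward()
        na = numgrad(lambda v: (prim(Tensor(v), Tensor(b0)) ** 2.0).sum().item(),
                     a0.copy())
        nb = numgrad(lambda v: (prim(Tensor(a0), Tensor(v)) ** 2.0).sum().item(),
                     b0.copy())
        np.testing.assert_allclose(a.grad, na, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(b.grad, nb, rtol=1e-5, atol=1e-7)


def test_log_softmax_grad_and_normalization(rng):
    x0 = rng.normal(size=(3, 5))
    probs = np.exp(ad.log_softmax(Tensor(x0)).data)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    _check_grad(lambda t: (ad.log_softmax(t) * Tensor(x0 * 0 + 0.3)).sum(), x0)


def test_batchnorm_composition_grad(rng):
    from peppersort.nn import BatchNorm2d

    bn = BatchNorm2d(3)
    x0 = rng.normal(size=(4, 3, 5, 5))

    def loss(t):
        return (bn(t) ** 2.0 * 0.5).sum()

    _check_grad(loss, x0, tol=1e-4)
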