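"""Gradient and forward correctness of the autodiff engine.

Every primitive's analytic adjoint is verified against central finite
differences in float64; the convolutions are additionally checked against
direct loop oracles.
"""

import numpy as np
import pytest

from mirdescribe.nnet import (
    Adam,
    BatchNorm,
    Conv1d,
    Conv2d,
    ConvTranspose1d,
    Linear,
    MaskedLinear,
    Tensor,
    concat,
    log_softmax,
    set_default_dtype,
    softplus,
)


@pytest.fixture(autouse=True)
def _float64():
    set_default_dtype(np.float64)
    yield


def numeric_grad(fn, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        fp = fn()
        flat[i] = orig - h
        fm = fn()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * h)
    return g


def check_grad(build, x_data, tol=1e-6):
    """`build(tensor) -> scalar Tensor`; compares backward to central diff."""
    x = Tensor(x_data.copy(), requires_grad=True)
    out = build(x)
    out.backward()
    ana = x.grad.copy()

    def fn():
        return build(Tensor(x.data)).item()

    num = numeric_grad(fn, x.data)
    assert np.allclose(ana, num, rtol=1e-5, atol=tol), (
        f"max abs diff {np.abs(ana - num).max()}"
    )


@pytest.mark.parametrize("op", [
    lambda x: (x * 3.0 + 1.5).sum(),
    lambda x: (x * x).mean(),
    lambda x: (x / (x * x + 2.0)).sum(),
    lambda x: x.exp().sum(),
    lambda x: (x * x + 0.1).log().sum(),
    lambda x: x.tanh().sum(),
    lambda x: x.sigmoid().sum(),
    lambda x: x.elu().sum(),
    lambda x: softplus(x).sum(),
    lambda x: (x ** 3.0).sum(),
    lambda x: (-x).sum(),
    lambda x: x.reshape(6, 2).sum(axis=0).mean(),
    lambda x: x.transpose(1, 0).sum(axis=1, keepdims=True).sum(),
    lambda x: log_softmax(x, axis=1).sum(),
    lambda x: x[1:3, :2].sum(),
    lambda x: concat([x, x * 2.0], axis=0).sum(),
])
def test_elementwise_and_shaping_gradients(op, rng):
    x = rng.normal(size=(4, 3)) + 0.1
    check_grad(op, x)


def test_matmul_and_broadcast_gradients(rng):
    a_data = rng.normal(size=(3, 4))
    b_data = rng.normal(size=(4, 2))
    c_data = rng.normal(size=(2,))

    a = Tensor(a_data.copy(), requires_grad=True)
    b = Tensor(b_data.copy(), requires_grad=True)
    c = Tensor(c_data.copy(), requires_grad=True)
    ((a @ b + c) ** 2.0).sum().backward()

    ga = numeric_grad(lambda: float((((Tensor(a.data) @ Tensor(b_data)
                                       + Tensor(c_data)) ** 2.0).sum()).data),
                      a.data)
    assert np.allclose(a.grad, ga, rtol=1e-5, atol=1e-6)
    gb = numeric_grad(lambda: float((((Tensor(a_data) @ Tensor(b.data)
                                       + Tensor(c_data)) ** 2.0).sum()).data),
                      b.data)
    assert np.allclose(b.grad, gb, rtol=1e-5, atol=1e-6)
    gc = numeric_grad(lambda: float((((Tensor(a_data) @ Tensor(b_data)
                                       + Tensor(c.data)) ** 2.0).sum()).data),
                      c.data)
    assert np.allclose(c.grad, gc, rtol=1e-5, atol=1e-6)


def _conv2d_oracle(x, w, b, stride, padding):
    """Direct quadruple-loop convolution."""
    sh, sw = stride
    ph, pw = padding
    B, C, H, W = x.shape
    F, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    out = np.zeros((B, F, Ho, Wo))
    for bi in range(B):
        for f in range(F):
            for i in range(Ho):
                for j in range(Wo):
                    patch = xp[bi, :, i * sh:i * sh + kh, j * sw:j * sw + kw]
                    out[bi, f, i, j] = (patch * w[f]).sum() + b[f]
    return out


@pytest.mark.parametrize("stride", [1, 2])
def test_conv2d_matches_loop_oracle_and_gradcheck(stride, rng):
    conv = Conv2d(3, 4, 3, rng, stride=stride)
    x = rng.normal(size=(2, 3, 7, 9))
    out = conv(Tensor(x))
    oracle = _conv2d_oracle(x, conv.weight.data, conv.bias.data,
                            conv.stride, conv.padding)
    assert np.allclose(out.data, oracle, atol=1e-10)

    check_grad(lambda t: (conv(t) ** 2.0).sum(), x)
    # weight gradient
    xt = Tensor(x)
    conv.weight.grad = None
    (conv(xt) ** 2.0).sum().backward()
    ana = conv.weight.grad.copy()

    def fn():
        return float(((conv(Tensor(x)) ** 2.0).sum()).data)

    num = numeric_grad(fn, conv.weight.data)
    assert np.allclose(ana, num, rtol=1e-5, atol=1e-6)


def test_conv_transpose1d_matches_loop_oracle_and_gradcheck(rng):
    ct = ConvTranspose1d(3, 2, 4, rng, stride=2, padding=1)
    x = rng.normal(size=(2, 3, 5))
    out = ct(Tensor(x))
    # direct oracle: out[b,f,l*s - p + i] += x[b,c,l] w[c,f,i]
    B, C, L = x.shape
    _, F, k = ct.weight.data.shape
    Lout = (L - 1) * 2 - 2 + k
    oracle = np.zeros((B, F, Lout))
    for bi in range(B):
        for c in range(C):
            for f in range(F):
                for l in range(L):
                    for i in range(k):
                        t = l * 2 - 1 + i
                        if 0 <= t < Lout:
                            oracle[bi, f, t] += x[bi, c, l] * ct.weight.data[c, f, i]
    oracle += ct.bias.data[:, None]
    assert out.data.shape == (2, 2, 2 * L)
    assert np.allclose(out.data, oracle, atol=1e-10)

    check_grad(lambda t: (ct(t) ** 2.0).sum(), x)
    ct.weight.grad = None
    (ct(Tensor(x)) ** 2.0).sum().backward()
    ana = ct.weight.grad.copy()
    num = numeric_grad(lambda: float(((ct(Tensor(x)) ** 2.0).sum()).data),
                       ct.weight.data)
    assert np.allclose(ana, num, rtol=1e-5, atol=1e-6)


def test_conv1d_reduces_to_conv2d(rng):
    conv = Conv1d(2, 3, 5, rng, stride=2)
    x = rng.normal(size=(2, 2, 10))
    out = conv(Tensor(x))
    assert out.data.shape == (2, 3, 5)
    check_grad(lambda t: (conv(t) ** 2.0).sum(), x)


@pytest.mark.parametrize("shape", [(6, 4), (5, 3, 7), (4, 2, 5, 6)])
def test_batchnorm_train_gradcheck_and_eval_consistency(shape, rng):
    nfeat = shape[1] if len(shape) > 2 else shape[-1]
    bn = BatchNorm(nfeat)
    x = rng.normal(size=shape) * 2 + 1
    check_grad(lambda t: (bn(t) ** 2.0).sum(), x)

    # train-mode output is exactly normalized per feature
    bn2 = BatchNorm(nfeat)
    y = bn2(Tensor(x)).data
    axes = (0,) if len(shape) == 2 else tuple(i for i in range(len(shape)) if i != 1)
    assert np.allclose(y.mean(axis=axes), 0, atol=1e-10)
    assert np.allclose(y.var(axis=axes), 1, atol=1e-4)

    # eval mode: frozen statistics, deterministic and repeatable
    bn2.train(False)
    e1 = bn2(Tensor(x)).data
    e2 = bn2(Tensor(x)).data
    assert np.array_equal(e1, e2)
    check_grad(lambda t: (bn2(t) ** 2.0).sum(), x)


def test_masked_linear_respects_mask(rng):
    mask = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    ml = MaskedLinear(3, 2, mask, rng)
    x = rng.normal(size=(5, 3))
    out = ml(Tensor(x))
    # output 0 must not depend on input 2 (mask zero)
    x2 = x.copy()
    x2[:, 2] += 10.0
    out2 = ml(Tensor(x2))
    assert np.allclose(out.data[:, 0], out2.data[:, 0])
    assert not np.allclose(out.data[:, 1], out2.data[:, 1])


def test_adam_decreases_quadratic(rng):
    target = rng.normal(size=(4,))
    p = Tensor(np.zeros(4), requires_grad=True)
    opt = Adam([p], lr=0.05)
    for _ in range(400):
        opt.zero_grad()
        loss = ((p - Tensor(target)) ** 2.0).sum()
        loss.backward()
        opt.step()
    assert np.allclose(p.data, target, atol=1e-3)


def test_linear_deterministic_given_rng():
    l1 = Linear(4, 3, np.random.default_rng(9))
    l2 = Linear(4, 3, np.random.default_rng(9))
    assert np.array_equal(l1.weight.data, l2.weight.data)
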