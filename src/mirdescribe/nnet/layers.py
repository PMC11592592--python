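"""Neural-network building blocks: linear, convolutional, batch-norm and
masked (autoregressive) layers, plus the Adam optimizer.

Layout conventions follow the usual channels-first form: images are
``(B, C, H, W)``, 1-D signals ``(B, C, L)``. Weights are stored as
:class:`~mirdescribe.nnet.tensor.Tensor` leaves; every module exposes
``parameters()`` in a deterministic order so optimizer state and
checkpoints are reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "MaskedLinear",
    "Conv2d",
    "Conv1d",
    "ConvTranspose1d",
    "BatchNorm",
    "Adam",
]


class Module:
    """Base class; submodules/parameters are discovered from ``__dict__``."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        std = scale if scale is not None else np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MaskedLinear(Module):
    """Linear layer whose weight is elementwise-masked (MADE-style)."""

    def __init__(self, n_in: int, n_out: int, mask: np.ndarray,
                 rng: np.random.Generator, zero_init: bool = False):
        if mask.shape != (n_in, n_out):
            raise ValueError("mask shape mismatch")
        std = 0.0 if zero_init else np.sqrt(2.0 / max(1, n_in))
        self.weight = Tensor(rng.normal(0.0, std, size=(n_in, n_out)) if std else
                             np.zeros((n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self._mask = Tensor(mask.astype(np.float64))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ (self.weight * self._mask) + self.bias


# --------------------------------------------------------------------- conv2d

def _conv2d_forward(x: Tensor, w: Tensor, b: Tensor, stride, padding) -> Tensor:
    """Convolution as a sum of shifted matmuls over the kernel taps
    (BLAS-friendly; avoids slow strided im2col gathers)."""
    sh, sw = stride
    ph, pw = padding
    B, C, H, W = x.data.shape
    F, _, kh, kw = w.data.shape
    Hp, Wp = H + 2 * ph, W + 2 * pw
    if ph or pw:
        xp = np.zeros((B, C, Hp, Wp), dtype=x.data.dtype)
        xp[:, :, ph:ph + H, pw:pw + W] = x.data
    else:
        xp = x.data
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    HW = Ho * Wo
    acc = np.zeros((B, F, HW), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xij = np.ascontiguousarray(
                xp[:, :, i:i + (Ho - 1) * sh + 1:sh, j:j + (Wo - 1) * sw + 1:sw]
            ).reshape(B, C, HW)
            acc += w.data[:, :, i, j] @ xij
    out = Tensor(acc.reshape(B, F, Ho, Wo) + b.data[:, None, None],
                 parents=(x, w, b))

    def bw(g):
        gf = np.ascontiguousarray(g).reshape(B, F, HW)
        if b.requires_grad:
            b._accumulate(gf.sum(axis=(0, 2)))
        need_dx = x.requires_grad
        dxp = np.zeros((B, C, Hp, Wp), dtype=x.data.dtype) if need_dx else None
        for i in range(kh):
            for j in range(kw):
                sl = np.s_[:, :, i:i + (Ho - 1) * sh + 1:sh,
                           j:j + (Wo - 1) * sw + 1:sw]
                if w.requires_grad:
                    xij = np.ascontiguousarray(xp[sl]).reshape(B, C, HW)
                    w.grad = w.grad if w.grad is not None else np.zeros_like(w.data)
                    w.grad[:, :, i, j] += np.tensordot(gf, xij, ([0, 2], [0, 2]))
                if need_dx:
                    dxp[sl] += (w.data[:, :, i, j].T @ gf).reshape(B, C, Ho, Wo)
        if need_dx:
            x._accumulate(dxp[:, :, ph:ph + H, pw:pw + W]
                          if (ph or pw) else dxp)

    out._backward = bw
    return out


class Conv2d(Module):
    """2-D convolution, 'same'-style symmetric zero padding.

    ``stride`` may be an int or an (sh, sw) tuple."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int | tuple[int, int] = 1, padding: int | None = None):
        padding = kernel // 2 if padding is None else padding
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(_he(rng, (c_out, c_in, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = (stride, stride) if isinstance(stride, int) else tuple(stride)
        self.padding = (padding, padding)

    def __call__(self, x: Tensor) -> Tensor:
        return _conv2d_forward(x, self.weight, self.bias, self.stride, self.padding)


class Conv1d(Module):
    """1-D convolution implemented as a height-1 2-D convolution."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        padding = kernel // 2 if padding is None else padding
        fan_in = c_in * kernel
        self.weight = Tensor(_he(rng, (c_out, c_in, 1, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = (1, stride)
        self.padding = (0, padding)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, L = x.shape
        y = _conv2d_forward(x.reshape(B, C, 1, L), self.weight, self.bias,
                            self.stride, self.padding)
        Bo, Co, _, Lo = y.shape
        return y.reshape(Bo, Co, Lo)


# ----------------------------------------------------------- conv_transpose1d

def _conv_transpose1d_forward(x: Tensor, w: Tensor, b: Tensor,
                              stride: int, padding: int) -> Tensor:
    """Transposed 1-D convolution: out[b,f,i-p+s*l] += w[c,f,i] x[b,c,l]."""
    B, C, L = x.data.shape
    _, F, k = w.data.shape
    s, p = stride, padding
    Lout = (L - 1) * s - 2 * p + k
    if Lout < 1:
        raise ValueError("transposed convolution output would be empty")

    def _bounds(i):
        start = i - p
        l0 = (-start + s - 1) // s if start < 0 else 0
        l1 = min(L, (Lout - start + s - 1) // s)
        return start, l0, l1

    acc = np.zeros((B, F, Lout), dtype=x.data.dtype)
    for i in range(k):
        start, l0, l1 = _bounds(i)
        if l1 <= l0:
            continue
        acc[:, :, start + s * l0:start + s * (l1 - 1) + 1:s] += \
            w.data[:, :, i].T @ x.data[:, :, l0:l1]
    out = Tensor(acc + b.data[:, None], parents=(x, w, b))

    def bw(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        dx = np.zeros_like(x.data) if x.requires_grad else None
        for i in range(k):
            start, l0, l1 = _bounds(i)
            if l1 <= l0:
                continue
            gseg = g[:, :, start + s * l0:start + s * (l1 - 1) + 1:s]  # (B,F,seg)
            if w.requires_grad:
                w.grad = w.grad if w.grad is not None else np.zeros_like(w.data)
                w.grad[:, :, i] += np.tensordot(x.data[:, :, l0:l1], gseg,
                                                ([0, 2], [0, 2]))
            if dx is not None:
                dx[:, :, l0:l1] += w.data[:, :, i] @ gseg
        if dx is not None:
            x._accumulate(dx)

    out._backward = bw
    return out


class ConvTranspose1d(Module):
    """1-D transposed convolution (kernel 4, stride 2, padding 1 doubles L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 2, padding: int = 1):
        fan_in = c_in * kernel
        self.weight = Tensor(_he(rng, (c_in, c_out, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return _conv_transpose1d_forward(x, self.weight, self.bias,
                                         self.stride, self.padding)


# ------------------------------------------------------------------ batchnorm

class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1,
    or the last axis for 2-D inputs ``(B, D)``)."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        nd = x.data.ndim
        axes = (0,) if nd == 2 else tuple(i for i in range(nd) if i != 1)
        shape = [1] * nd
        shape[1 if nd > 2 else -1] = -1
        gam = self.gamma.data.reshape(shape)

        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            n = x.data.size // mu.size
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.ravel())
            # unbiased running variance, biased batch variance for normalisation
            unb = var.ravel() * (n / max(1, n - 1))
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unb
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - mu) * invstd
            out = Tensor(gam * xhat + self.beta.data.reshape(shape),
                         parents=(x, self.gamma, self.beta))

            def bw(g):
                if self.gamma.requires_grad:
                    self.gamma._accumulate((g * xhat).sum(axis=axes))
                if self.beta.requires_grad:
                    self.beta._accumulate(g.sum(axis=axes))
                if x.requires_grad:
                    dxhat = g * gam
                    m1 = dxhat.mean(axis=axes, keepdims=True)
                    m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
                    x._accumulate(invstd * (dxhat - m1 - xhat * m2))

            out._backward = bw
            return out

        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        mu = self.running_mean.reshape(shape)
        istd = invstd.reshape(shape)
        xhat = (x.data - mu) * istd
        out = Tensor(gam * xhat + self.beta.data.reshape(shape),
                     parents=(x, self.gamma, self.beta))

        def bw_eval(g):
            if self.gamma.requires_grad:
                self.gamma._accumulate((g * xhat).sum(axis=axes))
            if self.beta.requires_grad:
                self.beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                x._accumulate(g * gam * istd)

        out._backward = bw_eval
        return out


# ---------------------------------------------------------------------- adam

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
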