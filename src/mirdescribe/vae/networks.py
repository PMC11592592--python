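"""Network components: residual encoders, conditional priors, IAF flows,
auxiliary heads and the factorized height/color decoder.

Every latent space gets its own small ResNet encoder producing posterior
mean, log-variance and a context vector for its flow. The bond-vector
space and the class space have learned conditional priors; the residual
space keeps a standard normal prior. The decoder emits, per bar slot
(2 rows x 100 columns), a categorical over the 12 discrete bar heights
{0, 2, 3, ..., 12} and a categorical over the 5 colors.
"""

from __future__ import annotations

import numpy as np

from ..encoding import HEIGHTS, N_CHANNELS, N_COLS
from ..nnet import (
    Adam,  # noqa: F401  (re-exported for callers)
    BatchNorm,
    Conv1d,
    Conv2d,
    ConvTranspose1d,
    Linear,
    MaskedLinear,
    Module,
    Tensor,
    concat,
    log_softmax,
)
from .config import ModelConfig

N_HEIGHT_CLASSES = len(HEIGHTS)  # 12


class ResBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.bn1 = BatchNorm(channels)
        self.conv2 = Conv2d(channels, channels, 3, rng)
        self.bn2 = BatchNorm(channels)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).elu()
        h = self.bn2(self.conv2(h))
        return (x + h).elu()


class Encoder(Module):
    """ResNet encoder for one latent space: (B,5,25,100) -> mu, logvar, ctx.

    Height is downsampled before width: structural features live in
    column runs (consecutive gap or weak-bond columns), so the 100-column
    axis keeps full resolution through the first stage to avoid blurring
    narrow bulges. Spatial path: (25,100) -> (13,100) -> (7,50) -> (7,25).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        F = cfg.filters
        n2 = cfg.res_blocks // 2
        n3 = cfg.res_blocks - n2
        self.conv_in = Conv2d(N_CHANNELS, F, 3, rng, stride=(2, 1))
        self.bn_in = BatchNorm(F)
        self.conv_mid = Conv2d(F, 2 * F, 3, rng, stride=(2, 2))
        self.bn_mid = BatchNorm(2 * F)
        self.blocks2 = [ResBlock(2 * F, rng) for _ in range(n2)]
        self.conv_out = Conv2d(2 * F, 2 * F, 3, rng, stride=(1, 2))
        self.bn_out = BatchNorm(2 * F)
        self.blocks3 = [ResBlock(2 * F, rng) for _ in range(n3)]
        self.fc = Linear(2 * F * 7 * 25, cfg.enc_hidden, rng)
        self.fc_mu = Linear(cfg.enc_hidden, cfg.latent_dim, rng, scale=0.01)
        self.fc_logvar = Linear(cfg.enc_hidden, cfg.latent_dim, rng, scale=0.01)
        self.fc_context = Linear(cfg.enc_hidden, cfg.iaf_context, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        h = self.bn_in(self.conv_in(x)).elu()
        h = self.bn_mid(self.conv_mid(h)).elu()
        for blk in self.blocks2:
            h = blk(h)
        h = self.bn_out(self.conv_out(h)).elu()
        for blk in self.blocks3:
            h = blk(h)
        B = h.shape[0]
        h = h.reshape(B, -1)
        h = self.fc(h).elu()
        return self.fc_mu(h), self.fc_logvar(h), self.fc_context(h)


class MADE(Module):
    """One masked autoregressive step: two masked layers plus context.

    Output layers are zero-initialized so the enclosing flow starts as the
    identity (zero shift, zero log-scale).
    """

    def __init__(self, dim: int, hidden: int, context: int,
                 rng: np.random.Generator, reverse: bool = False):
        deg_in = np.arange(1, dim + 1)
        if reverse:
            deg_in = deg_in[::-1].copy()
        deg_hidden = (np.arange(hidden) % max(1, dim - 1)) + 1
        mask1 = (deg_hidden[None, :] >= deg_in[:, None]).astype(float)
        mask2 = (deg_in[None, :] > deg_hidden[:, None]).astype(float)
        self.ml1 = MaskedLinear(dim, hidden, mask1, rng)
        self.ctx = Linear(context, hidden, rng)
        self.out_m = MaskedLinear(hidden, dim, mask2, rng, zero_init=True)
        self.out_s = MaskedLinear(hidden, dim, mask2, rng, zero_init=True)

    def __call__(self, z: Tensor, context: Tensor) -> tuple[Tensor, Tensor]:
        h = (self.ml1(z) + self.ctx(context)).elu()
        return self.out_m(h), self.out_s(h)


class IAF(Module):
    """Stack of MADE blocks with alternating variable order.

    Each block applies z <- z * exp(tanh(s)) + m; tanh bounds the
    per-block scale for stability while keeping the exact identity (zero
    log-determinant) at initialization.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.blocks = [MADE(cfg.latent_dim, cfg.iaf_hidden, cfg.iaf_context,
                            rng, reverse=bool(k % 2))
                       for k in range(cfg.iaf_blocks)]

    def __call__(self, z: Tensor, context: Tensor) -> tuple[Tensor, Tensor]:
        logdet = Tensor(np.zeros(z.shape[0]))
        for made in self.blocks:
            m, s = made(z, context)
            t = s.tanh()
            z = z * t.exp() + m
            logdet = logdet + t.sum(axis=1)
        return z, logdet


class PriorM(Module):
    """Conditional prior p(z_m | m): 1-D conv net over the bond vector."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        F = cfg.filters
        self.conv1 = Conv1d(1, F, 5, rng, stride=2)
        self.bn1 = BatchNorm(F)
        self.conv2 = Conv1d(F, F, 5, rng, stride=2)
        self.bn2 = BatchNorm(F)
        self.fc = Linear(F * 25, cfg.enc_hidden // 2, rng)
        self.fc_mu = Linear(cfg.enc_hidden // 2, cfg.latent_dim, rng, scale=0.01)
        self.fc_logvar = Linear(cfg.enc_hidden // 2, cfg.latent_dim, rng, scale=0.01)

    def __call__(self, m: Tensor) -> tuple[Tensor, Tensor]:
        B = m.shape[0]
        h = m.reshape(B, 1, N_COLS)
        h = self.bn1(self.conv1(h)).elu()
        h = self.bn2(self.conv2(h)).elu()
        h = self.fc(h.reshape(B, -1)).elu()
        return self.fc_mu(h), self.fc_logvar(h)


class PriorY(Module):
    """Conditional prior p(z_y | y): two fully connected layers."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.fc = Linear(2, cfg.enc_hidden // 2, rng)
        self.fc_mu = Linear(cfg.enc_hidden // 2, cfg.latent_dim, rng, scale=0.01)
        self.fc_logvar = Linear(cfg.enc_hidden // 2, cfg.latent_dim, rng, scale=0.01)

    def __call__(self, y_onehot: Tensor) -> tuple[Tensor, Tensor]:
        h = self.fc(y_onehot).elu()
        return self.fc_mu(h), self.fc_logvar(h)


class ClassifierY(Module):
    """Auxiliary classifier q(y | z): two fully connected layers."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.fc1 = Linear(cfg.latent_dim, cfg.enc_hidden // 2, rng)
        self.fc2 = Linear(cfg.enc_hidden // 2, 2, rng)

    def __call__(self, z: Tensor) -> Tensor:
        return log_softmax(self.fc2(self.fc1(z).elu()), axis=1)


class ClassifierM(Module):
    """Auxiliary reconstructor q(m | z_m): FC + 1-D deconvolutions,
    per-position Bernoulli logits over the 100 columns."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        F = cfg.filters
        self.F = F
        self.fc = Linear(cfg.latent_dim, F * 25, rng)
        self.ct1 = ConvTranspose1d(F, F, 4, rng)
        self.ct2 = ConvTranspose1d(F, 1, 4, rng)

    def __call__(self, z: Tensor) -> Tensor:
        B = z.shape[0]
        h = self.fc(z).elu().reshape(B, self.F, 25)
        h = self.ct1(h).elu()
        return self.ct2(h).reshape(B, N_COLS)


class Decoder(Module):
    """Factorized decoder: shared FC stem, then a height branch (categorical
    over the 12 discrete bar heights per slot) and a color branch
    (categorical over 5 colors per slot); slots are 2 rows x 100 columns."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        F = cfg.filters
        self.C0 = 2 * F
        self.fc = Linear(3 * cfg.latent_dim, self.C0 * 25, rng)
        # height branch
        self.h_ct1 = ConvTranspose1d(self.C0, F, 4, rng)
        self.h_bn1 = BatchNorm(F)
        self.h_ct2 = ConvTranspose1d(F, F, 4, rng)
        self.h_bn2 = BatchNorm(F)
        self.h_out = Conv1d(F, 2 * N_HEIGHT_CLASSES, 3, rng)
        # color branch
        self.c_ct1 = ConvTranspose1d(self.C0, F, 4, rng)
        self.c_bn1 = BatchNorm(F)
        self.c_ct2 = ConvTranspose1d(F, F, 4, rng)
        self.c_bn2 = BatchNorm(F)
        self.c_out = Conv1d(F, 2 * N_CHANNELS, 3, rng)

    def __call__(self, z: Tensor) -> tuple[Tensor, Tensor]:
        B = z.shape[0]
        stem = self.fc(z).elu().reshape(B, self.C0, 25)
        h = self.h_bn1(self.h_ct1(stem)).elu()
        h = self.h_bn2(self.h_ct2(h)).elu()
        h_logits = self.h_out(h).reshape(B, 2, N_HEIGHT_CLASSES, N_COLS)
        c = self.c_bn1(self.c_ct1(stem)).elu()
        c = self.c_bn2(self.c_ct2(c)).elu()
        c_logits = self.c_out(c).reshape(B, 2, N_CHANNELS, N_COLS)
        return log_softmax(h_logits, axis=2), log_softmax(c_logits, axis=2)
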