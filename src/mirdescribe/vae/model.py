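"""The three-latent-space VAE model and its fitted results object.

``DivaVAE`` follows the Model/Results pattern: the model is constructed
from an encoded dataset (bar images x, bond vectors m, class labels y),
``fit`` trains encoders, conditional priors, flows, auxiliary heads and
the factorized decoder jointly, and returns a :class:`DivaVAEResults`
carrying the loss trajectory and everything downstream stages need
(latent embeddings, reconstructions, conditional generation).

Objective. Per sample the evidence lower bound is

    L_s = E_q[log p(x | z_m, z_y, z_x)]
          - beta_m KL(q(z_m|x) || p(z_m|m))
          - beta_x KL(q(z_x|x) || N(0, I))
          - beta_y KL(q(z_y|x) || p(z_y|y))

and the full objective adds the auxiliary heads:

    F = L_s + alpha_y1 E_q[log q(y|z_y)] + alpha_y2 E_q[log q(y|z_m)]
            + alpha_m E_q[log q(m|z_m)].

F is maximized; this implementation minimizes -F (the only place the sign
convention appears). With flows enabled each KL term is the standard
single-sample estimate log q(z) - log p(z) evaluated at the flowed sample;
the analytic diagonal-Gaussian divergences of the base posteriors are
logged alongside as diagnostics.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass

import numpy as np

from ..encoding import HEIGHTS, N_CHANNELS, N_COLS, N_ROWS, encode_image
from ..metrics import ReconstructionReport, mae, mae_length, nucleotide_accuracy
from ..nnet import Adam, BatchNorm, Tensor, concat, set_default_dtype, softplus
from .config import ModelConfig
from .networks import (
    IAF,
    ClassifierM,
    ClassifierY,
    Decoder,
    Encoder,
    PriorM,
    PriorY,
)

__all__ = ["DivaVAE", "DivaVAEResults", "LatentCode", "SpaceCode",
           "gaussian_kl", "image_targets", "expected_image", "render_discrete"]

_LOG2PI = float(np.log(2.0 * np.pi))
_HEIGHTS = np.array(HEIGHTS)


def gaussian_kl(mu_q, logvar_q, mu_p, logvar_p) -> np.ndarray:
    """Analytic KL(N_q || N_p) between diagonal Gaussians, per sample."""
    mu_q, logvar_q = np.asarray(mu_q), np.asarray(logvar_q)
    mu_p, logvar_p = np.asarray(mu_p), np.asarray(logvar_p)
    term = (logvar_p - logvar_q
            + (np.exp(logvar_q) + (mu_q - mu_p) ** 2) / np.exp(logvar_p) - 1.0)
    return 0.5 * term.sum(axis=-1)


# ------------------------------------------------------------------- targets

def image_targets(images: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per bar slot (2 rows x 100 columns): height class, color class and
    occupancy, read from (N, 100, 25, 5) one-hot images."""
    occ = images.sum(axis=3) > 0.5                       # (N,100,25)
    top_len = np.cumprod(occ, axis=2).sum(axis=2)
    bot_len = np.cumprod(occ[:, :, ::-1], axis=2).sum(axis=2)
    top_color = images[:, :, 0, :].argmax(axis=2)
    bot_color = images[:, :, -1, :].argmax(axis=2)
    h = np.stack([top_len, bot_len], axis=1)             # (N,2,100), px
    c = np.stack([top_color, bot_color], axis=1)
    hcls = np.where(h == 0, 0, h - 1).astype(np.int64)   # heights are {0,2..12}
    return hcls, c.astype(np.int64), (h > 0)


def render_discrete(heights: np.ndarray, colors: np.ndarray) -> np.ndarray:
    """Draw images from discrete bar heights (px) and color indices,
    both (n, 2, 100)."""
    n = heights.shape[0]
    img = np.zeros((n, N_COLS, N_ROWS, N_CHANNELS), dtype=np.uint8)
    for k in range(n):
        for col in range(N_COLS):
            ht = int(heights[k, 0, col])
            if ht:
                img[k, col, :ht, int(colors[k, 0, col])] = 1
            hb = int(heights[k, 1, col])
            if hb:
                img[k, col, N_ROWS - hb:, int(colors[k, 1, col])] = 1
    return img


_DEPTH = (_HEIGHTS[None, :] >= np.arange(1, 13)[:, None]).astype(float)  # (12 depths, 12 cls)


def expected_image(h_p: np.ndarray, c_p: np.ndarray) -> np.ndarray:
    """Expected image from height probabilities (2, 12, 100) and color
    probabilities (2, 5, 100): occupancy P(height >= depth) times color
    probability, drawn from both edges."""
    img = np.zeros((N_COLS, N_ROWS, N_CHANNELS))
    occ_top = _DEPTH @ h_p[0]                     # (12, 100)
    occ_bot = _DEPTH @ h_p[1]
    img[:, :12, :] = np.einsum("rc,kc->crk", occ_top, c_p[0])
    img[:, 13:, :] = np.einsum("rc,kc->crk", occ_bot[::-1], c_p[1])
    return img


# --------------------------------------------------------------- latent code

@dataclass
class SpaceCode:
    """Posterior pieces of one latent space (all Tensors except eps)."""
    mu: Tensor
    logvar: Tensor
    eps: np.ndarray
    z0: Tensor
    z: Tensor
    logdet: Tensor
    context: Tensor


@dataclass
class LatentCode:
    m: SpaceCode
    y: SpaceCode
    x: SpaceCode

    def spaces(self) -> dict[str, SpaceCode]:
        return {"m": self.m, "y": self.y, "x": self.x}


def _logq(code: SpaceCode) -> Tensor:
    """log q(z | x) at the flowed sample, per item."""
    base = ((code.logvar + _LOG2PI + Tensor(code.eps**2)) * (-0.5)).sum(axis=1)
    return base - code.logdet


def _logp_gauss(z: Tensor, mu: Tensor, logvar: Tensor) -> Tensor:
    diff = z - mu
    return ((logvar + _LOG2PI) * (-0.5) - diff * diff * (logvar * (-1.0)).exp() * 0.5
            ).sum(axis=1)


def _logp_std(z: Tensor) -> Tensor:
    return (z * z * 0.5 + 0.5 * _LOG2PI).sum(axis=1) * (-1.0)


# --------------------------------------------------------------------- model

class DivaVAE:
    """Disentangling VAE over bar images with bond-strength and class
    conditioning.

    Parameters
    ----------
    images : (N, 100, 25, 5) one-hot uint8 array of encoded bar images.
    bonds : (N, 100) binary bond-strength vectors m.
    labels : (N,) binary class labels y (1 = pre-miRNA).
    config : ModelConfig, defaults to the desk scale.
    """

    def __init__(self, images: np.ndarray, bonds: np.ndarray, labels: np.ndarray,
                 config: ModelConfig | None = None):
        self.config = config or ModelConfig.desk()
        self.images = np.asarray(images, dtype=np.uint8)
        self.bonds = np.asarray(bonds, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[1:] != (N_COLS, N_ROWS, N_CHANNELS):
            raise ValueError(f"images must be (N, {N_COLS}, {N_ROWS}, {N_CHANNELS})")
        if len(self.bonds) != len(self.images) or len(self.labels) != len(self.images):
            raise ValueError("images, bonds and labels must have equal length")
        self.hcls, self.ccls, self.occ = image_targets(self.images)
        self.x_input = self.images.transpose(0, 3, 2, 1).astype(np.float32)  # (N,5,25,100)
        self._fitted = False

    @classmethod
    def from_records(cls, records, config: ModelConfig | None = None) -> "DivaVAE":
        imgs, ms, ys = [], [], []
        for r in records:
            img, m = encode_image(r)
            imgs.append(img)
            ms.append(m)
            ys.append(0 if r.label is None else r.label)
        return cls(np.stack(imgs), np.stack(ms), np.array(ys), config)

    # ------------------------------------------------------------- building
    def _build(self, seed: int) -> None:
        set_default_dtype(self.config.dtype)
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.enc_m = Encoder(cfg, rng)
        self.enc_y = Encoder(cfg, rng)
        self.enc_x = Encoder(cfg, rng)
        self.iaf_m = IAF(cfg, rng) if cfg.use_flows else None
        self.iaf_y = IAF(cfg, rng) if cfg.use_flows else None
        self.iaf_x = IAF(cfg, rng) if cfg.use_flows else None
        self.prior_m = PriorM(cfg, rng)
        self.prior_y = PriorY(cfg, rng)
        self.clf_y_zy = ClassifierY(cfg, rng)
        self.clf_y_zm = ClassifierY(cfg, rng)
        self.clf_m = ClassifierM(cfg, rng)
        self.decoder = Decoder(cfg, rng)

    def _module_list(self):
        mods = [self.enc_m, self.enc_y, self.enc_x]
        mods += [f for f in (self.iaf_m, self.iaf_y, self.iaf_x) if f is not None]
        mods += [self.prior_m, self.prior_y, self.clf_y_zy, self.clf_y_zm,
                 self.clf_m, self.decoder]
        return mods

    def parameters(self):
        params = []
        for mod in self._module_list():
            params.extend(mod.parameters())
        return params

    def train_mode(self, mode: bool = True) -> None:
        for mod in self._module_list():
            mod.train(mode)

    # ----------------------------------------------------------- state (de)ser
    def state_bytes(self) -> bytes:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        bn = [m for mod in self._module_list() for m in mod.modules()
              if isinstance(m, BatchNorm)]
        for i, b in enumerate(bn):
            arrays[f"bn{i}_mean"] = b.running_mean
            arrays[f"bn{i}_var"] = b.running_var
        buf = io.BytesIO()
        np.savez(buf, meta=np.frombuffer(
            json.dumps(self.config.as_dict()).encode(), dtype=np.uint8), **arrays)
        return buf.getvalue()

    def load_state_bytes(self, blob: bytes) -> None:
        data = np.load(io.BytesIO(blob))
        for i, p in enumerate(self.parameters()):
            p.data = data[f"p{i}"].copy()
        bn = [m for mod in self._module_list() for m in mod.modules()
              if isinstance(m, BatchNorm)]
        for i, b in enumerate(bn):
            b.running_mean = data[f"bn{i}_mean"].copy()
            b.running_var = data[f"bn{i}_var"].copy()

    def save_state(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.state_bytes())

    def load_state(self, path) -> None:
        self._build(seed=0)
        with open(path, "rb") as fh:
            self.load_state_bytes(fh.read())
        self._fitted = True

    # ------------------------------------------------------------- forward
    def latent_code(self, x_t: Tensor, eps: dict[str, np.ndarray] | None = None,
                    rng: np.random.Generator | None = None) -> LatentCode:
        """Encode a batch into the three latent spaces.

        ``eps`` supplies the standard-normal reparameterization noise per
        space (zeros give the deterministic mean pass); otherwise it is
        drawn from ``rng``.
        """
        set_default_dtype(self.config.dtype)
        B = x_t.shape[0]
        dim = self.config.latent_dim
        out = {}
        flows = {"m": self.iaf_m, "y": self.iaf_y, "x": self.iaf_x}
        for name, enc in (("m", self.enc_m), ("y", self.enc_y), ("x", self.enc_x)):
            mu, logvar, ctx = enc(x_t)
            if eps is not None:
                e = np.asarray(eps[name], dtype=np.float64)
            elif rng is not None:
                e = rng.standard_normal((B, dim))
            else:
                e = np.zeros((B, dim))
            z0 = mu + (logvar * 0.5).exp() * Tensor(e)
            if flows[name] is not None:
                z, logdet = flows[name](z0, ctx)
            else:
                z, logdet = z0, Tensor(np.zeros(B))
            if not np.all(np.isfinite(z.data)):
                raise FloatingPointError(f"non-finite activations in space {name}")
            out[name] = SpaceCode(mu, logvar, e, z0, z, logdet, ctx)
        return LatentCode(**out)

    def decode(self, z_m: Tensor, z_y: Tensor, z_x: Tensor) -> tuple[Tensor, Tensor]:
        """Height and color log-probabilities, (B,2,12,100) and (B,2,5,100)."""
        return self.decoder(concat([z_m, z_y, z_x], axis=1))

    def reconstruction_loglik(self, h_logp: Tensor, c_logp: Tensor,
                              hcls: np.ndarray, ccls: np.ndarray,
                              occ: np.ndarray) -> Tensor:
        """Mean per-sample log-likelihood of the factorized (height, color)
        categorical; the color factor is counted only for occupied slots
        (a zero-height slot carries no color)."""
        B = hcls.shape[0]
        hoh = np.zeros((B, 2, len(HEIGHTS), N_COLS))
        np.put_along_axis(hoh, hcls[:, :, None, :], 1.0, axis=2)
        coh = np.zeros((B, 2, N_CHANNELS, N_COLS))
        np.put_along_axis(coh, ccls[:, :, None, :], 1.0, axis=2)
        coh *= occ[:, :, None, :]
        ll = (h_logp * Tensor(hoh)).sum(axis=(1, 2, 3)) \
            + (c_logp * Tensor(coh)).sum(axis=(1, 2, 3))
        return ll.mean()

    def elbo_terms(self, m: np.ndarray, x_targets, y: np.ndarray,
                   code: LatentCode) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """The four summands of the ELBO: (reconstruction, KL_m, KL_x, KL_y).

        ``x_targets`` is the (height-class, color-class, occupancy) triple
        of the batch. KLs are single-sample estimates through the flows.
        """
        hcls, ccls, occ = x_targets
        h_logp, c_logp = self.decode(code.m.z, code.y.z, code.x.z)
        recon = self.reconstruction_loglik(h_logp, c_logp, hcls, ccls, occ)

        pm_mu, pm_logvar = self.prior_m(Tensor(m))
        kl_m = (_logq(code.m) - _logp_gauss(code.m.z, pm_mu, pm_logvar)).mean()
        kl_x = (_logq(code.x) - _logp_std(code.x.z)).mean()
        y_oh = np.eye(2)[y]
        py_mu, py_logvar = self.prior_y(Tensor(y_oh))
        kl_y = (_logq(code.y) - _logp_gauss(code.y.z, py_mu, py_logvar)).mean()
        for name, kl in (("m", kl_m), ("x", kl_x), ("y", kl_y)):
            if not np.isfinite(kl.data):
                raise FloatingPointError(f"non-finite KL in space {name}")
        return recon, kl_m, kl_x, kl_y

    def aux_terms(self, m: np.ndarray, y: np.ndarray,
                  code: LatentCode) -> tuple[Tensor, Tensor, Tensor]:
        """Mean log-probabilities of the auxiliary heads:
        (log q(y|z_y), log q(y|z_m), log q(m|z_m))."""
        y_oh = np.eye(2)[y]
        ay1 = (self.clf_y_zy(code.y.z) * Tensor(y_oh)).sum(axis=1).mean()
        ay2 = (self.clf_y_zm(code.m.z) * Tensor(y_oh)).sum(axis=1).mean()
        logits = self.clf_m(code.m.z)
        mt = Tensor(m)
        ll = (softplus(-logits) * mt + softplus(logits) * (1.0 - mt)) * (-1.0)
        am = ll.sum(axis=1).mean()
        return ay1, ay2, am

    def diva_loss(self, m: np.ndarray, x_targets, y: np.ndarray,
                  code: LatentCode) -> Tensor:
        """The full objective F (maximized; training minimizes -F)."""
        cfg = self.config
        recon, kl_m, kl_x, kl_y = self.elbo_terms(m, x_targets, y, code)
        ls = recon - cfg.beta_m * kl_m - cfg.beta_x * kl_x - cfg.beta_y * kl_y
        ay1, ay2, am = self.aux_terms(m, y, code)
        return ls + cfg.alpha_y1 * ay1 + cfg.alpha_y2 * ay2 + cfg.alpha_m * am

    def analytic_kls(self, m: np.ndarray, y: np.ndarray,
                     code: LatentCode) -> dict[str, float]:
        """Analytic diagonal-Gaussian KLs of the base posteriors against the
        (conditional) priors; logged as non-negative diagnostics."""
        pm_mu, pm_logvar = self.prior_m(Tensor(m))
        py_mu, py_logvar = self.prior_y(Tensor(np.eye(2)[y]))
        return {
            "m": float(np.mean(gaussian_kl(code.m.mu.data, code.m.logvar.data,
                                           pm_mu.data, pm_logvar.data))),
            "x": float(np.mean(gaussian_kl(code.x.mu.data, code.x.logvar.data,
                                           0.0, 0.0))),
            "y": float(np.mean(gaussian_kl(code.y.mu.data, code.y.logvar.data,
                                           py_mu.data, py_logvar.data))),
        }

    # ------------------------------------------------------------- training
    def fit(self, seed: int = 0, epochs: int | None = None, max_epochs: int = 200,
            val_fraction: float = 0.15, rel_tol: float = 1e-3,
            verbose: bool = False, resume: bool = False) -> "DivaVAEResults":
        """Train with Adam until convergence (or for a fixed epoch count).

        Convergence: the 5-epoch moving average of the validation loss
        improves by less than ``rel_tol`` (0.1%). Identical seeds yield
        identical trajectories. On divergence (non-finite loss) training
        stops and the last finite checkpoint is restored. With
        ``resume=True`` the current weights (e.g. from ``load_state``) are
        kept and training continues instead of re-initializing.
        """
        rng = np.random.default_rng(seed)
        init_seed = int(rng.integers(2**31 - 1))
        if not (resume and getattr(self, "enc_m", None) is not None):
            self._build(init_seed)
        cfg = self.config
        opt = Adam(self.parameters(), lr=cfg.lr)
        n = len(self.images)
        order = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n))) if n > 4 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]

        history: list[dict] = []
        checkpoint = self.state_bytes()
        val_ma: list[float] = []
        n_epochs = epochs if epochs is not None else max_epochs
        for epoch in range(n_epochs):
            self.train_mode(True)
            perm = rng.permutation(train_idx)
            sums: dict[str, float] = {}
            n_batches = 0
            try:
                for lo in range(0, len(perm), cfg.batch_size):
                    idx = perm[lo:lo + cfg.batch_size]
                    if len(idx) < 2:
                        continue  # batch-norm needs > 1 sample
                    terms = self._step(idx, opt, rng)
                    for k, v in terms.items():
                        sums[k] = sums.get(k, 0.0) + v
                    n_batches += 1
            except FloatingPointError as exc:
                warnings.warn(f"training diverged at epoch {epoch} ({exc}); "
                              "restoring last finite checkpoint")
                self.load_state_bytes(checkpoint)
                break
            row = {k: v / max(1, n_batches) for k, v in sums.items()}
            row["epoch"] = epoch
            row["val_loss"] = self._eval_loss(val_idx) if len(val_idx) else row["loss"]
            if not np.isfinite(row["loss"]) or not np.isfinite(row["val_loss"]):
                warnings.warn(f"training diverged at epoch {epoch}; "
                              "restoring last finite checkpoint")
                self.load_state_bytes(checkpoint)
                break
            history.append(row)
            checkpoint = self.state_bytes()
            if verbose:
                print(f"epoch {epoch:3d}  loss {row['loss']:10.2f}  "
                      f"val {row['val_loss']:10.2f}")
            if epochs is None:
                val_ma.append(row["val_loss"])
                if len(val_ma) >= 10:
                    prev = float(np.mean(val_ma[-10:-5]))
                    curr = float(np.mean(val_ma[-5:]))
                    if prev - curr < rel_tol * abs(prev):
                        break

        self._fitted = True
        import pandas as pd

        return DivaVAEResults(self, pd.DataFrame(history), seed,
                              train_idx=train_idx, val_idx=val_idx)

    def _batch(self, idx: np.ndarray):
        x_t = Tensor(self.x_input[idx])
        return (x_t, self.bonds[idx], self.labels[idx],
                (self.hcls[idx], self.ccls[idx], self.occ[idx]))

    def _step(self, idx, opt: Adam, rng) -> dict[str, float]:
        x_t, m, y, targets = self._batch(idx)
        code = self.latent_code(x_t, rng=rng)
        recon, kl_m, kl_x, kl_y = self.elbo_terms(m, targets, y, code)
        cfg = self.config
        ls = recon - cfg.beta_m * kl_m - cfg.beta_x * kl_x - cfg.beta_y * kl_y
        ay1, ay2, am = self.aux_terms(m, y, code)
        f = ls + cfg.alpha_y1 * ay1 + cfg.alpha_y2 * ay2 + cfg.alpha_m * am
        loss = -f
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite loss")
        opt.zero_grad()
        loss.backward()
        opt.step()
        akl = self.analytic_kls(m, y, code)
        return {"loss": loss.item(), "recon": recon.item(),
                "kl_m": kl_m.item(), "kl_x": kl_x.item(), "kl_y": kl_y.item(),
                "kl_m_analytic": akl["m"], "kl_x_analytic": akl["x"],
                "kl_y_analytic": akl["y"],
                "aux_y1": ay1.item(), "aux_y2": ay2.item(), "aux_m": am.item()}

    def _eval_loss(self, idx: np.ndarray) -> float:
        """Deterministic (mean-pass) validation loss in eval mode."""
        self.train_mode(False)
        total, count = 0.0, 0
        for lo in range(0, len(idx), self.config.batch_size):
            sub = idx[lo:lo + self.config.batch_size]
            x_t, m, y, targets = self._batch(sub)
            dim = self.config.latent_dim
            eps = {k: np.zeros((len(sub), dim)) for k in ("m", "y", "x")}
            code = self.latent_code(x_t, eps=eps)
            f = self.diva_loss(m, targets, y, code)
            total += -f.item() * len(sub)
            count += len(sub)
        self.train_mode(True)
        return total / max(1, count)


# ------------------------------------------------------------------- results

class _PredBar:
    __slots__ = ("color", "length")

    def __init__(self, color: str, length: int):
        self.color = color
        self.length = length


_COLOR_NAMES = ("A", "C", "G", "U", "GAP")


class DivaVAEResults:
    """Fitted VAE: loss trajectory plus encode/decode conveniences."""

    def __init__(self, model: DivaVAE, history, seed: int, train_idx=None,
                 val_idx=None):
        self.model = model
        self.history = history
        self.seed = seed
        self.train_idx = train_idx
        self.val_idx = val_idx
        self.config = model.config

    # ------------------------------------------------------------- latents
    def encode_latents(self, images: np.ndarray | None = None,
                       batch_size: int = 256) -> dict[str, np.ndarray]:
        """Deterministic (mean-pass, eval-mode) latent embeddings."""
        model = self.model
        x_in = (model.x_input if images is None
                else np.asarray(images, np.float64).transpose(0, 3, 2, 1))
        model.train_mode(False)
        out = {"z_m": [], "z_y": [], "z_x": []}
        dim = model.config.latent_dim
        for lo in range(0, len(x_in), batch_size):
            xb = Tensor(x_in[lo:lo + batch_size])
            eps = {k: np.zeros((xb.shape[0], dim)) for k in ("m", "y", "x")}
            code = model.latent_code(xb, eps=eps)
            out["z_m"].append(code.m.z.data)
            out["z_y"].append(code.y.z.data)
            out["z_x"].append(code.x.z.data)
        return {k: np.concatenate(v) for k, v in out.items()}

    # ------------------------------------------------------- reconstruction
    def decode_distributions(self, images: np.ndarray,
                             batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """Height and color probabilities (N,2,12,100), (N,2,5,100) for the
        deterministic reconstruction of each image."""
        model = self.model
        x_in = np.asarray(images, np.float64).transpose(0, 3, 2, 1)
        model.train_mode(False)
        hs, cs = [], []
        dim = model.config.latent_dim
        for lo in range(0, len(x_in), batch_size):
            xb = Tensor(x_in[lo:lo + batch_size])
            eps = {k: np.zeros((xb.shape[0], dim)) for k in ("m", "y", "x")}
            code = model.latent_code(xb, eps=eps)
            h_logp, c_logp = model.decode(code.m.z, code.y.z, code.x.z)
            hs.append(np.exp(h_logp.data))
            cs.append(np.exp(c_logp.data))
        return np.concatenate(hs), np.concatenate(cs)

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        """Expected reconstructed images, (N, 100, 25, 5) floats."""
        h_p, c_p = self.decode_distributions(images)
        return np.stack([expected_image(h_p[i], c_p[i]) for i in range(len(h_p))])

    def evaluate(self, images: np.ndarray) -> ReconstructionReport:
        """Reconstruction metrics against the given images.

        MAE uses the expected image over every pixel-channel value; color
        accuracy and length error enumerate the true image's occupied bars
        in column order (top row before bottom) and compare the decoder's
        argmax color / height at those slots.
        """
        images = np.asarray(images, np.uint8)
        h_p, c_p = self.decode_distributions(images)
        hcls, ccls, occ = image_targets(images)
        heights_hat = _HEIGHTS[h_p.argmax(axis=2)]      # (N,2,100) px
        colors_hat = c_p.argmax(axis=2)                 # (N,2,100)
        err = 0.0
        true_bars, pred_bars = [], []
        for i in range(len(images)):
            err += mae(images[i], expected_image(h_p[i], c_p[i]))
            for col in range(N_COLS):
                for row in (0, 1):
                    if occ[i, row, col]:
                        h = int(hcls[i, row, col])
                        true_bars.append(_PredBar(_COLOR_NAMES[ccls[i, row, col]],
                                                  HEIGHTS[h]))
                        pred_bars.append(_PredBar(_COLOR_NAMES[colors_hat[i, row, col]],
                                                  int(heights_hat[i, row, col])))
        return ReconstructionReport(
            mae=err / len(images),
            nucleotide_accuracy=nucleotide_accuracy(true_bars, pred_bars),
            mae_length=mae_length(true_bars, pred_bars),
            n_images=len(images),
            n_bars=len(true_bars),
        )

    # ------------------------------------------------- conditional generation
    def conditional_generate(self, image: np.ndarray, m_new: np.ndarray,
                             n_samples: int = 1,
                             rng: np.random.Generator | None = None,
                             mode: str = "sample",
                             prior_eps: np.ndarray | None = None) -> np.ndarray:
        """Swap the bond-strength conditioning of one image.

        Encodes ``image`` to (z_y, z_x), samples z_m' from the conditional
        prior given ``m_new`` and decodes. ``mode='sample'`` draws discrete
        heights/colors per bar slot; ``mode='argmax'`` renders the modal
        bar. ``prior_eps`` (n_samples, latent_dim) fixes the prior's
        reparameterization noise, which pairs draws across different
        ``m_new`` so comparisons isolate the conditioning effect.
        Returns (n_samples, 100, 25, 5) uint8 images.
        """
        if not self.model._fitted:
            raise RuntimeError("model is not trained; call fit() first")
        model = self.model
        rng = rng or np.random.default_rng(0)
        model.train_mode(False)
        x_t = Tensor(np.asarray(image, np.float64)[None].transpose(0, 3, 2, 1))
        dim = model.config.latent_dim
        eps = {k: np.zeros((1, dim)) for k in ("m", "y", "x")}
        code = model.latent_code(x_t, eps=eps)
        pm_mu, pm_logvar = model.prior_m(Tensor(np.asarray(m_new, np.float64)[None]))
        sigma = np.exp(0.5 * pm_logvar.data)
        out = []
        for k in range(n_samples):
            e = (prior_eps[k][None] if prior_eps is not None
                 else rng.standard_normal((1, dim)))
            z_m = Tensor(pm_mu.data + sigma * e)
            h_logp, c_logp = model.decode(z_m, code.y.z, code.x.z)
            h_p, c_p = np.exp(h_logp.data[0]), np.exp(c_logp.data[0])
            if mode == "argmax":
                heights = _HEIGHTS[h_p.argmax(axis=1)][None]
                colors = c_p.argmax(axis=1)[None]
            else:
                heights = np.zeros((1, 2, N_COLS), dtype=int)
                colors = np.zeros((1, 2, N_COLS), dtype=int)
                for row in range(2):
                    for col in range(N_COLS):
                        hc = rng.choice(len(HEIGHTS), p=h_p[row, :, col]
                                        / h_p[row, :, col].sum())
                        heights[0, row, col] = HEIGHTS[hc]
                        colors[0, row, col] = rng.choice(
                            N_CHANNELS, p=c_p[row, :, col] / c_p[row, :, col].sum())
            out.append(render_discrete(heights, colors)[0])
        return np.stack(out)

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "DIVA-style VAE results",
            "=" * 52,
            f"scale preset        {cfg.scale}",
            f"latent dims         3 x {cfg.latent_dim}",
            f"IAF                 {cfg.iaf_blocks} blocks, hidden {cfg.iaf_hidden}",
            f"beta (m, x, y)      {cfg.beta_m}, {cfg.beta_x}, {cfg.beta_y}",
            f"alpha (y1, y2, m)   {cfg.alpha_y1}, {cfg.alpha_y2}, {cfg.alpha_m}",
            f"n samples           {len(self.model.images)}",
            f"epochs run          {len(self.history)}",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines += [
                f"final train loss    {last['loss']:.3f}",
                f"final val loss      {last['val_loss']:.3f}",
                f"final recon loglik  {last['recon']:.3f}",
                f"final KL (m,x,y)    {last['kl_m']:.3f}, {last['kl_x']:.3f}, "
                f"{last['kl_y']:.3f}",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.model.save_state(path)
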