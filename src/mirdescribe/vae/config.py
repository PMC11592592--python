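"""Hyperparameter configuration for the three-latent-space VAE."""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = ["ModelConfig"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and objective weights.

    The ``full`` scale is the reference configuration (latent spaces of
    64, 8 IAF blocks of 2 MADE layers with hidden size 1080 and context
    32, beta = 0.5 per KL term, alpha_y1 = alpha_y2 = 12, alpha_m = 1,
    Adam at lr 5e-4 with batch size 64). The ``desk`` scale shrinks widths
    (latent 8, fewer filters, small flows) for CPU-scale experiments while
    keeping every loss term unchanged.
    """

    latent_dim: int = 64
    iaf_blocks: int = 8
    iaf_context: int = 32
    iaf_hidden: int = 1080
    beta_m: float = 0.5
    beta_x: float = 0.5
    beta_y: float = 0.5
    alpha_y1: float = 12.0
    alpha_y2: float = 12.0
    alpha_m: float = 1.0
    lr: float = 5e-4
    batch_size: int = 64
    scale: str = "full"
    filters: int = 32
    res_blocks: int = 8
    enc_hidden: int = 256
    use_flows: bool = True
    dtype: str = "float32"

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        for name in ("beta_m", "beta_x", "beta_y", "alpha_y1", "alpha_y2", "alpha_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batch_size < 1 or self.iaf_blocks < 0:
            raise ValueError("batch_size >= 1 and iaf_blocks >= 0 required")
        if self.scale not in ("full", "desk", "tiny"):
            raise ValueError("scale must be 'full', 'desk' or 'tiny'")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    @classmethod
    def full(cls, **overrides) -> "ModelConfig":
        return cls(**{**dict(scale="full"), **overrides})

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        base = dict(latent_dim=8, iaf_blocks=2, iaf_context=8, iaf_hidden=32,
                    filters=8, res_blocks=4, enc_hidden=64, scale="desk")
        return cls(**{**base, **overrides})

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """2-dimensional latents and minimal widths; for numerical tests."""
        base = dict(latent_dim=2, iaf_blocks=1, iaf_context=2, iaf_hidden=8,
                    filters=2, res_blocks=1, enc_hidden=8, batch_size=2,
                    scale="tiny", dtype="float64")
        return cls(**{**base, **overrides})

    def as_dict(self) -> dict:
        return asdict(self)
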