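"""VAE contracts: shapes, determinism, loss algebra, flows, decoder codec."""

import numpy as np
import pytest

from mirdescribe.encoding import HEIGHTS
from mirdescribe.nnet import Tensor, set_default_dtype
from mirdescribe.simulate import GeneratorConfig, generate_dataset
from mirdescribe.vae.config import ModelConfig
from mirdescribe.vae.model import (
    DivaVAE,
    expected_image,
    gaussian_kl,
    image_targets,
    render_discrete,
)
from mirdescribe.vae.networks import IAF


@pytest.fixture(scope="module")
def tiny_model():
    recs = generate_dataset(GeneratorConfig(n_samples=16, seed=5))
    model = DivaVAE.from_records(recs, ModelConfig.tiny())
    model._build(0)
    return model


def _eps(n, dim, seed=0):
    r = np.random.default_rng(seed)
    return {k: r.standard_normal((n, dim)) for k in ("m", "y", "x")}


def test_latent_shapes(tiny_model):
    x_t, m, y, targets = tiny_model._batch(np.arange(2))
    code = tiny_model.latent_code(x_t, eps=_eps(2, 2))
    for space in (code.m, code.y, code.x):
        assert space.z.shape == (2, 2)
        assert space.mu.shape == (2, 2)
        assert space.logdet.shape == (2,)


def test_same_noise_same_latents(tiny_model):
    x_t, *_ = tiny_model._batch(np.arange(3))
    c1 = tiny_model.latent_code(x_t, eps=_eps(3, 2, seed=1))
    c2 = tiny_model.latent_code(x_t, eps=_eps(3, 2, seed=1))
    assert np.array_equal(c1.m.z.data, c2.m.z.data)
    c3 = tiny_model.latent_code(x_t, eps=_eps(3, 2, seed=2))
    assert not np.array_equal(c1.m.z.data, c3.m.z.data)


def test_identity_initialized_flow_is_passthrough():
    set_default_dtype(np.float64)
    cfg = ModelConfig.tiny(latent_dim=4, iaf_blocks=3, iaf_context=2)
    flow = IAF(cfg, np.random.default_rng(0))
    rng = np.random.default_rng(1)
    z = Tensor(rng.normal(size=(6, 4)))
    ctx = Tensor(rng.normal(size=(6, 2)))
    out, logdet = flow(z, ctx)
    assert np.array_equal(out.data, z.data)
    assert np.array_equal(logdet.data, np.zeros(6))


def test_flow_disabled_equals_identity_initialized(tiny_model):
    recs = generate_dataset(GeneratorConfig(n_samples=8, seed=5))
    no_flow = DivaVAE.from_records(recs, ModelConfig.tiny(use_flows=False))
    no_flow._build(0)
    x_t, *_ = no_flow._batch(np.arange(2))
    code = no_flow.latent_code(x_t, eps=_eps(2, 2))
    assert np.array_equal(code.m.z.data, code.m.z0.data)
    assert np.array_equal(code.m.logdet.data, np.zeros(2))


def test_loss_decomposition_is_exact(tiny_model):
    x_t, m, y, targets = tiny_model._batch(np.arange(4))
    code = tiny_model.latent_code(x_t, eps=_eps(4, 2))
    recon, kl_m, kl_x, kl_y = tiny_model.elbo_terms(m, targets, y, code)
    ay1, ay2, am = tiny_model.aux_terms(m, y, code)
    cfg = tiny_model.config
    code2 = tiny_model.latent_code(x_t, eps=_eps(4, 2))
    f = tiny_model.diva_loss(m, targets, y, code2)
    manual = (recon.item()
              - cfg.beta_m * kl_m.item() - cfg.beta_x * kl_x.item()
              - cfg.beta_y * kl_y.item()
              + cfg.alpha_y1 * ay1.item() + cfg.alpha_y2 * ay2.item()
              + cfg.alpha_m * am.item())
    assert f.item() == pytest.approx(manual, rel=1e-12)


def test_alpha_zero_reduces_to_elbo():
    recs = generate_dataset(GeneratorConfig(n_samples=8, seed=5))
    model = DivaVAE.from_records(
        recs, ModelConfig.tiny(alpha_y1=0.0, alpha_y2=0.0, alpha_m=0.0))
    model._build(0)
    x_t, m, y, targets = model._batch(np.arange(4))
    code = model.latent_code(x_t, eps=_eps(4, 2))
    recon, kl_m, kl_x, kl_y = model.elbo_terms(m, targets, y, code)
    code2 = model.latent_code(x_t, eps=_eps(4, 2))
    f = model.diva_loss(m, targets, y, code2)
    ls = (recon.item() - 0.5 * (kl_m.item() + kl_x.item() + kl_y.item()))
    assert f.item() == pytest.approx(ls, rel=1e-12)


def test_beta_zero_reduces_to_reconstruction():
    recs = generate_dataset(GeneratorConfig(n_samples=8, seed=5))
    model = DivaVAE.from_records(
        recs, ModelConfig.tiny(beta_m=0.0, beta_x=0.0, beta_y=0.0,
                               alpha_y1=0.0, alpha_y2=0.0, alpha_m=0.0))
    model._build(0)
    x_t, m, y, targets = model._batch(np.arange(4))
    code = model.latent_code(x_t, eps=_eps(4, 2))
    recon, *_ = model.elbo_terms(m, targets, y, code)
    code2 = model.latent_code(x_t, eps=_eps(4, 2))
    f = model.diva_loss(m, targets, y, code2)
    assert f.item() == pytest.approx(recon.item(), rel=1e-12)


def test_matched_posterior_prior_gives_zero_kl():
    mu = np.array([[0.3, -1.2]])
    logvar = np.array([[0.1, -0.4]])
    assert gaussian_kl(mu, logvar, mu, logvar) == pytest.approx(0.0, abs=1e-12)


def test_analytic_gaussian_kl_matches_monte_carlo(rng):
    mu_q, logvar_q = np.array([0.5, -0.3]), np.array([0.2, -0.8])
    mu_p, logvar_p = np.array([-0.1, 0.4]), np.array([-0.5, 0.3])
    analytic = gaussian_kl(mu_q, logvar_q, mu_p, logvar_p)
    n = 100_000
    z = mu_q + np.exp(0.5 * logvar_q) * rng.standard_normal((n, 2))

    def logpdf(z, mu, logvar):
        return (-0.5 * (np.log(2 * np.pi) + logvar + (z - mu) ** 2
                        / np.exp(logvar))).sum(axis=1)

    diffs = logpdf(z, mu_q, logvar_q) - logpdf(z, mu_p, logvar_p)
    mc, se = diffs.mean(), diffs.std(ddof=1) / np.sqrt(n)
    assert abs(analytic - mc) < 3 * se


def test_analytic_kls_are_non_negative(tiny_model):
    x_t, m, y, targets = tiny_model._batch(np.arange(4))
    code = tiny_model.latent_code(x_t, eps=_eps(4, 2))
    for value in tiny_model.analytic_kls(m, y, code).values():
        assert value >= 0.0


def test_image_targets_and_render_round_trip(small_dataset):
    imgs = np.stack([__import__("mirdescribe.encoding", fromlist=["encode_image"])
                     .encode_image(r)[0] for r in small_dataset[:30]])
    hcls, ccls, occ = image_targets(imgs)
    heights = np.where(occ, np.array(HEIGHTS)[hcls], 0)
    rendered = render_discrete(heights, ccls)
    assert np.array_equal(rendered, imgs)


def test_expected_decode_consistency(small_dataset):
    """One-hot height/color distributions reproduce the image exactly."""
    from mirdescribe.encoding import encode_image

    img, _ = encode_image(small_dataset[2])
    hcls, ccls, occ = image_targets(img[None])
    h_p = np.zeros((2, len(HEIGHTS), 100))
    c_p = np.zeros((2, 5, 100))
    for row in range(2):
        for col in range(100):
            h_p[row, hcls[0, row, col], col] = 1.0
            c_p[row, ccls[0, row, col], col] = 1.0
    assert np.array_equal(expected_image(h_p, c_p), img.astype(float))


def test_uniform_colors_spread_mass_equally():
    h_p = np.zeros((2, len(HEIGHTS), 100))
    h_p[:, 2, :] = 1.0  # height 3 everywhere
    c_p = np.full((2, 5, 100), 0.2)
    img = expected_image(h_p, c_p)
    assert np.allclose(img[:, :3, :], 0.2)
    assert np.allclose(img[:, 3:12, :], 0.0)


def test_decode_shapes(tiny_model):
    z = Tensor(np.zeros((3, 2)))
    h_logp, c_logp = tiny_model.decode(z, z, z)
    assert h_logp.shape == (3, 2, len(HEIGHTS), 100)
    assert c_logp.shape == (3, 2, 5, 100)
    assert np.allclose(np.exp(h_logp.data).sum(axis=2), 1.0, atol=1e-6)
    assert np.allclose(np.exp(c_logp.data).sum(axis=2), 1.0, atol=1e-6)


def test_untrained_conditional_generation_raises(tiny_model):
    from mirdescribe.vae.model import DivaVAEResults

    res = DivaVAEResults(tiny_model, history=None, seed=0)
    with pytest.raises(RuntimeError, match="not trained"):
        res.conditional_generate(tiny_model.images[0], np.ones(100))


def test_state_round_trip(tiny_model):
    blob = tiny_model.state_bytes()
    x_t, *_ = tiny_model._batch(np.arange(2))
    before = tiny_model.latent_code(x_t, eps=_eps(2, 2)).m.z.data.copy()
    for p in tiny_model.parameters():
        p.data = p.data + 0.1
    changed = tiny_model.latent_code(x_t, eps=_eps(2, 2)).m.z.data
    assert not np.allclose(before, changed)
    tiny_model.load_state_bytes(blob)
    after = tiny_model.latent_code(x_t, eps=_eps(2, 2)).m.z.data
    assert np.array_equal(before, after)


def test_full_preset_instantiates_and_evaluates():
    """Full-scale configuration (latent 64, 8 IAF blocks of hidden 1080)
    builds and produces a finite objective on a 2-record batch."""
    recs = generate_dataset(GeneratorConfig(n_samples=4, seed=5))
    model = DivaVAE.from_records(recs, ModelConfig.full())
    model._build(0)
    x_t, m, y, targets = model._batch(np.arange(2))
    eps = {k: np.zeros((2, 64)) for k in ("m", "y", "x")}
    code = model.latent_code(x_t, eps=eps)
    for space in (code.m, code.y, code.x):
        assert space.z.shape == (2, 64)
    f = model.diva_loss(m, targets, y, code)
    assert np.isfinite(f.item())


def test_fit_resume_keeps_current_weights():
    recs = generate_dataset(GeneratorConfig(n_samples=24, seed=6))
    model = DivaVAE.from_records(recs, ModelConfig.tiny(batch_size=8))
    model.fit(seed=0, epochs=1)
    before = [p.data.copy() for p in model.parameters()]
    model.fit(seed=1, epochs=0, resume=True)       # no steps: weights kept
    after = model.parameters()
    assert all(np.array_equal(a, b.data) for a, b in zip(before, after))
    model.fit(seed=1, epochs=0)                    # fresh fit re-initializes
    assert any(not np.array_equal(a, b.data)
               for a, b in zip(before, model.parameters()))
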