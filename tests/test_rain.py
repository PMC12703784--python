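"""Style VAE, reparameterized sampling and the four-term style-transfer loss."""

import numpy as np
import pytest

from swisseg.autodiff import Adam, Tensor
from swisseg.feature_statistics import ChannelStats, compute_channel_stats, moment_inject
from swisseg.rain import (
    LatentStyleDistribution,
    RainWeights,
    StyleVAE,
    content_loss,
    decode_style,
    encode_style,
    kl_loss,
    load_vae,
    rain_forward,
    rain_total_loss,
    reconstruction_loss,
    sample_latent,
    save_vae,
    style_loss,
)


@pytest.fixture
def vae(rng):
    return StyleVAE(n_channels=4, latent_dim=8, hidden_width=32, rng=rng)


def test_encode_deterministic_and_psi_positive(vae, rng):
    s = rng.standard_normal((3, 8)).astype(np.float32)
    d1, d2 = encode_style(vae, s), encode_style(vae, s)
    np.testing.assert_array_equal(d1.xi.data, d2.xi.data)
    assert (d1.psi.data > 0).all()


def test_encode_finite_for_large_inputs(vae, rng):
    for scale in (1.0, 100.0, 1000.0):
        s = scale * rng.standard_normal((2, 8)).astype(np.float32)
        d = encode_style(vae, s)
        assert np.isfinite(d.xi.data).all() and np.isfinite(d.psi.data).all()


def test_encode_width_mismatch_rejected(vae):
    with pytest.raises(ValueError):
        encode_style(vae, np.zeros((1, 6)))


def test_sample_latent_zero_noise_and_identity(rng):
    xi = rng.standard_normal((2, 5)).astype(np.float32)
    dist = LatentStyleDistribution(xi=Tensor(xi), log_var=Tensor(np.zeros((2, 5))))
    np.testing.assert_allclose(sample_latent(dist, np.zeros((2, 5))).data, xi)
    noise = rng.standard_normal((2, 5)).astype(np.float32)
    zero_mean = LatentStyleDistribution(xi=Tensor(np.zeros((2, 5))),
                                        log_var=Tensor(np.zeros((2, 5))))
    np.testing.assert_allclose(sample_latent(zero_mean, noise).data, noise)
    with pytest.raises(ValueError):
        sample_latent(dist, np.zeros((2, 4)))


def test_decode_sigma_block_nonnegative(vae, rng):
    z = 10.0 * rng.standard_normal((5, 8)).astype(np.float32)
    s_hat = decode_style(vae, z)
    assert (s_hat.data[:, 4:] >= 0).all()
    with pytest.raises(ValueError):
        decode_style(vae, np.zeros((1, 3)))


def test_kl_closed_form_values():
    std_normal = LatentStyleDistribution(xi=Tensor(np.zeros((1, 3))),
                                         log_var=Tensor(np.zeros((1, 3))))
    assert kl_loss(std_normal).item() == pytest.approx(0.0, abs=1e-7)
    shifted = LatentStyleDistribution(xi=Tensor(np.ones((1, 1))),
                                      log_var=Tensor(np.zeros((1, 1))))
    assert kl_loss(shifted).item() == pytest.approx(0.5, rel=1e-6)


def test_kl_nonnegative_random(rng):
    for _ in range(20):
        d = LatentStyleDistribution(
            xi=Tensor(rng.standard_normal((2, 6))),
            log_var=Tensor(rng.standard_normal((2, 6))))
        assert kl_loss(d).item() >= -1e-6


def test_reconstruction_loss_examples():
    assert reconstruction_loss(np.array([[1.0, 2.0]]),
                               np.array([[1.0, 2.0]])).item() == 0.0
    assert reconstruction_loss(np.array([[1.0, 2.0]]),
                               np.array([[1.0, 4.0]])).item() == pytest.approx(4.0)
    a, b = np.array([[1.0, 3.0]]), np.array([[2.0, 5.0]])
    assert reconstruction_loss(a, b).item() == pytest.approx(
        reconstruction_loss(b, a).item())


def test_content_loss_zero_cases_and_oracle(rng):
    f = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
    assert content_loss(f, f).item() == pytest.approx(0.0, abs=1e-8)
    t = ChannelStats(mu=rng.standard_normal((1, 2)), sigma=1.0 + rng.random((1, 2)))
    styled = moment_inject(f, t)
    assert content_loss(styled, f).item() == pytest.approx(0.0, abs=1e-5)

    # loop oracle on 2x2 maps
    a = rng.standard_normal((1, 1, 2, 2))
    b = rng.standard_normal((1, 1, 2, 2))

    def normed(x):
        mu, var = x.mean(), x.var()
        return (x - mu) / np.sqrt(var + 1e-10)

    expected = ((normed(a) - normed(b)) ** 2).mean()
    assert content_loss(a, b).item() == pytest.approx(expected, rel=1e-3)


def test_style_loss_examples(rng):
    f = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
    own = compute_channel_stats(f)
    assert style_loss(f, own).item() == pytest.approx(0.0, abs=1e-8)
    t = ChannelStats(mu=own.mu.data + 1.0, sigma=own.sigma.data + 2.0)
    # mu gap 1, sigma gap 2, C=1 -> (1 + 4) / 2
    assert style_loss(f, t).item() == pytest.approx(2.5, rel=1e-4)
    styled = moment_inject(f, t)
    assert style_loss(styled, t).item() == pytest.approx(0.0, abs=1e-5)


def test_rain_total_loss_arithmetic():
    only_content = RainWeights(lambda_content=1.0, lambda_s=0, lambda_kl=0,
                               lambda_rec=0)
    assert rain_total_loss(3.0, 9.0, 9.0, 9.0, only_content).item() == 3.0
    equal = RainWeights(lambda_content=1, lambda_s=1, lambda_kl=1, lambda_rec=1)
    assert rain_total_loss(1, 1, 1, 1, equal).item() == pytest.approx(4.0)
    paper = RainWeights()  # 2e-4, 1.0, 1.0, 5.0
    assert rain_total_loss(1, 1, 1, 1, paper).item() == pytest.approx(7.0002)
    with pytest.raises(ValueError):
        RainWeights(lambda_s=-1.0)


def test_rain_forward_shapes_and_errors(vae, rng):
    content = rng.standard_normal((3, 4, 6, 6)).astype(np.float32)
    style = rng.standard_normal((3, 4, 6, 6)).astype(np.float32)
    rf = rain_forward(vae, content, style, rng)
    assert rf.stylized.shape == content.shape
    assert rf.style_vec.shape == (3, 8)
    with pytest.raises(ValueError):
        rain_forward(vae, content, rng.standard_normal((3, 5, 6, 6)), rng)


def test_rain_forward_stochastic_dispersion(vae, rng):
    """Different noise draws yield different injected styles (stochasticity)."""
    content = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
    style = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
    sigmas = []
    for _ in range(30):
        rf = rain_forward(vae, content, style, rng)
        sigmas.append(compute_channel_stats(rf.stylized).sigma.data.ravel())
    spread = np.var(np.stack(sigmas), axis=0)
    assert (spread > 0).all()


def test_rain_loss_gradients_reach_vae_and_content(vae, rng):
    content = Tensor(rng.standard_normal((2, 4, 6, 6)), requires_grad=True)
    style = rng.standard_normal((2, 4, 6, 6)).astype(np.float32)
    rf = rain_forward(vae, content, style, rng)
    loss = rain_total_loss(
        content_loss(rf.stylized, content.detach()),
        style_loss(rf.stylized, compute_channel_stats(Tensor(style))),
        kl_loss(rf.dist),
        reconstruction_loss(rf.style_vec, rf.style_vec_hat),
        RainWeights())
    loss.backward()
    assert content.grad is not None and np.isfinite(content.grad).all()
    grads = [p.grad for p in vae.parameters()]
    assert all(g is not None and np.isfinite(g).all() for g in grads)
    assert any(np.abs(g).max() > 0 for g in grads)


def test_vae_checkpoint_roundtrip(vae, rng, tmp_path):
    s = rng.standard_normal((2, 8)).astype(np.float32)
    path = tmp_path / "vae.json"
    save_vae(vae, path)
    restored = load_vae(path)
    np.testing.assert_allclose(encode_style(restored, s).xi.data,
                               encode_style(vae, s).xi.data, atol=1e-6)
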