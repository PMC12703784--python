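"""Random adaptive instance normalization (RAIN): stochastic feature-space
style transfer through a variational autoencoder over style vectors.

A style vector s = [mu ; sigma] summarizes a feature map's appearance. The
Style VAE encodes s into a Gaussian latent posterior N(xi, psi^2), samples a
latent code with the reparameterization trick z = xi + psi * noise, and
decodes z back into a (possibly novel) style, which is injected into content
features by moment injection. Training balances four terms: content
preservation, style matching, a KL pull of the posterior toward N(0, I), and
style-vector reconstruction.

Content and style losses are defined in backbone feature space (no external
perceptual network): content loss compares instance-normalized maps, so it is
blind to channel moments by construction; style loss compares channel moments
only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .feature_statistics import (
    DEFAULT_EPS,
    ChannelStats,
    compute_channel_stats,
    make_style_vector,
    moment_inject,
    split_style_vector,
)
from .layers import Linear, Module

__all__ = [
    "LatentStyleDistribution",
    "RainWeights",
    "StyleVAE",
    "encode_style",
    "sample_latent",
    "decode_style",
    "kl_loss",
    "reconstruction_loss",
    "content_loss",
    "style_loss",
    "rain_total_loss",
    "rain_forward",
    "RainForward",
    "save_vae",
    "load_vae",
]


@dataclass
class LatentStyleDistribution:
    """Latent Gaussian posterior: mean ``xi`` and log-variance (B, D)."""

    xi: Tensor
    log_var: Tensor

    @property
    def psi(self) -> Tensor:
        """Latent standard deviation, structurally positive."""
        return (0.5 * self.log_var).exp()


@dataclass
class RainWeights:
    """Loss weights; defaults are the grid-searched training values."""

    lambda_content: float = 2e-4
    lambda_s: float = 1.0
    lambda_kl: float = 1.0
    lambda_rec: float = 5.0

    def __post_init__(self):
        for name in ("lambda_content", "lambda_s", "lambda_kl", "lambda_rec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


class StyleVAE(Module):
    """Fully connected style autoencoder: (B, 2C) -> N(xi, psi^2) -> (B, 2C)."""

    def __init__(self, n_channels: int, latent_dim: int = 64,
                 hidden_width: int = 256, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.n_channels = n_channels
        self.latent_dim = latent_dim
        self.hidden_width = hidden_width
        width = 2 * n_channels
        self.enc1 = Linear(width, hidden_width, rng)
        self.enc2 = Linear(hidden_width, hidden_width, rng)
        self.enc_out = Linear(hidden_width, 2 * latent_dim, rng)
        self.dec1 = Linear(latent_dim, hidden_width, rng)
        self.dec2 = Linear(hidden_width, hidden_width, rng)
        self.dec_out = Linear(hidden_width, width, rng)


def encode_style(vae: StyleVAE, s) -> LatentStyleDistribution:
    """Map a style vector to its latent posterior parameters."""
    s = s if isinstance(s, Tensor) else Tensor(s)
    if s.shape[1] != 2 * vae.n_channels:
        raise ValueError(
            f"style vector width {s.shape[1]} != encoder input {2 * vae.n_channels}")
    h = vae.enc2(vae.enc1(s).relu()).relu()
    out = vae.enc_out(h)
    D = vae.latent_dim
    # bound the log-variance smoothly so psi = exp(logvar/2) never overflows
    log_var = 10.0 * (out[:, D:] * 0.1).tanh()
    return LatentStyleDistribution(xi=out[:, :D], log_var=log_var)


def sample_latent(dist: LatentStyleDistribution, noise) -> Tensor:
    """Reparameterized draw z = xi + psi * noise."""
    noise = noise if isinstance(noise, Tensor) else Tensor(noise)
    if noise.shape != dist.xi.shape:
        raise ValueError(f"noise shape {noise.shape} != latent shape {dist.xi.shape}")
    return dist.xi + dist.psi * noise


def decode_style(vae: StyleVAE, z) -> Tensor:
    """Decode a latent code into a style vector; sigma block is softplus-positive."""
    z = z if isinstance(z, Tensor) else Tensor(z)
    if z.shape[1] != vae.latent_dim:
        raise ValueError(f"latent width {z.shape[1]} != {vae.latent_dim}")
    h = vae.dec2(vae.dec1(z).relu()).relu()
    raw = vae.dec_out(h)
    C = vae.n_channels
    return concat([raw[:, :C], raw[:, C:].softplus()], axis=1)


def kl_loss(dist: LatentStyleDistribution) -> Tensor:
    """KL(N(xi, psi^2) || N(0, I)), summed over latent dims, batch-averaged.

    Closed form: 1/2 sum_d (psi_d^2 + xi_d^2 - 1 - log psi_d^2).
    """
    psi2 = dist.log_var.exp()
    per_sample = 0.5 * (psi2 + dist.xi ** 2 - 1.0 - dist.log_var).sum(axis=1)
    return per_sample.mean()


def reconstruction_loss(s, s_hat) -> Tensor:
    """Squared Euclidean distance between style vectors, batch-averaged."""
    s = s if isinstance(s, Tensor) else Tensor(s)
    s_hat = s_hat if isinstance(s_hat, Tensor) else Tensor(s_hat)
    if s.shape != s_hat.shape:
        raise ValueError(f"style vector shapes differ: {s.shape} vs {s_hat.shape}")
    return ((s - s_hat) ** 2).sum(axis=1).mean()


def _instance_normalize(f: Tensor, eps: float) -> Tensor:
    st = compute_channel_stats(f, eps)
    B, C = st.shape
    return (f - st.mu.reshape(B, C, 1, 1)) / st.sigma.reshape(B, C, 1, 1)


def content_loss(f_styl, f_content, eps: float = DEFAULT_EPS) -> Tensor:
    """MSE between instance-normalized maps: invariant to moment injection."""
    f_styl = f_styl if isinstance(f_styl, Tensor) else Tensor(f_styl)
    f_content = f_content if isinstance(f_content, Tensor) else Tensor(f_content)
    if f_styl.shape != f_content.shape:
        raise ValueError(f"shape mismatch: {f_styl.shape} vs {f_content.shape}")
    return ((_instance_normalize(f_styl, eps)
             - _instance_normalize(f_content, eps)) ** 2).mean()


def style_loss(f_styl, target: ChannelStats, eps: float = DEFAULT_EPS) -> Tensor:
    """MSE between the stylized map's channel moments and the target moments."""
    st = compute_channel_stats(f_styl, eps)
    if st.shape != target.shape:
        raise ValueError(f"stats shape mismatch: {st.shape} vs {target.shape}")
    d_mu = (st.mu - target.mu) ** 2
    d_sigma = (st.sigma - target.sigma) ** 2
    return concat([d_mu, d_sigma], axis=1).mean()


def rain_total_loss(lc, ls, lkl, lrec, w: RainWeights) -> Tensor:
    """Weighted sum: lambda_content*Lc + lambda_s*Ls + lambda_kl*Lkl + lambda_rec*Lrec."""
    terms = [lc, ls, lkl, lrec]
    terms = [t if isinstance(t, Tensor) else Tensor(t) for t in terms]
    return (w.lambda_content * terms[0] + w.lambda_s * terms[1]
            + w.lambda_kl * terms[2] + w.lambda_rec * terms[3])


@dataclass
class RainForward:
    """All intermediates of one stochastic stylization pass."""

    stylized: Tensor
    dist: LatentStyleDistribution
    style_vec: Tensor
    style_vec_hat: Tensor


def rain_forward(vae: StyleVAE, content_f, style_f, rng: np.random.Generator,
                 eps: float = DEFAULT_EPS, noise_scale: float = 1.0) -> RainForward:
    """Extract style, encode, sample, decode, inject: one RAIN pass.

    ``noise_scale`` = 0 collapses the draw to the posterior mean.
    """
    content_f = content_f if isinstance(content_f, Tensor) else Tensor(content_f)
    style_f = style_f if isinstance(style_f, Tensor) else Tensor(style_f)
    if content_f.shape[1] != style_f.shape[1]:
        raise ValueError(
            f"channel mismatch: content C={content_f.shape[1]}, style C={style_f.shape[1]}")
    s = make_style_vector(compute_channel_stats(style_f, eps))
    dist = encode_style(vae, s)
    noise = noise_scale * rng.standard_normal(dist.xi.shape).astype(np.float32)
    z = sample_latent(dist, noise)
    s_hat = decode_style(vae, z)
    target = split_style_vector(s_hat)
    # broadcast style batch onto content batch if the two differ
    Bc = content_f.shape[0]
    if target.mu.shape[0] != Bc:
        if target.mu.shape[0] == 1:
            ones = Tensor(np.ones((Bc, 1), dtype=np.float32))
            target = ChannelStats(mu=ones @ target.mu, sigma=ones @ target.sigma)
        else:
            raise ValueError(
                f"style batch {target.mu.shape[0]} incompatible with content batch {Bc}")
    stylized = moment_inject(content_f, target, eps)
    return RainForward(stylized=stylized, dist=dist, style_vec=s, style_vec_hat=s_hat)


def save_vae(vae: StyleVAE, path) -> None:
    """Serialize VAE hyperparameters and weights to a JSON checkpoint."""
    payload = {
        "n_channels": vae.n_channels,
        "latent_dim": vae.latent_dim,
        "hidden_width": vae.hidden_width,
        "arrays": [a.tolist() for a in vae.state_arrays()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_vae(path) -> StyleVAE:
    with open(path) as fh:
        payload = json.load(fh)
    vae = StyleVAE(payload["n_channels"], payload["latent_dim"],
                   payload["hidden_width"], rng=np.random.default_rng(0))
    vae.load_state_arrays([np.asarray(a, dtype=np.float32) for a in payload["arrays"]])
    return vae
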