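"""Channel-wise instance statistics and moment-injection transforms.

These are the shared primitives of the framework: every style operation —
stochastic style transfer and adversarial feature normalization alike — is a
composition of (i) per-sample, per-channel spatial moments and (ii) the
AdaIN-form transform that replaces one feature map's moments with another's.

Statistics are always taken per sample and per channel over the spatial
dimensions only (instance normalization convention), with the population
variance (divide by H*W) and a small epsilon added inside the square root so
constant channels receive sigma = eps instead of zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "ChannelStats",
    "compute_channel_stats",
    "make_style_vector",
    "split_style_vector",
    "moment_inject",
    "DEFAULT_EPS",
]

DEFAULT_EPS = 1e-5


@dataclass
class ChannelStats:
    """Per-sample, per-channel mean and standard deviation, each (B, C)."""

    mu: Tensor
    sigma: Tensor

    def __post_init__(self):
        if not isinstance(self.mu, Tensor):
            self.mu = Tensor(self.mu)
        if not isinstance(self.sigma, Tensor):
            self.sigma = Tensor(self.sigma)
        if self.mu.shape != self.sigma.shape:
            raise ValueError(
                f"mu shape {self.mu.shape} != sigma shape {self.sigma.shape}")
        if np.any(self.sigma.data < 0):
            raise ValueError("sigma must be nonnegative")

    @property
    def shape(self):
        return self.mu.shape


def _as_feature_tensor(f) -> Tensor:
    t = f if isinstance(f, Tensor) else Tensor(f)
    if t.ndim != 4:
        raise ValueError(f"feature map must be 4-D (B, C, H, W), got shape {t.shape}")
    bad = ~np.isfinite(t.data)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite feature value at index {idx}")
    return t


def compute_channel_stats(f, eps: float = DEFAULT_EPS) -> ChannelStats:
    """Spatial mean and stabilized standard deviation of a (B, C, H, W) map.

    sigma = sqrt(population_variance + eps^2), so a constant channel gets
    sigma exactly eps. Invariant to any spatial permutation of the input.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    f = _as_feature_tensor(f)
    B, C = f.shape[:2]
    mu = f.mean(axis=(2, 3))
    mu_keep = mu.reshape(B, C, 1, 1)
    var = ((f - mu_keep) ** 2).mean(axis=(2, 3))
    sigma = (var + eps ** 2) ** 0.5
    return ChannelStats(mu=mu, sigma=sigma)


def make_style_vector(stats: ChannelStats) -> Tensor:
    """Concatenate [mu ; sigma] per sample into a (B, 2C) style vector."""
    return concat([stats.mu, stats.sigma], axis=1)


def split_style_vector(s) -> ChannelStats:
    """Inverse of :func:`make_style_vector`: split a (B, 2C) vector."""
    s = s if isinstance(s, Tensor) else Tensor(s)
    if s.ndim != 2 or s.shape[1] % 2 != 0:
        raise ValueError(f"style vector must be (B, 2C), got shape {s.shape}")
    C = s.shape[1] // 2
    return ChannelStats(mu=s[:, :C], sigma=s[:, C:])


def moment_inject(content, target: ChannelStats, eps: float = DEFAULT_EPS) -> Tensor:
    """Replace the channel moments of ``content`` with ``target``'s (AdaIN form).

    out = target.sigma * (content - mu(content)) / sigma(content) + target.mu

    The output's per-channel moments equal the target's whenever the content's
    spatial variance dominates eps^2.
    """
    content = _as_feature_tensor(content)
    B, C = content.shape[:2]
    if target.shape != (B, C):
        raise ValueError(
            f"target stats shape {target.shape} incompatible with content (B, C)=({B}, {C})")
    own = compute_channel_stats(content, eps)
    normalized = (content - own.mu.reshape(B, C, 1, 1)) / own.sigma.reshape(B, C, 1, 1)
    return target.sigma.reshape(B, C, 1, 1) * normalized + target.mu.reshape(B, C, 1, 1)
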