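"""Dynamic gradient back-propagation (DGB): adversarial feature normalization.

A pair of learnable per-channel statistics (mu_adv, sigma_adv) is injected
into the backbone features by the same AdaIN-form transform used for style
transfer. A gradient reversal layer (GRL) sits between those statistics and
the task loss, so that one ordinary descent step on the whole graph performs
descent on the segmentation model but *ascent* on the adversarial statistics
— the statistics chase feature distributions the current model finds hard,
expanding the style manifold seen during training. sigma_adv is stored as a
log so it stays structurally positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor
from .autodiff import grl as _grl
from .feature_statistics import DEFAULT_EPS, compute_channel_stats

__all__ = [
    "AdversarialStats",
    "GrlConfig",
    "adversarial_normalize",
    "grl",
    "dgb_step",
    "consistency_loss",
]


@dataclass
class GrlConfig:
    """Gradient reversal coefficient, update step size and its schedule."""

    lambda_grl: float = 1.0
    phi: float = 0.01  # style perturbation rate (the adversarial learning rate)
    schedule: str = "constant"  # constant | linear-ramp
    ramp_fraction: float = 0.1

    def __post_init__(self):
        if self.lambda_grl < 0:
            raise ValueError("lambda_grl must be nonnegative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.schedule not in ("constant", "linear-ramp"):
            raise ValueError(f"unknown schedule {self.schedule!r}")

    def lambda_at(self, iteration: int, n_iterations: int) -> float:
        """Effective coefficient at a training iteration."""
        if self.schedule == "constant":
            return self.lambda_grl
        ramp_len = max(1, int(self.ramp_fraction * n_iterations))
        return self.lambda_grl * min(1.0, iteration / ramp_len)


class AdversarialStats:
    """Learnable per-channel adversarial moments; sigma kept positive via log."""

    def __init__(self, n_channels: int, mu_init=None, log_sigma_init=None):
        self.n_channels = n_channels
        mu = np.zeros(n_channels) if mu_init is None else np.asarray(mu_init)
        ls = np.zeros(n_channels) if log_sigma_init is None else np.asarray(log_sigma_init)
        if mu.shape != (n_channels,) or ls.shape != (n_channels,):
            raise ValueError("adversarial stats must be 1-D of length n_channels")
        self.mu_adv = Parameter(mu)
        self.log_sigma_adv = Parameter(ls)

    @property
    def sigma_adv(self) -> np.ndarray:
        return np.exp(self.log_sigma_adv.data)

    def parameters(self):
        return [self.mu_adv, self.log_sigma_adv]

    def copy(self) -> "AdversarialStats":
        return AdversarialStats(self.n_channels, self.mu_adv.data.copy(),
                                self.log_sigma_adv.data.copy())

    @classmethod
    def from_features(cls, f, eps: float = DEFAULT_EPS) -> "AdversarialStats":
        """Initialize at the source style distribution of a feature batch.

        The iterative adversarial update starts from the Gaussian the source
        features actually follow, so early perturbations stay on-manifold.
        """
        st = compute_channel_stats(f, eps)
        mu = st.mu.data.mean(axis=0)
        sigma = st.sigma.data.mean(axis=0)
        return cls(mu.shape[0], mu, np.log(np.maximum(sigma, eps)))


def grl(x, lambda_grl: float) -> Tensor:
    """Identity forward; upstream gradient is -lambda_grl times the downstream one."""
    return _grl(x, lambda_grl)


def adversarial_normalize(x, adv: AdversarialStats, eps: float = DEFAULT_EPS,
                          lambda_grl: float | None = None) -> Tensor:
    """Inject the learnable adversarial moments into per-sample normalized features.

    x_t = sigma_adv * (x - mu(x)) / sigma(x) + mu_adv

    If ``lambda_grl`` is given, a gradient reversal layer is placed between
    the adversarial parameters and the output, so a single descent step on the
    total loss moves them in the task-loss *ascent* direction.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    if x.ndim != 4:
        raise ValueError(f"expected (B, C, H, W), got shape {x.shape}")
    B, C = x.shape[:2]
    if adv.n_channels != C:
        raise ValueError(f"adversarial stats for {adv.n_channels} channels, input has {C}")
    st = compute_channel_stats(x, eps)
    normalized = (x - st.mu.reshape(B, C, 1, 1)) / st.sigma.reshape(B, C, 1, 1)
    mu_a: Tensor = adv.mu_adv
    sig_a: Tensor = adv.log_sigma_adv.exp()
    if lambda_grl is not None:
        mu_a = _grl(mu_a, lambda_grl)
        sig_a = _grl(sig_a, lambda_grl)
    return sig_a.reshape(1, C, 1, 1) * normalized + mu_a.reshape(1, C, 1, 1)


def dgb_step(adv: AdversarialStats, task_grad_mu, task_grad_log_sigma,
             cfg: GrlConfig) -> AdversarialStats:
    """One ascent step of the adversarial statistics along the task gradient.

    new = old + phi * lambda_grl * dL_task/d(stats): the reversed-gradient
    update that makes the statistics adversarial to the current model.
    """
    g_mu = np.asarray(task_grad_mu, dtype=np.float64)
    g_ls = np.asarray(task_grad_log_sigma, dtype=np.float64)
    if not (np.all(np.isfinite(g_mu)) and np.all(np.isfinite(g_ls))):
        raise ValueError("non-finite gradient passed to dgb_step")
    step = cfg.phi * cfg.lambda_grl
    return AdversarialStats(
        adv.n_channels,
        adv.mu_adv.data + step * g_mu.astype(np.float32),
        adv.log_sigma_adv.data + step * g_ls.astype(np.float32),
    )


def consistency_loss(z_batch) -> Tensor:
    """Mean squared distance of batch feature vectors from their batch mean.

    (1/N) sum_i ||z_i - z_bar||^2 — zero iff all vectors coincide, invariant
    to reordering; algebraically the per-coordinate variance summed over width.
    """
    z = z_batch if isinstance(z_batch, Tensor) else Tensor(np.asarray(z_batch))
    if z.ndim != 2:
        raise ValueError(f"expected a (N, D) batch of feature vectors, got {z.shape}")
    z_bar = z.mean(axis=0, keepdims=True)
    return ((z - z_bar) ** 2).sum(axis=1).mean()
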