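"""Reconstruction and adversarial losses.

Each modality gets the loss matched to its data regime: focal loss for the
extremely 0/1-imbalanced binary peak matrix, a negative-binomial negative
log-likelihood for overdispersed RNA counts, mean squared error for
CLR-scale protein, and a Wasserstein critic objective for adversarial
pre-training.  All reconstruction losses reduce by the mean over matrix
elements, keeping magnitudes comparable across feature dimensions.

Gradient companions (``*_grad``) return d(loss)/d(prediction) including the
mean-reduction factor, for use by the training loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

logger = logging.getLogger(__name__)

#: probabilities are clamped into [P_CLAMP, 1-P_CLAMP] before any log
P_CLAMP = 1e-7


@dataclass
class FocalParams:
    """alpha weights class 1 (1-alpha weights class 0); gamma >= 0 focuses
    the loss on hard examples.  ``alpha=None`` disables class weighting
    (alpha_t identically 1), in which case gamma = 0 recovers the plain
    binary cross-entropy exactly.  Defaults are the values used for every
    reported ATAC-generation result."""

    alpha: float | None = 0.93
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class NBParamsBatch:
    """Negative-binomial mean/dispersion for a batch (cells x genes)."""

    mu: np.ndarray
    theta: np.ndarray
    eps: float = 1e-8

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if (self.mu <= 0).any():
            raise ValueError("mu must be strictly positive")
        if (self.theta <= 0).any():
            raise ValueError("theta must be strictly positive")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")


def _clamp_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p <= 0).any() or (p >= 1).any():
        logger.debug("clamping probabilities into [%g, %g]", P_CLAMP, 1 - P_CLAMP)
    return np.clip(p, P_CLAMP, 1.0 - P_CLAMP)


def _pt(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return np.where(y == 1, p, 1.0 - p)


def binary_cross_entropy(p, y) -> float:
    """-log(pt) with pt = p where y = 1 and 1-p where y = 0; mean-reduced."""
    p = _clamp_p(p)
    return float(np.mean(-np.log(_pt(p, y))))


def focal_loss(p, y, params: FocalParams = FocalParams()) -> float:
    """-alpha_t (1-pt)^gamma log(pt), mean-reduced.

    With gamma = 0 and alpha chosen so alpha_t is identically 1 this is
    exactly the binary cross-entropy.
    """
    p = _clamp_p(p)
    y = np.asarray(y, dtype=float)
    pt = _pt(p, y)
    if params.alpha is None:
        alpha_t = 1.0
    else:
        alpha_t = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    return float(np.mean(-alpha_t * (1.0 - pt) ** params.gamma * np.log(pt)))


def focal_loss_grad(p, y, params: FocalParams = FocalParams()) -> np.ndarray:
    """d(mean focal loss)/dp, elementwise; zero where p was clamped."""
    p_raw = np.asarray(p, dtype=float)
    p = _clamp_p(p_raw)
    y = np.asarray(y, dtype=float)
    pt = _pt(p, y)
    if params.alpha is None:
        alpha_t = 1.0
    else:
        alpha_t = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    one_m = 1.0 - pt
    # d/dpt of -alpha_t (1-pt)^g log pt
    if params.gamma == 0:
        dpt = -alpha_t / pt
    else:
        dpt = alpha_t * (
            params.gamma * one_m ** (params.gamma - 1.0) * np.log(pt) - one_m ** params.gamma / pt
        )
    dp = np.where(y == 1, dpt, -dpt)  # dpt/dp = +1 for y=1, -1 for y=0
    dp = np.where((p_raw > P_CLAMP) & (p_raw < 1.0 - P_CLAMP), dp, 0.0)
    return dp / p.size


def nb_nll(x, params: NBParamsBatch) -> float:
    """Negative-binomial negative log-likelihood, mean-reduced.

    Per element, with mean mu, dispersion theta and stability constant eps:

        -theta [log(theta+eps) - log(theta+mu)]
        - x [log(mu+eps) - log(theta+mu)]
        - lgamma(x+theta) + lgamma(x+1) + lgamma(theta+eps)

    At eps = 0 this is exactly -log NB(x; mu, theta).  Non-negative real x is
    accepted (the factorial generalises through the gamma function), which
    lets size-normalised counts serve as targets.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    mu, theta, eps = params.mu, params.theta, params.eps
    log_tm = np.log(theta + mu)
    ll_terms = (
        -theta * (np.log(theta + eps) - log_tm)
        - x * (np.log(mu + eps) - log_tm)
        - gammaln(x + theta)
        + gammaln(x + 1.0)
        + gammaln(theta + eps)
    )
    return float(np.mean(ll_terms))


def nb_nll_grad(x, params: NBParamsBatch) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the mean-reduced NB NLL w.r.t. mu and theta."""
    x = np.asarray(x, dtype=float)
    mu, theta, eps = params.mu, params.theta, params.eps
    inv_tm = 1.0 / (theta + mu)
    d_mu = (theta + x) * inv_tm - x / (mu + eps)
    d_theta = (
        -np.log(theta + eps)
        - theta / (theta + eps)
        + np.log(theta + mu)
        + (theta + x) * inv_tm
        - digamma(x + theta)
        + digamma(theta + eps)
    )
    n = x.size
    return d_mu / n, d_theta / n


def wasserstein_critic_losses(
    critic_real_scores, critic_fake_scores
) -> tuple[float, float]:
    """WGAN objectives from critic scores.

    critic_loss = mean(fake) - mean(real): minimising it drives the critic to
    score real above generated, i.e. to maximise the estimated Wasserstein
    distance.  generator_loss = -mean(fake): the generator raises its
    samples' scores.  Both unbounded; no sigmoid anywhere.
    """
    real = np.asarray(critic_real_scores, dtype=float)
    fake = np.asarray(critic_fake_scores, dtype=float)
    if real.size == 0 or fake.size == 0:
        raise ValueError("score batches must be nonempty")
    critic_loss = float(fake.mean() - real.mean())
    generator_loss = float(-fake.mean())
    return critic_loss, generator_loss


def mse_loss(pred, target) -> float:
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


def mse_grad(pred, target) -> np.ndarray:
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    return 2.0 * (pred - target) / pred.size
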