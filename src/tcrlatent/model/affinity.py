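"""Unnormalized binding affinity between a CDR3B embedding and an epitope Gaussian.

The affinity p(x, y) is the density of the CDR3B latent point f(x) under the
epitope's diagonal Gaussian N(mu(y), diag(sigma(y))):

    p(x, y) = exp(-1/2 (f - mu)^T Sigma^{-1} (f - mu)) / sqrt((2 pi)^k |Sigma|)

With k = 32 the density underflows in linear space, so the log form

    log p = -1/2 [ sum_j ((f_j - mu_j)^2 / sigma_j + ln sigma_j) + k ln(2 pi) ]

is used everywhere internally.
"""

from __future__ import annotations

import math

import numpy as np

LOG_2PI = math.log(2.0 * math.pi)


def log_affinity(f: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Log unnormalized affinity for a single (f, mu, sigma) triple."""
    f = np.asarray(f, float)
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma entries must be strictly positive")
    d = f - mu
    return float(-0.5 * (np.sum(d * d / sigma + np.log(sigma)) + f.size * LOG_2PI))


def unnormalized_affinity(f: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Linear-space affinity; may underflow to 0 for large k."""
    return math.exp(log_affinity(f, mu, sigma))


def log_affinity_batch(F: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log affinities of rows of ``F`` (n, k) against one Gaussian (k,)."""
    if np.any(sigma <= 0):
        raise ValueError("sigma entries must be strictly positive")
    D = F - mu[None, :]
    k = F.shape[1]
    return -0.5 * (np.sum(D * D / sigma[None, :], axis=1)
                   + np.sum(np.log(sigma)) + k * LOG_2PI)


def nll_loss(F: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Mean negative log affinity over paired rows of F and (mu, sigma)."""
    D = F - mu
    k = F.shape[1]
    per_pair = 0.5 * (np.sum(D * D / sigma + np.log(sigma), axis=1) + k * LOG_2PI)
    return float(per_pair.mean())


def nll_loss_grad(F: np.ndarray, mu: np.ndarray, sigma: np.ndarray):
    """Mean NLL over paired rows plus gradients w.r.t. F, mu and sigma."""
    n, k = F.shape
    D = F - mu
    inv = 1.0 / sigma
    loss = float(
        (0.5 * (np.sum(D * D * inv + np.log(sigma), axis=1) + k * LOG_2PI)).mean()
    )
    gF = D * inv / n
    g_mu = -gF
    g_sigma = 0.5 * (inv - D * D * inv * inv) / n
    return loss, gF, g_mu, g_sigma
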