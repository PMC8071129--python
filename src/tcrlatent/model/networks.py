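"""The CDR3B embedding network and the epitope mapping network.

The CDR3B embedding network maps an encoded CDR3B matrix (20 x 6) to a point
f(x) in a k-dimensional latent space (k = 32 by default): two 1-D
convolutions over the 20 positions (6 -> 32 -> 64 channels, kernel 3, ReLU)
followed by a position-preserving flatten and a dense layer to k. Flattening
rather than pooling keeps motif detectors tied to their sequence positions,
which matters both for classification of position-specific motifs and for
the interpretability of the affinity landscape.

The epitope mapping network maps an encoded epitope matrix (10 x 6) to the
parameters of a diagonal Gaussian over the same latent space: one 1-D
convolution (6 -> 32 channels, kernel 3, ReLU), global max-pooling, and two
dense heads producing mu(y) and a pre-variance vector; the variance is
sigma(y) = softplus(pre) + variance_floor, guaranteeing strict positivity.
"""

from __future__ import annotations

import numpy as np

from .nn import (Adam, Conv1d, Dense, Flatten, GlobalMaxPool, ReLU, Sequential,
                 sigmoid, softplus)

DEFAULT_LATENT_DIM = 32
DEFAULT_VARIANCE_FLOOR = 0.1


class Cdr3bEmbedder:
    def __init__(self, latent_dim: int = DEFAULT_LATENT_DIM,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.latent_dim = latent_dim
        # position-preserving read-out: the conv stack is flattened, not
        # max-pooled, so motif detectors stay tied to sequence positions
        self.net = Sequential(
            Conv1d(6, 32, 3, rng),
            ReLU(),
            Conv1d(32, 64, 3, rng),
            ReLU(),
            Flatten(),
            Dense(16 * 64, latent_dim, rng),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 20, 6) -> (B, k) embeddings."""
        out = self.net.forward(x)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite CDR3B embedding")
        return out

    def backward(self, g: np.ndarray) -> None:
        self.net.backward(g)

    @property
    def params(self):
        return self.net.params


class EpitopeMapper:
    def __init__(self, latent_dim: int = DEFAULT_LATENT_DIM,
                 variance_floor: float = DEFAULT_VARIANCE_FLOOR,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.latent_dim = latent_dim
        self.variance_floor = variance_floor
        self.trunk = Sequential(
            Conv1d(6, 32, 3, rng),
            ReLU(),
            GlobalMaxPool(),
        )
        self.head_mu = Dense(32, latent_dim, rng)
        self.head_pre_sigma = Dense(32, latent_dim, rng)
        self._pre_sigma: np.ndarray | None = None

    def forward(self, y: np.ndarray):
        """(B, 10, 6) -> (mu (B, k), sigma (B, k)), sigma >= variance_floor."""
        h = self.trunk.forward(y)
        mu = self.head_mu.forward(h)
        pre = self.head_pre_sigma.forward(h)
        self._pre_sigma = pre
        sigma = softplus(pre) + self.variance_floor
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
            raise FloatingPointError("non-finite epitope Gaussian parameters")
        return mu, sigma

    def backward(self, g_mu: np.ndarray, g_sigma: np.ndarray) -> None:
        g_pre = g_sigma * sigmoid(self._pre_sigma)  # d softplus = sigmoid
        gh = self.head_mu.backward(g_mu) + self.head_pre_sigma.backward(g_pre)
        self.trunk.backward(gh)

    @property
    def params(self):
        return self.trunk.params + self.head_mu.params + self.head_pre_sigma.params


def collect_params(embedder: Cdr3bEmbedder, mapper: EpitopeMapper):
    return embedder.params + mapper.params


def make_optimizer(embedder: Cdr3bEmbedder, mapper: EpitopeMapper,
                   lr: float = 1e-3) -> Adam:
    return Adam(collect_params(embedder, mapper), lr=lr)
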