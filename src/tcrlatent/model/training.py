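"""Joint training of the Triplet and Modal Alignment networks.

Both objectives share the CDR3B embedding network: per minibatch, all valid
triplets are extracted for the batch-all Triplet Loss, the positive (CDR3B,
epitope) pairs feed the Gaussian negative log likelihood, and the combined
loss  L = L_triplet + lambda * L_nll  is minimized by Adam. Ambient negatives
participate only as triplet negatives (they have no binding epitope for the
likelihood term). The training set is reshuffled every epoch; minibatch size
defaults to 128. Everything is reproducible from ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ..encoding import encode_batch, default_atchley_table
from .affinity import log_affinity_batch, nll_loss_grad
from .networks import (
    Cdr3bEmbedder,
    EpitopeMapper,
    DEFAULT_LATENT_DIM,
    DEFAULT_VARIANCE_FLOOR,
    make_optimizer,
)
from .triplets import AMBIENT_LABEL, batch_all_triplet_loss_grad


@dataclass
class ModelConfig:
    latent_dim: int = DEFAULT_LATENT_DIM
    triplet_margin: float = 1.0
    loss_weight: float = 1.0  # lambda balancing NLL against Triplet Loss
    minibatch_size: int = 128
    epochs: int = 50
    variance_floor: float = DEFAULT_VARIANCE_FLOOR
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    input_noise: float = 0.05  # sd of Gaussian jitter on real-residue factors
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


class TrainedModel:
    """A trained (embedder, mapper) pair exposing affinity scoring."""

    def __init__(self, embedder: Cdr3bEmbedder, mapper: EpitopeMapper,
                 seen_epitopes, config: ModelConfig, loss_trace=None):
        self.embedder = embedder
        self.mapper = mapper
        self.seen_epitopes = list(seen_epitopes)
        self.config = config
        self.loss_trace = list(loss_trace) if loss_trace is not None else []
        self._gaussian_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def embed(self, cdr3bs) -> np.ndarray:
        """Latent embeddings f(x) for a list of CDR3B strings."""
        return self.embedder.forward(encode_batch(cdr3bs, "cdr3b"))

    def embed_encoded(self, X: np.ndarray) -> np.ndarray:
        if X.ndim == 2:
            X = X[None, :, :]
        return self.embedder.forward(X)

    def epitope_gaussian(self, epitope: str):
        """(mu, sigma) of the epitope's latent Gaussian (cached)."""
        if epitope not in self._gaussian_cache:
            Y = encode_batch([epitope], "epitope")
            mu, sigma = self.mapper.forward(Y)
            self._gaussian_cache[epitope] = (mu[0], sigma[0])
        return self._gaussian_cache[epitope]

    def log_affinity(self, cdr3b: str, epitope: str) -> float:
        return float(self.log_affinity_many([cdr3b], epitope)[0])

    def log_affinity_many(self, cdr3bs, epitope: str) -> np.ndarray:
        mu, sigma = self.epitope_gaussian(epitope)
        F = self.embed(cdr3bs)
        return log_affinity_batch(F, mu, sigma)

    def log_affinity_encoded(self, X: np.ndarray, epitope: str) -> np.ndarray:
        """Log affinities for pre-encoded CDR3B matrices (n, 20, 6)."""
        mu, sigma = self.epitope_gaussian(epitope)
        F = self.embed_encoded(X)
        return log_affinity_batch(F, mu, sigma)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        params = self.embedder.params + self.mapper.params
        arrays = {f"param_{i}": p.value for i, p in enumerate(params)}
        meta = {
            "config": asdict(self.config),
            "seen_epitopes": self.seen_epitopes,
            "loss_trace": self.loss_trace,
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        config = ModelConfig(**meta["config"])
        rng = np.random.default_rng(config.rng_seed)
        embedder = Cdr3bEmbedder(config.latent_dim, rng)
        mapper = EpitopeMapper(config.latent_dim, config.variance_floor, rng)
        params = embedder.params + mapper.params
        for i, p in enumerate(params):
            p.value[...] = data[f"param_{i}"]
        return cls(embedder, mapper, meta["seen_epitopes"], config,
                   meta["loss_trace"])


def train(split, config: ModelConfig) -> TrainedModel:
    """Train on an :class:`~tcrlatent.datasets.AssembledSplit`.

    Raises ``RuntimeError`` with the loss trace attached if the combined loss
    becomes non-finite.
    """
    rng = np.random.default_rng(config.rng_seed)
    embedder = Cdr3bEmbedder(config.latent_dim, rng)
    mapper = EpitopeMapper(config.latent_dim, config.variance_floor, rng)
    optimizer = make_optimizer(embedder, mapper, lr=config.learning_rate)
    optimizer.weight_decay = config.weight_decay

    seen = list(split.seen_epitopes)
    class_index = {e: i for i, e in enumerate(seen)}
    table = default_atchley_table()

    seqs = list(split.train_pairs["cdr3b"]) + list(split.train_negatives)
    labels = np.array(
        [class_index[e] for e in split.train_pairs["epitope"]]
        + [AMBIENT_LABEL] * len(split.train_negatives)
    )
    unique_seqs = sorted(set(seqs))
    seq_index = {s: i for i, s in enumerate(unique_seqs)}
    X_all = encode_batch(unique_seqs, "cdr3b", table)
    x_of = np.array([seq_index[s] for s in seqs])
    Y_epitopes = encode_batch(seen, "epitope", table)

    n = len(seqs)
    trace = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.minibatch_size):
            batch = order[start:start + config.minibatch_size]
            if len(batch) < 2:
                continue
            Xb = X_all[x_of[batch]]
            if config.input_noise > 0:
                Xb = Xb.copy()
                real = Xb[:, :, 5] > 0
                Xb[:, :, :5] += (config.input_noise
                                 * rng.standard_normal(Xb[:, :, :5].shape)
                                 * real[:, :, None])
            yb = labels[batch]
            optimizer.zero_grad()

            F = embedder.forward(Xb)
            t_loss, dF, _ = batch_all_triplet_loss_grad(
                F, yb, config.triplet_margin
            )

            pos = np.flatnonzero(yb != AMBIENT_LABEL)
            nll = 0.0
            if len(pos) > 0:
                mu_all, sigma_all = mapper.forward(Y_epitopes)
                cls = yb[pos]
                nll, gF_pos, g_mu_pairs, g_sigma_pairs = nll_loss_grad(
                    F[pos], mu_all[cls], sigma_all[cls]
                )
                lam = config.loss_weight
                dF[pos] += lam * gF_pos
                g_mu = np.zeros_like(mu_all)
                g_sigma = np.zeros_like(sigma_all)
                np.add.at(g_mu, cls, lam * g_mu_pairs)
                np.add.at(g_sigma, cls, lam * g_sigma_pairs)
                mapper.backward(g_mu, g_sigma)

            embedder.backward(dF)
            optimizer.step()
            loss = t_loss + config.loss_weight * nll
            if not np.isfinite(loss):
                err = RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
                err.loss_trace = trace
                raise err
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))

    return TrainedModel(embedder, mapper, seen, config, trace)
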