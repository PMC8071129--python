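"""Triplet extraction and Triplet Loss over latent CDR3B embeddings.

A valid triplet (anchor, positive, negative) pairs two distinct records of the
same epitope class with any record of a different class or of the ambient
negative set; ambient records never serve as anchor or positive. The loss is
the batch-all hinge

    mean over valid triplets of max(0, d(f_a, f_p) - d(f_a, f_n) + margin)

with Euclidean latent distance d. ``batch_all_triplet_loss_grad`` evaluates
the same quantity and its gradient in O(B^3) boolean work plus O(B^2 k)
arithmetic, by counting, for each ordered record pair, the number of active
triplets in which it appears as (anchor, positive) or (anchor, negative).
"""

from __future__ import annotations

import numpy as np

AMBIENT_LABEL = -1
DEFAULT_MARGIN = 1.0
_EPS = 1e-12


def extract_valid_triplets(labels) -> np.ndarray:
    """All valid (anchor, positive, negative) index triples for ``labels``.

    ``labels`` are integer class codes with ``AMBIENT_LABEL`` (-1) marking
    ambient negatives. Returns an (n_triplets, 3) integer array; empty batches
    yield an empty array.
    """
    labels = np.asarray(labels)
    valid = _valid_mask(labels)
    idx = np.argwhere(valid)
    return idx.reshape(-1, 3)


def _valid_mask(labels: np.ndarray) -> np.ndarray:
    n = labels.size
    is_pos = labels != AMBIENT_LABEL
    same = labels[:, None] == labels[None, :]
    anchor_positive = same & is_pos[:, None] & is_pos[None, :]
    anchor_positive &= ~np.eye(n, dtype=bool)
    diff = labels[:, None] != labels[None, :]
    return anchor_positive[:, :, None] & diff[:, None, :]


def pairwise_distances(F: np.ndarray) -> np.ndarray:
    sq = np.sum(F * F, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (F @ F.T)
    np.maximum(D2, 0.0, out=D2)
    return np.sqrt(D2)


def triplet_loss(F: np.ndarray, triplets: np.ndarray,
                 margin: float = DEFAULT_MARGIN) -> float:
    """Mean hinge loss over explicitly listed triplets of rows of ``F``."""
    if len(triplets) == 0:
        raise ValueError("no triplets supplied")
    a, p, n = triplets[:, 0], triplets[:, 1], triplets[:, 2]
    d_ap = np.linalg.norm(F[a] - F[p], axis=1)
    d_an = np.linalg.norm(F[a] - F[n], axis=1)
    return float(np.maximum(0.0, d_ap - d_an + margin).mean())


def batch_all_triplet_loss_grad(F: np.ndarray, labels,
                                margin: float = DEFAULT_MARGIN):
    """Batch-all triplet loss and its gradient w.r.t. the embeddings ``F``.

    Returns ``(loss, grad, n_valid)``; with no valid triplets the loss and
    gradient are zero. Coincident embeddings (upsampled duplicates) get a zero
    subgradient for their distance term.
    """
    labels = np.asarray(labels)
    valid = _valid_mask(labels)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(F), 0
    D = pairwise_distances(F)
    hinge_pos = (D[:, :, None] - D[:, None, :] + margin) > 0
    active = valid & hinge_pos
    A = active.sum(axis=2).astype(float)  # (a, p) -> active negative count
    B = active.sum(axis=1).astype(float)  # (a, n) -> active positive count
    n_active = float(active.sum())
    loss = ((A * D).sum() - (B * D).sum() + margin * n_active) / n_valid

    W = A - B  # ordered-pair weight of the d(i, j) term
    C = W + W.T
    G = np.where(D > _EPS, C / np.where(D > _EPS, D, 1.0), 0.0)
    grad = (G.sum(axis=1)[:, None] * F - G @ F) / n_valid
    return float(loss), grad, n_valid
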