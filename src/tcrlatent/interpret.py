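"""Maximum-entropy MCMC interpretation of the trained binding model.

With the epitope and CDR3B length fixed, a Metropolis chain samples CDR3B
sequence space biased toward high unnormalized binding affinity: proposals
mutate a uniformly chosen inner position (the conserved terminal C and F are
never touched) to a uniformly chosen different residue, and are accepted with
probability min(1, (p'/p)^beta), evaluated in log space. The stationary law
is p^beta / sum p^beta over the fixed-length sequence space. Batteries of
runs started from the top-affinity seeds are summarized by per-position
amino-acid frequency matrices (PFMs), clustered by Jensen-Shannon divergence,
ranked by uniqueness against alternative epitopes, converted to biochemical
(Atchley-factor) matrices, and scored by position-wise KL divergence from the
uniform residue distribution -- the model's salience signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .encoding import AMINO_ACIDS, AtchleyTable, default_atchley_table, encode_sequence

logger = logging.getLogger(__name__)

N_AA = len(AMINO_ACIDS)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

DEFAULT_STEPS = 20_000
DEFAULT_N_SEEDS = 40
DEFAULT_RUNS_PER_SEED = 5
EDGE_EXCLUSION = 4  # leading/trailing positions dropped in biochem/salience analyses

# Inverse temperatures used in the original analyses, keyed by epitope, for
# the motif battery and for the structure-matched battery respectively.
MOTIF_BETAS = {"GILGFVFTL": 2.8, "NLVPMVATV": 2.8,
               "GLCTLVAML": 2.0, "ELAGIGILTV": 1.6}
STRUCTURE_BETAS = {"GILGFVFTL": 1.7, "NLVPMVATV": 1.7,
                   "GLCTLVAML": 1.7, "ELAGIGILTV": 1.3}


def seq_to_indices(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX[a] for a in seq], dtype=np.uint8)


def indices_to_seq(idx) -> str:
    return "".join(AMINO_ACIDS[i] for i in idx)


@dataclass
class MCMCRun:
    """One Metropolis chain; ``samples`` holds the state at every step as
    residue indices (shape (steps, L))."""

    epitope: str
    length: int
    seed_sequence: str
    beta: float
    steps: int
    samples: np.ndarray
    rng_seed: int

    def sample_strings(self):
        return [indices_to_seq(row) for row in self.samples]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Row-stochastic (L x 20) per-position residue frequencies."""

    freqs: np.ndarray
    n_samples: int

    def __post_init__(self):
        rows = self.freqs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("PFM rows must sum to 1")

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.freqs, columns=list(AMINO_ACIDS))
        df.index = np.arange(1, len(df) + 1)
        df.index.name = "position"
        df.to_csv(path, sep="\t")


def select_seeds(model, epitope: str, length: int, pool,
                 n_seeds: int = DEFAULT_N_SEEDS):
    """Top ``n_seeds`` pool sequences of the given length by log affinity.

    Ties break by string order; a pool smaller than ``n_seeds`` is used whole
    with a warning (desk-scale fixtures may be small).
    """
    candidates = sorted({s for s in pool if len(s) == length})
    if not candidates:
        raise ValueError(f"no pool sequences of length {length}")
    if len(candidates) < n_seeds:
        logger.warning("seed pool has only %d sequences (requested %d)",
                       len(candidates), n_seeds)
    scores = model.log_affinity_many(candidates, epitope)
    order = np.lexsort((candidates, -scores))
    return [candidates[i] for i in order[:n_seeds]]


def mcmc_sample(model, epitope: str, seed_sequence: str, beta: float,
                steps: int = DEFAULT_STEPS, rng_seed: int = 0) -> MCMCRun:
    """Run one Metropolis chain from ``seed_sequence``.

    The proposal picks a uniform inner position (2..L-1, 1-based) and a
    uniform replacement among the other 19 residues; acceptance is
    min(1, exp(beta * (log p' - log p))). The post-decision state is recorded
    at every step (rejections repeat the current state); there is no burn-in.
    """
    if seed_sequence[0] != "C" or seed_sequence[-1] != "F":
        raise ValueError("seed must be a proper CDR3B (C...F)")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    L = len(seed_sequence)
    if L < 3:
        raise ValueError("sequence too short to have inner positions")
    rng = np.random.default_rng(rng_seed)
    state = seq_to_indices(seed_sequence)
    X = encode_sequence(seed_sequence, "cdr3b").values.copy()
    table_matrix = default_atchley_table().matrix()

    cache: dict[bytes, float] = {}

    def score(idx: np.ndarray, Xenc: np.ndarray) -> float:
        key = idx.tobytes()
        if key not in cache:
            cache[key] = float(model.log_affinity_encoded(Xenc, epitope)[0])
        return cache[key]

    logp = score(state, X)
    samples = np.empty((steps, L), dtype=np.uint8)
    inner = rng.integers(1, L - 1, size=steps)
    residue_draw = rng.integers(0, N_AA - 1, size=steps)
    accept_u = rng.random(steps)
    for t in range(steps):
        pos = int(inner[t])
        old = int(state[pos])
        new = int(residue_draw[t])
        if new >= old:
            new += 1  # uniform over the 19 alternatives
        state[pos] = new
        old_row = X[pos, :5].copy()
        X[pos, :5] = table_matrix[new]
        logp_new = score(state, X) if beta > 0 else 0.0
        if beta == 0 or accept_u[t] < np.exp(min(0.0, beta * (logp_new - logp))):
            logp = logp_new
        else:
            state[pos] = old
            X[pos, :5] = old_row
        samples[t] = state
    return MCMCRun(epitope=epitope, length=L, seed_sequence=seed_sequence,
                   beta=beta, steps=steps, samples=samples, rng_seed=rng_seed)


def run_battery(model, epitope: str, length: int, pool,
                n_seeds: int = DEFAULT_N_SEEDS,
                runs_per_seed: int = DEFAULT_RUNS_PER_SEED,
                beta: float = 2.0, steps: int = DEFAULT_STEPS,
                rng_seed: int = 0):
    """Independent runs per seed plus the pooled representative run.

    Returns ``(individual_runs, representative_run)``; the representative run
    is the concatenation of all individual runs' samples.
    """
    seeds = select_seeds(model, epitope, length, pool, n_seeds)
    runs = []
    counter = 0
    for seed_seq in seeds:
        for _ in range(runs_per_seed):
            runs.append(
                mcmc_sample(model, epitope, seed_seq, beta, steps,
                            rng_seed=(rng_seed * 100_003 + counter) % (2**31))
            )
            counter += 1
    pooled = MCMCRun(
        epitope=epitope, length=length, seed_sequence="",
        beta=beta, steps=sum(r.n_samples for r in runs),
        samples=np.concatenate([r.samples for r in runs]),
        rng_seed=rng_seed,
    )
    return runs, pooled


def empirical_pfm(run: MCMCRun) -> PositionFrequencyMatrix:
    """Per-position residue frequencies over all samples of ``run``."""
    if run.n_samples == 0:
        raise ValueError("empty run")
    L = run.samples.shape[1]
    counts = np.zeros((L, N_AA))
    for j in range(L):
        counts[j] = np.bincount(run.samples[:, j], minlength=N_AA)
    return PositionFrequencyMatrix(counts / run.n_samples, run.n_samples)


def pool_pfms(pfms) -> PositionFrequencyMatrix:
    """Sample-count-weighted mean of PFMs (the pooled-run identity)."""
    total = sum(p.n_samples for p in pfms)
    freqs = sum(p.freqs * p.n_samples for p in pfms) / total
    return PositionFrequencyMatrix(freqs, total)


def _kl(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise KL(p || q), natural log; 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / q), 0.0)
    return terms.sum(axis=1)


def jsd_profile(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-position Jensen-Shannon divergence between row-stochastic matrices."""
    m = 0.5 * (a + b)
    return 0.5 * _kl(a, m) + 0.5 * _kl(b, m)


def jsd_between_runs(a: PositionFrequencyMatrix,
                     b: PositionFrequencyMatrix) -> float:
    """Mean over positions of the per-position JSD (natural log, <= ln 2)."""
    if a.freqs.shape != b.freqs.shape:
        raise ValueError("PFM shapes differ")
    return float(jsd_profile(a.freqs, b.freqs).mean())


def _silhouette_cluster(dist: np.ndarray, q_range) -> tuple[int, np.ndarray]:
    """Complete-linkage clustering; Q chosen at the global silhouette maximum
    (smallest Q on ties). Returns (Q, labels)."""
    n = dist.shape[0]
    Z = linkage(squareform(dist, checks=False), method="complete")
    best_q, best_score, best_labels = None, -np.inf, None
    for q in q_range:
        if q < 2 or q > n - 1:
            continue
        labels = fcluster(Z, t=q, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dist, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_q, best_score, best_labels = q, score, labels
    if best_labels is None:
        logger.warning("degenerate distances: falling back to a single cluster")
        return 1, np.ones(n, dtype=int)
    return best_q, best_labels


def cluster_runs(runs, q_range=range(2, 41)):
    """Cluster runs by pairwise JSD of their PFMs; pool each cluster.

    Returns ``(chosen_Q, labels, cluster_runs)`` where ``cluster_runs`` maps
    cluster label -> pooled :class:`MCMCRun`.
    """
    if len(runs) < 3:
        raise ValueError("need at least 3 runs to cluster")
    pfms = [empirical_pfm(r) for r in runs]
    n = len(runs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = jsd_between_runs(pfms[i], pfms[j])
    q, labels = _silhouette_cluster(dist, q_range)
    clusters = {}
    for lab in np.unique(labels):
        members = [runs[i] for i in np.flatnonzero(labels == lab)]
        clusters[int(lab)] = MCMCRun(
            epitope=runs[0].epitope, length=runs[0].length, seed_sequence="",
            beta=runs[0].beta, steps=sum(m.n_samples for m in members),
            samples=np.concatenate([m.samples for m in members]),
            rng_seed=runs[0].rng_seed,
        )
    return q, labels, clusters


def uniqueness_score(cluster_pfm: PositionFrequencyMatrix,
                     alternative_pfms) -> float:
    """Mean JSD between a cluster PFM and the representative PFMs of the
    alternative epitopes (same CDR3B length). Higher = more unique."""
    alternative_pfms = list(alternative_pfms)
    if not alternative_pfms:
        raise ValueError("at least one alternative representative is required")
    return float(np.mean([jsd_between_runs(cluster_pfm, alt)
                          for alt in alternative_pfms]))


def analyzed_positions(length: int,
                       edge_exclusion: int = EDGE_EXCLUSION) -> np.ndarray:
    """0-based inner positions with ``edge_exclusion`` trimmed from each end."""
    pos = np.arange(edge_exclusion, length - edge_exclusion)
    if pos.size == 0:
        raise ValueError("no positions remain after edge exclusion")
    return pos


def biochem_matrix(pfm: PositionFrequencyMatrix,
                   table: AtchleyTable | None = None,
                   positions=None) -> np.ndarray:
    """5 x L' matrix of frequency-weighted scaled factor scores.

    Column j is sum_aa freq(position_j, aa) * factor_vector(aa); entries are
    convex combinations of scaled factors, hence in [0, 1]. ``positions``
    defaults to the inner positions with four residues trimmed at each end.
    """
    if table is None:
        table = default_atchley_table()
    if positions is None:
        positions = analyzed_positions(pfm.freqs.shape[0])
    return (pfm.freqs[positions] @ table.matrix()).T


def frobenius_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def cluster_matrices(matrices, r_range=range(2, 41)):
    """Cluster biochemical matrices by Frobenius distance (complete linkage).

    Returns ``(chosen_R, labels, cluster_means)`` with cluster label ->
    elementwise-mean matrix.
    """
    matrices = [np.asarray(m) for m in matrices]
    if len(matrices) < 3:
        raise ValueError("need at least 3 matrices to cluster")
    n = len(matrices)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = frobenius_distance(matrices[i], matrices[j])
    r, labels = _silhouette_cluster(dist, r_range)
    means = {
        int(lab): np.mean([matrices[i] for i in np.flatnonzero(labels == lab)],
                          axis=0)
        for lab in np.unique(labels)
    }
    return r, labels, means


def matrix_uniqueness(cluster_matrix: np.ndarray, alternative_matrices) -> float:
    """Mean Frobenius distance to alternative epitopes' representative matrices."""
    alternative_matrices = list(alternative_matrices)
    if not alternative_matrices:
        raise ValueError("at least one alternative representative is required")
    return float(np.mean([frobenius_distance(cluster_matrix, m)
                          for m in alternative_matrices]))


def position_kl(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-position KL divergence from the uniform residue distribution.

    KL(row || uniform_20) = sum_a f_a ln(20 f_a); zero frequencies contribute
    0. Uniform rows give 0; one-hot rows give ln 20.
    """
    uniform = np.full(N_AA, 1.0 / N_AA)
    return _kl(pfm.freqs, uniform[None, :])
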