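"""Residue-level CDR3B-epitope distance analysis of TCR-pMHC structures.

For each crystal structure (resolution finer than 3 A), the pairwise distance
between every CDR3B-region residue and every epitope residue is computed --
by default the minimum over heavy-atom pairs, with a C-alpha option.
Matrices sharing an epitope and CDR3B length are aggregated elementwise;
per CDR3B position the median distance to the epitope is taken, excluding the
four leading and four trailing positions (the conserved flanks). MCMC runs
matched to the same (epitope, length) provide the salience signal: positions
are ranked by KL divergence in decreasing order (rank 0 = most salient), the
ranks are summed over runs and z-scored, and the pooled (salience rank,
median distance) points are tested for Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .interpret import EDGE_EXCLUSION, analyzed_positions, empirical_pfm, position_kl

logger = logging.getLogger(__name__)

RESOLUTION_CUTOFF = 3.0


@dataclass
class StructureDistanceMatrix:
    """(L_cdr3b x L_epitope) residue distance table in Angstroms."""

    distances: np.ndarray
    structure_id: str
    epitope: str
    cdr3b: str
    resolution: float


@dataclass
class SalienceProfile:
    """Per-position KL values and the standardized summed salience rank."""

    positions: np.ndarray  # 0-based CDR3B positions analyzed
    kl_values: np.ndarray  # (n_runs, n_positions)
    salience_rank: np.ndarray  # z-scored summed rank per position


def _residue_coords(residue, atom_mode: str) -> np.ndarray:
    coords = []
    for atom in residue:
        if atom.altloc not in ("", "\x00", " ", "A"):  # first altloc only
            continue
        if atom.is_hydrogen():
            continue
        if atom_mode == "ca" and atom.name != "CA":
            continue
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return np.asarray(coords)


def residue_distance_matrix(
    path,
    cdr3b_chain: str,
    cdr3b_range: tuple[int, int],
    epitope_chain: str,
    structure_id: str | None = None,
    epitope: str = "",
    cdr3b: str = "",
    atom_mode: str = "heavy",
    resolution_cutoff: float = RESOLUTION_CUTOFF,
) -> StructureDistanceMatrix:
    """Distance matrix between a CDR3B region and an epitope chain.

    ``cdr3b_range`` gives inclusive author residue numbers on
    ``cdr3b_chain``. ``atom_mode`` is "heavy" (minimum over heavy-atom pairs)
    or "ca" (C-alpha only). Residues missing all relevant atoms are flagged
    NaN and excluded from downstream aggregation. Structures at or above the
    resolution cutoff are rejected.
    """
    structure = gemmi.read_structure(str(path))
    resolution = structure.resolution
    if resolution and resolution >= resolution_cutoff:
        raise ValueError(
            f"resolution {resolution:.2f} A fails the < {resolution_cutoff} A filter"
        )
    model = structure[0]
    chain_c = model[cdr3b_chain]
    chain_e = model[epitope_chain]
    lo, hi = cdr3b_range
    cdr_res = [r for r in chain_c if lo <= r.seqid.num <= hi]
    epi_res = list(chain_e)
    if not cdr_res or not epi_res:
        raise ValueError("CDR3B region or epitope chain resolved no residues")
    dist = np.full((len(cdr_res), len(epi_res)), np.nan)
    cdr_coords = [_residue_coords(r, atom_mode) for r in cdr_res]
    epi_coords = [_residue_coords(r, atom_mode) for r in epi_res]
    for i, ci in enumerate(cdr_coords):
        if ci.size == 0:
            continue
        for j, ej in enumerate(epi_coords):
            if ej.size == 0:
                continue
            diffs = ci[:, None, :] - ej[None, :, :]
            dist[i, j] = np.sqrt((diffs ** 2).sum(axis=2)).min()
    return StructureDistanceMatrix(
        distances=dist,
        structure_id=structure_id or str(path),
        epitope=epitope,
        cdr3b=cdr3b,
        resolution=float(resolution) if resolution else float("nan"),
    )


def aggregate_distance_matrices(matrices) -> np.ndarray:
    """Elementwise mean over structures (NaN entries excluded per cell)."""
    shapes = {m.distances.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across structures: {shapes}")
    stacked = np.stack([m.distances for m in matrices])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def median_epitope_distance(aggregated: np.ndarray,
                            edge_exclusion: int = EDGE_EXCLUSION):
    """Per-CDR3B-position median distance to the epitope.

    Returns ``(positions, medians)`` with the first and last
    ``edge_exclusion`` CDR3B positions excluded.
    """
    L = aggregated.shape[0]
    positions = analyzed_positions(L, edge_exclusion)
    medians = np.array([np.nanmedian(aggregated[p]) for p in positions])
    return positions, medians


def salience_rank(runs, edge_exclusion: int = EDGE_EXCLUSION) -> SalienceProfile:
    """Standardized summed KL rank over MCMC runs matched to one structure.

    Per run, the analyzed positions are ranked by KL divergence in decreasing
    order (rank 0 = highest KL, average ranks on ties); the ranks are summed
    over runs and z-scored across positions.
    """
    if not runs:
        raise ValueError("at least one matched MCMC run is required")
    L = runs[0].length
    positions = analyzed_positions(L, edge_exclusion)
    kl_rows = []
    rank_sum = np.zeros(positions.size)
    for run in runs:
        kl = position_kl(empirical_pfm(run))[positions]
        kl_rows.append(kl)
        rank_sum += rankdata(-kl, method="average") - 1.0
    sd = rank_sum.std()
    if sd == 0:
        standardized = np.zeros_like(rank_sum)
    else:
        standardized = (rank_sum - rank_sum.mean()) / sd
    return SalienceProfile(
        positions=positions,
        kl_values=np.asarray(kl_rows),
        salience_rank=standardized,
    )


def correlate_salience_distance(profiles_and_medians):
    """Pearson correlation between salience rank and median epitope distance.

    ``profiles_and_medians`` is an iterable of (SalienceProfile, medians)
    pairs, one per structure; points are pooled across structures and
    positions. Returns ``(r, p, table)`` with the scatter table as a
    DataFrame. Zero variance on either axis is an error.
    """
    xs, ys, rows = [], [], []
    for k, (profile, medians) in enumerate(profiles_and_medians):
        if len(medians) != profile.salience_rank.size:
            raise ValueError("profile and median lengths differ")
        for pos, s, d in zip(profile.positions, profile.salience_rank, medians):
            xs.append(s)
            ys.append(d)
            rows.append({"structure_index": k, "position": int(pos) + 1,
                         "salience_rank": float(s), "median_distance": float(d)})
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if xs.size < 3:
        raise ValueError("need at least 3 pooled points")
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero variance on one axis; correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), pd.DataFrame(rows)
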