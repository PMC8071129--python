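"""Numeric encoding of CDR3B and epitope sequences.

Each amino acid is mapped to a six-dimensional row vector: the five Atchley
factor scores (a factor-analytic summary of 54 physicochemical descriptors)
min-max scaled to [0, 1], followed by a real-residue indicator of 1.
Sequences are padded with placeholder rows (0.5, 0.5, 0.5, 0.5, 0.5, 0) to a
fixed row count -- 20 for CDR3B sequences, 10 for epitopes -- so that every
sequence becomes a fixed-shape matrix suitable for convolutional input.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_FACTORS = 5
CDR3B_PAD_LENGTH = 20
EPITOPE_PAD_LENGTH = 10
PLACEHOLDER_ROW = np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.0])

_PAD_LENGTHS = {"cdr3b": CDR3B_PAD_LENGTH, "epitope": EPITOPE_PAD_LENGTH}


class EncodingError(ValueError):
    """Raised when a sequence or factor table violates the encoding contract."""


@dataclass(frozen=True)
class AtchleyTable:
    """Min-max-scaled Atchley factor scores for the 20 proteinogenic residues.

    ``entries`` maps each one-letter residue code to a 5-vector with every
    component in [0, 1]; per factor column, the minimum over residues is
    exactly 0 and the maximum exactly 1.
    """

    entries: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.entries)
        if missing:
            raise EncodingError(f"missing amino acids: {sorted(missing)}")

    def vector(self, letter: str) -> np.ndarray:
        return self.entries[letter]

    def matrix(self) -> np.ndarray:
        """20x5 array with rows in ``AMINO_ACIDS`` order."""
        return np.stack([self.entries[a] for a in AMINO_ACIDS])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.matrix(),
            index=list(AMINO_ACIDS),
            columns=[f"factor{i + 1}" for i in range(N_FACTORS)],
        )
        df.index.name = "amino_acid"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "AtchleyTable":
        df = pd.read_csv(path, sep="\t", index_col="amino_acid")
        return cls({a: df.loc[a].to_numpy(float) for a in df.index})


def build_atchley_table(raw_scores: pd.DataFrame) -> AtchleyTable:
    """Min-max scale a 20x5 table of raw factor scores, column by column.

    ``raw_scores`` must be indexed by one-letter residue code with five factor
    columns. Each column is rescaled as (v - min) / (max - min).
    """
    for letter in AMINO_ACIDS:
        if letter not in raw_scores.index:
            raise EncodingError(f"raw factor table missing amino acid {letter!r}")
    if raw_scores.shape[1] != N_FACTORS:
        raise EncodingError(
            f"expected {N_FACTORS} factor columns, got {raw_scores.shape[1]}"
        )
    values = raw_scores.loc[list(AMINO_ACIDS)].to_numpy(float)
    for j, col in enumerate(raw_scores.columns):
        if not np.all(np.isfinite(values[:, j])):
            raise EncodingError(f"non-finite score in factor column {col!r}")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    scaled = (values - lo) / (hi - lo)
    return AtchleyTable({a: scaled[i] for i, a in enumerate(AMINO_ACIDS)})


def default_atchley_table() -> AtchleyTable:
    """The scaled table built from the published 2005 factor scores."""
    ref = importlib.resources.files("tcrlatent.data") / "atchley_factors_2005.tsv"
    with importlib.resources.as_file(ref) as path:
        raw = pd.read_csv(path, sep="\t", index_col="amino_acid")
    return build_atchley_table(raw)


@dataclass(frozen=True)
class SequenceMatrix:
    """Fixed-shape encoded sequence: (pad_length x 6) values plus true length."""

    values: np.ndarray
    length: int
    kind: str

    @property
    def pad_length(self) -> int:
        return _PAD_LENGTHS[self.kind]


def validate_sequence(seq: str, kind: str) -> None:
    if not seq:
        raise EncodingError("empty sequence")
    for i, letter in enumerate(seq):
        if letter not in AMINO_ACIDS:
            raise EncodingError(
                f"non-proteinogenic letter {letter!r} at position {i + 1}"
            )
    pad = _PAD_LENGTHS[kind]
    if len(seq) > pad:
        raise EncodingError(
            f"{kind} sequence of length {len(seq)} exceeds the {pad}-residue limit"
        )


def encode_sequence(seq: str, kind: str, table: AtchleyTable | None = None) -> SequenceMatrix:
    """Encode ``seq`` as a (pad_length x 6) matrix of scaled factor scores.

    Row i of a real residue is (5 scaled factors, 1); rows beyond the sequence
    length are the placeholder row (0.5 x5, 0).
    """
    if table is None:
        table = _shared_table()
    validate_sequence(seq, kind)
    pad = _PAD_LENGTHS[kind]
    values = np.tile(PLACEHOLDER_ROW, (pad, 1))
    for i, letter in enumerate(seq):
        values[i, :N_FACTORS] = table.vector(letter)
        values[i, N_FACTORS] = 1.0
    return SequenceMatrix(values=values, length=len(seq), kind=kind)


def decode_sequence(
    m: SequenceMatrix, table: AtchleyTable | None = None, atol: float = 1e-9
) -> str:
    """Invert :func:`encode_sequence` by nearest-row lookup (tolerance ``atol``)."""
    if table is None:
        table = _shared_table()
    if m.length < 1:
        raise EncodingError("matrix encodes no real residues")
    letters = []
    ref = table.matrix()
    for i in range(m.length):
        row = m.values[i, :N_FACTORS]
        diffs = np.abs(ref - row).max(axis=1)
        j = int(np.argmin(diffs))
        if diffs[j] > atol:
            raise EncodingError(f"row {i + 1} matches no amino acid within {atol}")
        letters.append(AMINO_ACIDS[j])
    return "".join(letters)


def encode_batch(seqs, kind: str, table: AtchleyTable | None = None) -> np.ndarray:
    """Stack encodings of ``seqs`` into an (n, pad_length, 6) array."""
    if table is None:
        table = _shared_table()
    return np.stack([encode_sequence(s, kind, table).values for s in seqs])


_TABLE_CACHE: list[AtchleyTable] = []


def _shared_table() -> AtchleyTable:
    if not _TABLE_CACHE:
        _TABLE_CACHE.append(default_atchley_table())
    return _TABLE_CACHE[0]
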