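"""Assembly of training and test sets from positive pairs and ambient negatives.

The positive binding dataset is a table of (CDR3B, epitope) pairs curated from
public databases; the negative set is an ambient repertoire of CDR3B sequences
assumed not to bind any seen epitope. For a chosen seen-epitope set, each
epitope class is split 80-20 on its distinct CDR3B strings, both sides are
independently upsampled with replacement to the majority-class size, 0.5 x N
ambient negatives (N = post-upsampling positive train size) are added to the
training set, and a fixed number of further negatives to the test set. All
sampling is seeded and train/test negative draws are disjoint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import AMINO_ACIDS, CDR3B_PAD_LENGTH, EPITOPE_PAD_LENGTH

logger = logging.getLogger(__name__)

AMBIENT_LABEL = -1


def _is_proteinogenic(seq: str) -> bool:
    return bool(seq) and all(c in AMINO_ACIDS for c in seq)


def filter_positive_pairs(
    records: pd.DataFrame,
    host: str = "human",
    hla: str = "HLA-A*02:01",
) -> pd.DataFrame:
    """Apply the curation filters to raw database exports.

    Keeps rows with the requested host and HLA restriction, proteinogenic
    sequences, CDR3B length <= 20 and epitope length <= 10; merges sources and
    drops duplicate (cdr3b, epitope) pairs. Malformed rows are logged and
    dropped.
    """
    df = records.copy()
    n_raw = len(df)
    required = {"cdr3b", "epitope"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    df = df.dropna(subset=["cdr3b", "epitope"])
    if "host" in df.columns:
        df = df[df["host"].str.lower() == host.lower()]
    if "hla" in df.columns:
        df = df[df["hla"].str.upper().str.replace(" ", "")
                == hla.upper().replace(" ", "")]
    ok = (
        df["cdr3b"].map(_is_proteinogenic)
        & df["epitope"].map(_is_proteinogenic)
        & (df["cdr3b"].str.len() <= CDR3B_PAD_LENGTH)
        & (df["epitope"].str.len() <= EPITOPE_PAD_LENGTH)
    )
    df = df[ok]
    df = df.drop_duplicates(subset=["cdr3b", "epitope"]).reset_index(drop=True)
    logger.info("filter_positive_pairs: kept %d of %d records", len(df), n_raw)
    return df


def filter_negative_repertoire(sequences, positives: pd.DataFrame) -> list[str]:
    """Filter an ambient CDR3B repertoire for use as the negative set.

    Keeps proteinogenic sequences of length <= 20 with the conserved leading C
    and trailing F, excluding any string present among the positive CDR3Bs.
    """
    positive_strings = set(positives["cdr3b"])
    kept = []
    seen = set()
    for seq in sequences:
        if seq in seen:
            continue
        seen.add(seq)
        if not _is_proteinogenic(seq) or len(seq) > CDR3B_PAD_LENGTH:
            continue
        if seq[0] != "C" or seq[-1] != "F":
            continue
        if seq in positive_strings:
            continue
        kept.append(seq)
    return kept


@dataclass
class AssembledSplit:
    """One train/test split with upsampled positives and injected negatives."""

    train_pairs: pd.DataFrame
    test_pairs: pd.DataFrame
    train_negatives: list[str]
    test_negatives: list[str]
    seen_epitopes: list[str]
    rng_seed: int

    def to_json_sidecar(self, path) -> None:
        meta = {
            "rng_seed": self.rng_seed,
            "seen_epitopes": self.seen_epitopes,
            "n_train_pairs": int(len(self.train_pairs)),
            "n_test_pairs": int(len(self.test_pairs)),
            "n_train_negatives": len(self.train_negatives),
            "n_test_negatives": len(self.test_negatives),
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def _upsample(groups: dict[str, list[str]], rng: np.random.Generator) -> pd.DataFrame:
    """Upsample each class with replacement to the majority-class size."""
    target = max(len(v) for v in groups.values())
    rows = []
    for epitope in sorted(groups):
        members = sorted(groups[epitope])
        chosen = list(members)
        deficit = target - len(members)
        if deficit > 0:
            chosen += [members[i] for i in rng.integers(0, len(members), deficit)]
        rows.extend((c, epitope) for c in chosen)
    return pd.DataFrame(rows, columns=["cdr3b", "epitope"])


def _split_distinct(
    positives: pd.DataFrame,
    seen_epitopes,
    train_fraction: float,
    rng: np.random.Generator,
):
    """Per-epitope shuffled split of distinct CDR3B strings."""
    train_groups: dict[str, list[str]] = {}
    test_groups: dict[str, list[str]] = {}
    for epitope in seen_epitopes:
        members = sorted(set(positives.loc[positives["epitope"] == epitope, "cdr3b"]))
        if len(members) < 2:
            raise ValueError(f"epitope {epitope!r} has fewer than 2 distinct CDR3Bs")
        perm = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_groups[epitope] = [members[i] for i in perm[:n_train]]
        test_groups[epitope] = [members[i] for i in perm[n_train:]]
    return train_groups, test_groups


def _draw_negatives(
    negatives, n_train: int, n_test: int, rng: np.random.Generator
):
    pool = sorted(set(negatives))
    if n_train + n_test > len(pool):
        raise ValueError(
            f"negative pool too small: need {n_train + n_test}, have {len(pool)}"
        )
    perm = rng.permutation(len(pool))
    train_neg = [pool[i] for i in perm[:n_train]]
    test_neg = [pool[i] for i in perm[n_train:n_train + n_test]]
    return train_neg, test_neg


def _assemble_from_groups(
    train_groups,
    test_groups,
    negatives,
    seen_epitopes,
    test_negative_count: int,
    rng_seed: int,
    rng: np.random.Generator,
) -> AssembledSplit:
    train_pairs = _upsample(train_groups, rng)
    test_pairs = _upsample(test_groups, rng)
    n_train_neg = int(round(0.5 * len(train_pairs)))
    train_neg, test_neg = _draw_negatives(
        negatives, n_train_neg, test_negative_count, rng
    )
    return AssembledSplit(
        train_pairs=train_pairs,
        test_pairs=test_pairs,
        train_negatives=train_neg,
        test_negatives=test_neg,
        seen_epitopes=list(seen_epitopes),
        rng_seed=rng_seed,
    )


def assemble_split(
    positives: pd.DataFrame,
    negatives,
    seen_epitopes,
    train_fraction: float = 0.8,
    test_negative_count: int = 10_000,
    rng_seed: int = 0,
) -> AssembledSplit:
    """Build one seeded train/test split per the upsampling protocol.

    Distinct CDR3Bs of each seen epitope are split ``train_fraction`` /
    (1 - ``train_fraction``); each side is upsampled independently with
    replacement until all classes match the majority class; 0.5 x N ambient
    negatives (N = upsampled positive train size) go into training and
    ``test_negative_count`` further negatives (disjoint draw) into the test
    set.
    """
    rng = np.random.default_rng(rng_seed)
    train_groups, test_groups = _split_distinct(
        positives, seen_epitopes, train_fraction, rng
    )
    return _assemble_from_groups(
        train_groups, test_groups, negatives, seen_epitopes,
        test_negative_count, rng_seed, rng,
    )


def kfold_splits(
    positives: pd.DataFrame,
    negatives,
    seen_epitopes,
    folds: int = 5,
    test_negative_count: int = 10_000,
    rng_seed: int = 0,
) -> list[AssembledSplit]:
    """Per-epitope k-fold partition of distinct CDR3Bs; one split per fold.

    Each fold serves once as the test side; upsampling and negative injection
    follow :func:`assemble_split`. The union of test folds covers every
    distinct positive CDR3B exactly once per epitope.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(rng_seed)
    fold_members: dict[str, list[list[str]]] = {}
    for epitope in seen_epitopes:
        members = sorted(set(positives.loc[positives["epitope"] == epitope, "cdr3b"]))
        if len(members) < folds:
            raise ValueError(
                f"epitope {epitope!r} has {len(members)} distinct CDR3Bs "
                f"but {folds} folds were requested"
            )
        perm = rng.permutation(len(members))
        fold_members[epitope] = [
            [members[i] for i in chunk] for chunk in np.array_split(perm, folds)
        ]
    splits = []
    for f in range(folds):
        train_groups = {
            e: [m for g, chunk in enumerate(chunks) for m in chunk if g != f]
            for e, chunks in fold_members.items()
        }
        test_groups = {e: list(chunks[f]) for e, chunks in fold_members.items()}
        splits.append(
            _assemble_from_groups(
                train_groups, test_groups, negatives, seen_epitopes,
                test_negative_count, rng_seed, rng,
            )
        )
    return splits
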