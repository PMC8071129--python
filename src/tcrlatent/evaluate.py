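"""Task 1 and Task 2 evaluation and cross-validation aggregation.

Task 1: for one query epitope, score its test-set binders and all ambient
test negatives by log affinity and report the AUC -- computed exactly through
the rank-sum identity (ties count one half), equivalent to the
Mann-Whitney U statistic divided by n_pos * n_neg.

Task 2: remove the ambient negatives, score every test CDR3B against every
seen epitope, predict the argmax, and report accuracy plus the row-normalized
confusion matrix. Upsampled duplicate records each count once, matching the
construction of the test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Task1Result:
    epitope: str
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class Task2Result:
    accuracy: float
    confusion: np.ndarray  # row-normalized, rows indexed by true epitope
    epitopes: list


def auc_rank_sum(pos_scores, neg_scores) -> float:
    """Exact AUC via midranks: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both positive and negative scores are required")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def task1_auc(model, query_epitope: str, split) -> Task1Result:
    """AUC of the query epitope's binders against the test negatives."""
    if query_epitope not in split.seen_epitopes:
        raise ValueError(f"{query_epitope!r} is not in the seen epitope set")
    mask = split.test_pairs["epitope"] == query_epitope
    pos_seqs = list(split.test_pairs.loc[mask, "cdr3b"])
    neg_seqs = list(split.test_negatives)
    if not pos_seqs or not neg_seqs:
        raise ValueError("empty positive or negative query set")
    pos_scores = model.log_affinity_many(pos_seqs, query_epitope)
    neg_scores = model.log_affinity_many(neg_seqs, query_epitope)
    return Task1Result(
        epitope=query_epitope,
        auc=auc_rank_sum(pos_scores, neg_scores),
        n_pos=len(pos_seqs),
        n_neg=len(neg_seqs),
    )


def task2_classify(model, split, seen_epitopes=None) -> Task2Result:
    """Multi-class assignment of test CDR3Bs to their argmax epitope.

    Argmax ties are broken by seen-epitope list order (and logged).
    """
    epitopes = list(seen_epitopes if seen_epitopes is not None
                    else split.seen_epitopes)
    seqs = list(split.test_pairs["cdr3b"])
    truth = np.array([epitopes.index(e) for e in split.test_pairs["epitope"]])
    scores = np.column_stack(
        [model.log_affinity_many(seqs, e) for e in epitopes]
    )
    pred = scores.argmax(axis=1)
    n_tied = int((np.sum(scores == scores.max(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_tied:
        logger.warning("%d argmax ties broken by epitope list order", n_tied)
    m = len(epitopes)
    confusion = np.zeros((m, m))
    np.add.at(confusion, (truth, pred), 1.0)
    row_sums = confusion.sum(axis=1, keepdims=True)
    confusion = np.divide(confusion, row_sums, where=row_sums > 0,
                          out=np.zeros_like(confusion))
    return Task2Result(
        accuracy=float((pred == truth).mean()),
        confusion=confusion,
        epitopes=epitopes,
    )


def _accuracy_on(model, pairs, epitopes) -> float:
    seqs = list(pairs["cdr3b"])
    truth = np.array([epitopes.index(e) for e in pairs["epitope"]])
    scores = np.column_stack([model.log_affinity_many(seqs, e) for e in epitopes])
    return float((scores.argmax(axis=1) == truth).mean())


def context_accuracies(unfixed, fixed, seen_epitopes, negatives, config,
                       folds: int = 5, test_negative_count: int = 1000,
                       rng_seed: int = 0) -> dict:
    """Task 2 accuracy under the four preprocessing contexts.

    Context 1: train and test on the unfixed dataset.
    Context 2: train on unfixed; test restricted to native proper sequences.
    Context 3: train and test on the fixed dataset.
    Context 4: train on fixed; test restricted to native proper sequences.

    A gap between Contexts 1 and 2 exposes the model's reliance on
    epitope-correlated curation artifacts; agreement between Contexts 3 and 4
    shows standardization removed them. ``unfixed`` and ``fixed`` must carry
    the ``fix_status`` column from
    :func:`~tcrlatent.standardize.standardize_dataset`. Returns
    ``{context: (mean accuracy, sd over folds)}``.
    """
    from .datasets import kfold_splits
    from .model.training import train

    native = {
        df: set(frame.loc[frame["fix_status"] == "native_proper", "cdr3b"])
        for df, frame in (("unfixed", unfixed), ("fixed", fixed))
    }
    results = {}
    for context, (name, frame, filtered) in {
        1: ("unfixed", unfixed, False),
        2: ("unfixed", unfixed, True),
        3: ("fixed", fixed, False),
        4: ("fixed", fixed, True),
    }.items():
        splits = kfold_splits(frame[["cdr3b", "epitope"]], negatives,
                              seen_epitopes, folds=folds,
                              test_negative_count=test_negative_count,
                              rng_seed=rng_seed)
        accs = []
        for split in splits:
            model = train(split, config)
            test = split.test_pairs
            if filtered:
                test = test[test["cdr3b"].isin(native[name])]
            accs.append(_accuracy_on(model, test, list(seen_epitopes)))
        results[context] = (float(np.mean(accs)),
                            float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0)
    return results


@dataclass
class CrossValidationResult:
    task1: list  # per fold: list of Task1Result
    task2: list  # per fold: Task2Result
    mean_accuracy: float
    sd_accuracy: float
    mean_auc: dict  # epitope -> mean AUC over folds
    mean_confusion: np.ndarray


def cross_validate(positives, negatives, seen_epitopes, folds, config,
                   test_negative_count: int = 10_000,
                   rng_seed: int = 0) -> CrossValidationResult:
    """Train once per fold and aggregate Task 1/Task 2 results.

    The confusion matrix is the elementwise mean of the per-fold normalized
    confusion matrices; accuracies are summarized by mean and standard
    deviation over folds.
    """
    from .datasets import kfold_splits
    from .model.training import train

    splits = kfold_splits(positives, negatives, seen_epitopes, folds=folds,
                          test_negative_count=test_negative_count,
                          rng_seed=rng_seed)
    task1_all, task2_all = [], []
    for split in splits:
        model = train(split, config)
        task1_all.append([task1_auc(model, e, split) for e in seen_epitopes])
        task2_all.append(task2_classify(model, split))
    accs = np.array([t.accuracy for t in task2_all])
    mean_auc = {
        e: float(np.mean([fold[i].auc for fold in task1_all]))
        for i, e in enumerate(seen_epitopes)
    }
    return CrossValidationResult(
        task1=task1_all,
        task2=task2_all,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        mean_auc=mean_auc,
        mean_confusion=np.mean([t.confusion for t in task2_all], axis=0),
    )
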