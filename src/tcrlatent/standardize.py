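"""Standardization of CDR3B sequences to the conserved C...F convention.

Public TCR databases curate CDR3B sequences inconsistently: some report the
full region flanked by the conserved cysteine (N-terminus) and phenylalanine
(C-terminus), others trim one or both, and some retain a superfluous
G after the conserved F. A sequence starting with C and ending with F is
"proper"; anything else is "improper". Improper sequences are repaired with a
terminal-3-mer frequency heuristic: an N-terminus lacking C is fixable at k if
its leading 3-mer is among the top-k most frequent 3-mers both directly after
the conserved C in native proper sequences and at the start of improper
sequences; fixing prepends C. Symmetrically, a C-terminus lacking F is fixable
if its trailing 3-mer is top-k on both C-side tables (fix: append F) or
matches the XFG motif (fix: trim the trailing G). The result is an "unfixed"
dataset (original strings of native proper + fixable sequences) and a "fixed"
dataset (same membership, repaired strings).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


logger = logging.getLogger(__name__)

DEFAULT_K = 10
MIN_COUNTING_LENGTH = 5


def classify_properness(seq: str) -> str:
    """Return "proper" iff ``seq`` starts with C and ends with F."""
    if not seq:
        raise ValueError("empty CDR3B sequence")
    return "proper" if seq[0] == "C" and seq[-1] == "F" else "improper"


@dataclass(frozen=True)
class TerminalKmerTables:
    """3-mer counts at the two termini, split by properness.

    n_proper:   3-mers directly following the conserved C of proper sequences.
    n_improper: N-terminal 3-mers of improper sequences lacking the leading C.
    c_proper:   3-mers directly preceding the conserved F of proper sequences.
    c_improper: C-terminal 3-mers of improper sequences lacking the trailing F.
    """

    n_proper: dict[str, int]
    n_improper: dict[str, int]
    c_proper: dict[str, int]
    c_improper: dict[str, int]


def top_k_kmers(counts: dict[str, int], k: int) -> set[str]:
    """Top-k keys by (count desc, lexicographic asc) -- deterministic ties."""
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {kmer for kmer, _ in ranked[:k]}


def count_terminal_3mers(sequences) -> TerminalKmerTables:
    """Count terminal 3-mers over ``sequences`` per the properness rules.

    Sequences shorter than 5 residues are skipped (no 3-mer fits beside a
    conserved terminus) with a logged warning.
    """
    n_proper: Counter = Counter()
    n_improper: Counter = Counter()
    c_proper: Counter = Counter()
    c_improper: Counter = Counter()
    n_skipped = 0
    for seq in sequences:
        if len(seq) < MIN_COUNTING_LENGTH:
            n_skipped += 1
            continue
        has_c = seq[0] == "C"
        has_f = seq[-1] == "F"
        if has_c and has_f:
            n_proper[seq[1:4]] += 1
            c_proper[seq[-4:-1]] += 1
        else:
            if not has_c:
                n_improper[seq[:3]] += 1
            if not has_f:
                c_improper[seq[-3:]] += 1
    if n_skipped:
        logger.warning("skipped %d sequences shorter than %d residues",
                       n_skipped, MIN_COUNTING_LENGTH)
    return TerminalKmerTables(dict(n_proper), dict(n_improper),
                              dict(c_proper), dict(c_improper))


@dataclass(frozen=True)
class FixDecision:
    """Outcome of the repair procedure for one CDR3B sequence."""

    status: str  # native_proper | fixed_proper | unfixable_improper
    n_action: str  # none | prepend_C
    c_action: str  # none | append_F | trim_G
    fixed_sequence: str | None


def fix_sequence(seq: str, tables: TerminalKmerTables, k: int = DEFAULT_K) -> FixDecision:
    """Decide whether ``seq`` is proper, fixable at ``k``, or unfixable.

    The N- and C-terminal decisions are independent; a sequence needing a fix
    at a terminus that is not fixable is unfixable overall. XFG trimming takes
    precedence over appending F.
    """
    if classify_properness(seq) == "proper":
        return FixDecision("native_proper", "none", "none", seq)

    n_action = "none"
    c_action = "none"
    fixed = seq

    if seq[0] != "C":
        n_top_proper = top_k_kmers(tables.n_proper, k)
        n_top_improper = top_k_kmers(tables.n_improper, k)
        if seq[:3] in n_top_proper and seq[:3] in n_top_improper:
            n_action = "prepend_C"
        else:
            return FixDecision("unfixable_improper", "none", "none", None)

    if seq[-1] != "F":
        tail = seq[-3:]
        if len(tail) == 3 and tail[1] == "F" and tail[2] == "G":
            c_action = "trim_G"
        else:
            c_top_proper = top_k_kmers(tables.c_proper, k)
            c_top_improper = top_k_kmers(tables.c_improper, k)
            if tail in c_top_proper and tail in c_top_improper:
                c_action = "append_F"
            else:
                return FixDecision("unfixable_improper", "none", "none", None)

    if c_action == "trim_G":
        fixed = fixed[:-1]
    elif c_action == "append_F":
        fixed = fixed + "F"
    if n_action == "prepend_C":
        fixed = "C" + fixed
    return FixDecision("fixed_proper", n_action, c_action, fixed)


def standardize_dataset(pairs: pd.DataFrame, k: int = DEFAULT_K):
    """Build the unfixed and fixed datasets from a (cdr3b, epitope[, ...]) table.

    Returns ``(unfixed, fixed, report)``:

    - ``unfixed``: native proper plus fixable improper records, original strings;
    - ``fixed``: same records, improper strings repaired;
    - ``report``: per-epitope counts and the proportion of native proper
      sequences (the properness/epitope association diagnostic).

    Both output frames carry ``properness``, ``fix_status`` and ``fixed_cdr3b``
    columns. The procedure is idempotent: applied to an already fixed dataset
    it changes nothing.
    """
    tables = count_terminal_3mers(pairs["cdr3b"])
    decisions = [fix_sequence(s, tables, k) for s in pairs["cdr3b"]]
    annotated = pairs.copy()
    annotated["properness"] = [classify_properness(s) for s in pairs["cdr3b"]]
    annotated["fix_status"] = [d.status for d in decisions]
    annotated["fixed_cdr3b"] = [d.fixed_sequence for d in decisions]

    keep = annotated["fix_status"] != "unfixable_improper"
    unfixed = annotated[keep].reset_index(drop=True)
    fixed = unfixed.copy()
    fixed["cdr3b"] = fixed["fixed_cdr3b"]

    report = (
        annotated.groupby("epitope")
        .agg(
            n_total=("cdr3b", "size"),
            n_native_proper=("properness", lambda s: int((s == "proper").sum())),
            n_unfixable=("fix_status",
                         lambda s: int((s == "unfixable_improper").sum())),
        )
        .reset_index()
    )
    report["proper_proportion"] = report["n_native_proper"] / report["n_total"]
    return unfixed, fixed, report


def confounder_log_ratio_test(
    scorer,
    test_cdr3bs,
    epitope_a: str,
    epitope_b: str,
    exact_below: int = 40,
):
    """Diagnose terminus-processing artifacts via affinity log-ratios.

    For each test CDR3B x_i, r_i = log p(x_i, epitope_a) - log p(x_i, epitope_b)
    is computed under two variants: the proper sequence, and the N-truncated
    variant with the leading C removed (trailing F kept). ``scorer`` must
    expose ``log_affinity(cdr3b, epitope) -> float``. Returns
    ``(r_proper, r_truncated, U, p)`` with a two-sided Mann-Whitney U test
    between the two r_i samples (exact method below a combined n of
    ``exact_below``, normal approximation with tie correction otherwise).

    Sequences without a leading C cannot be truncated and are skipped with a
    warning.
    """
    r_proper = []
    r_truncated = []
    n_skipped = 0
    for seq in test_cdr3bs:
        if seq[0] != "C":
            n_skipped += 1
            continue
        r_proper.append(
            scorer.log_affinity(seq, epitope_a) - scorer.log_affinity(seq, epitope_b)
        )
        trunc = seq[1:]
        r_truncated.append(
            scorer.log_affinity(trunc, epitope_a)
            - scorer.log_affinity(trunc, epitope_b)
        )
    if n_skipped:
        logger.warning("skipped %d sequences without a leading C", n_skipped)
    r_proper = np.asarray(r_proper)
    r_truncated = np.asarray(r_truncated)
    method = "exact" if len(r_proper) + len(r_truncated) < exact_below else "asymptotic"
    res = stats.mannwhitneyu(r_proper, r_truncated, alternative="two-sided",
                             method=method)
    return r_proper, r_truncated, float(res.statistic), float(res.pvalue)
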