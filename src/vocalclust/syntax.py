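"""Transition-probability syntax analysis of labeled vocal sequences.

From a sequence of cluster/call-type labels (in emission order) a
first-order transition matrix is estimated — P(next type | current type)
over consecutive pairs, self-transitions included — together with per-type
frequencies. Two sessions are compared by correlating the corresponding
rows of their transition matrices, yielding four summary scores
(unweighted/weighted x unpenalized/penalized):

* *weighting* multiplies each row correlation by 1 - |f_a - f_b|, the
  agreement in that type's frequency of use;
* *penalizing* averages over the union vocabulary, with types absent from
  one session entering as all-zero rows that correlate 0 — novel or dropped
  types lower the score.

Syntax entropy summarizes sequence stereotypy: the Shannon entropy of each
leading type's transition distribution, frequency-weighted and normalized
by log2(number of types), so 0 means fully deterministic sequencing and 1
means uniformly random transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TransitionMatrix",
    "SyntaxComparison",
    "transition_matrix",
    "compare_syntax",
    "syntax_entropy",
]


@dataclass
class TransitionMatrix:
    """Per-type transition probabilities and frequencies of one session."""

    types: list[str]
    tp: np.ndarray  # row = leading type, column = following type
    freq: np.ndarray  # renditions of type / total renditions
    n_transitions: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.tp, index=self.types, columns=self.types)


@dataclass
class SyntaxComparison:
    """The four syntax similarity scores and per-type row correlations.

    ``unpenalized`` scores are NaN (with ``disjoint=True``) when the two
    vocabularies share no type.
    """

    unweighted_unpenalized: float
    unweighted_penalized: float
    weighted_unpenalized: float
    weighted_penalized: float
    per_type_correlations: dict[str, float]
    disjoint: bool = False


def transition_matrix(labels) -> TransitionMatrix:
    """Estimate the first-order transition matrix of a label sequence.

    Counts consecutive pairs (self-transitions included) and normalizes each
    row by the leading type's total outgoing transitions; rows of a type
    that never leads (sequence-final only) stay zero. The vocabulary is
    sorted alphabetically for reproducibility.
    """
    labels = [str(l) for l in labels]
    if len(labels) < 2:
        raise ValueError("need a sequence of at least 2 labels")
    types = sorted(set(labels))
    index = {t: i for i, t in enumerate(types)}
    n = len(types)
    counts = np.zeros((n, n))
    for a, b in zip(labels[:-1], labels[1:]):
        counts[index[a], index[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    tp = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    freq = np.array([labels.count(t) for t in types]) / len(labels)
    return TransitionMatrix(types, tp, freq, len(labels) - 1)


def _expand(t: TransitionMatrix, union: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Embed tp/freq into the union vocabulary (zero rows/cols for absent types)."""
    n = len(union)
    pos = {u: i for i, u in enumerate(union)}
    tp = np.zeros((n, n))
    freq = np.zeros(n)
    idx = [pos[t] for t in t.types]
    tp[np.ix_(idx, idx)] = t.tp
    freq[idx] = t.freq
    return tp, freq


def _row_corr(ra: np.ndarray, rb: np.ndarray) -> float:
    """Row correlation with degenerate rules: identical rows (including two
    all-zero rows) correlate 1; an all-zero or zero-variance row against a
    different row correlates 0 — this is the novel-type penalty."""
    if np.allclose(ra, rb):
        return 1.0
    if not ra.any() or not rb.any():
        return 0.0
    if ra.std() < 1e-12 or rb.std() < 1e-12:
        return 0.0
    return float(np.corrcoef(ra, rb)[0, 1])


def compare_syntax(a: TransitionMatrix, b: TransitionMatrix) -> SyntaxComparison:
    """Compute the four syntax similarity scores between two sessions."""
    union = sorted(set(a.types) | set(b.types))
    shared = set(a.types) & set(b.types)
    tpa, fa = _expand(a, union)
    tpb, fb = _expand(b, union)
    r = {t: _row_corr(tpa[i], tpb[i]) for i, t in enumerate(union)}
    weight = {t: 1.0 - abs(fa[i] - fb[i]) for i, t in enumerate(union)}
    # unpenalized averages run over shared types that actually lead
    # transitions in both sessions; penalized averages run over the union
    leads = [
        t
        for i, t in enumerate(union)
        if t in shared and tpa[i].any() and tpb[i].any()
    ]
    disjoint = len(shared) == 0
    if leads:
        uu = float(np.mean([r[t] for t in leads]))
        wu = float(np.mean([r[t] * weight[t] for t in leads]))
    else:
        uu = wu = float("nan")
    up = float(np.mean([r[t] for t in union]))
    wp = float(np.mean([r[t] * weight[t] for t in union]))
    return SyntaxComparison(uu, up, wu, wp, r, disjoint=disjoint)


def syntax_entropy(t: TransitionMatrix) -> float:
    """Normalized conditional entropy of the transition structure, in [0, 1].

    Sum over leading types of freq(type) * H(row) / log2(n types); types
    without outgoing transitions contribute zero. A deterministic cycle
    scores 0; uniform transitions score 1.
    """
    n = len(t.types)
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        row = t.tp[i]
        if not row.any():
            continue
        p = row[row > 0]
        h = float(-(p * np.log2(p)).sum())
        total += t.freq[i] * h
    return total / np.log2(n)
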