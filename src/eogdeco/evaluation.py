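"""Error-rate scoring for continuous recognition.

A hypothesis is aligned to its reference by minimum-edit-distance
dynamic programming with unit costs, yielding substitution (S),
deletion (D) and insertion (I) counts.  The error rate is

    rate = 100 * (S + D + I) / N

with N the reference length; the same formula scores characters (CER)
and eye motions (motion error rate).  Insertion-dominated hypotheses
can push the rate above 100%.  On equal-cost alignments the traceback
prefers substitution over deletion over insertion.

Corpus-level rates pool the counts (sum of S+D+I over the sum of N),
the convention used in continuous speech recognition scoring -- they
are not the mean of per-utterance rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ErrorCounts",
    "align_and_count",
    "error_rate",
    "evaluate_corpus",
    "corpus_counts",
    "score_report",
    "relative_reduction",
]


@dataclass(frozen=True)
class ErrorCounts:
    """Substitutions, deletions, insertions and reference length."""

    S: int
    D: int
    I: int
    N: int

    def __post_init__(self):
        if min(self.S, self.D, self.I, self.N) < 0:
            raise ValueError("counts must be non-negative")
        if self.S + self.D > self.N:
            raise ValueError("S + D cannot exceed the reference length")

    def __add__(self, other: "ErrorCounts") -> "ErrorCounts":
        return ErrorCounts(self.S + other.S, self.D + other.D,
                           self.I + other.I, self.N + other.N)

    @property
    def total_errors(self) -> int:
        return self.S + self.D + self.I


def align_and_count(ref: Sequence, hyp: Sequence) -> ErrorCounts:
    """Minimum-edit-distance alignment counts between two symbol sequences."""
    n, m = len(ref), len(hyp)
    # cost[i, j]: edit distance between ref[:i] and hyp[:j]
    cost = np.zeros((n + 1, m + 1), dtype=np.int64)
    cost[:, 0] = np.arange(n + 1)
    cost[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        ri = ref[i - 1]
        for j in range(1, m + 1):
            sub = cost[i - 1, j - 1] + (ri != hyp[j - 1])
            dele = cost[i - 1, j] + 1
            ins = cost[i, j - 1] + 1
            cost[i, j] = min(sub, dele, ins)
    # traceback; tie preference: substitution/match > deletion > insertion
    S = D = I = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and cost[i, j] == cost[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            S += ref[i - 1] != hyp[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and cost[i, j] == cost[i - 1, j] + 1:
            D += 1
            i -= 1
        else:
            I += 1
            j -= 1
    return ErrorCounts(S=int(S), D=int(D), I=int(I), N=n)


def error_rate(counts: ErrorCounts) -> float:
    """Percent error rate 100*(S+D+I)/N; undefined for an empty reference."""
    if counts.N == 0:
        raise ValueError("reference length is zero")
    return 100.0 * counts.total_errors / counts.N


def corpus_counts(outputs: Sequence[Sequence], references: Sequence[Sequence]) -> ErrorCounts:
    """Pooled error counts over a corpus of (hypothesis, reference) pairs."""
    if len(outputs) != len(references):
        raise ValueError("outputs and references differ in cardinality")
    if len(references) == 0:
        raise ValueError("empty corpus")
    total = ErrorCounts(0, 0, 0, 0)
    for hyp, ref in zip(outputs, references):
        total = total + align_and_count(ref, hyp)
    return total


def evaluate_corpus(outputs: Sequence[Sequence], references: Sequence[Sequence]) -> float:
    """Pooled corpus error rate in percent."""
    return error_rate(corpus_counts(outputs, references))


def score_report(outputs: Sequence[Sequence], references: Sequence[Sequence]) -> pd.DataFrame:
    """Per-utterance S/D/I/N/rate rows plus a pooled TOTAL row."""
    rows = []
    total = ErrorCounts(0, 0, 0, 0)
    for k, (hyp, ref) in enumerate(zip(outputs, references)):
        c = align_and_count(ref, hyp)
        total = total + c
        rows.append({"utterance": str(k), "S": c.S, "D": c.D, "I": c.I,
                     "N": c.N, "rate": error_rate(c) if c.N else float("nan")})
    rows.append({"utterance": "TOTAL", "S": total.S, "D": total.D, "I": total.I,
                 "N": total.N, "rate": error_rate(total)})
    return pd.DataFrame(rows)


def relative_reduction(baseline: float, improved: float) -> float:
    """Relative error-rate reduction in percent, 100*(a-b)/a."""
    if baseline == 0:
        raise ValueError("baseline rate is zero")
    return 100.0 * (baseline - improved) / baseline
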