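"""Comparing predicted calls with known variants: the double-uncertainty metric.

A prediction with breakends (x, y) and uncertainty eps matches a known variant
with breakends (a, b) and reference uncertainty delta when both closed
uncertainty intervals intersect:

    [x - eps, x + eps] n [a - delta, a + delta] != {}   and
    [y - eps, y + eps] n [b - delta, b + delta] != {}.

Intervals are closed, so touching endpoints count as a match. The default
prediction uncertainty is Lmax / 2 (the sequencing process); the reference
uncertainty is 0 for breakpoint-exact truth sets and ~200 for truth sets
derived from paired-read mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PredictionRecord",
    "KnownVariant",
    "du_overlap",
    "match_calls",
    "roc_table",
    "evaluate_calls",
]


@dataclass(frozen=True)
class PredictionRecord:
    """A predicted variant: breakends (x, y), uncertainty eps, and a score."""

    chrom: str
    x: int
    y: int
    eps: float
    score: float = 0.0
    svtype: str = ""
    copy_call: int = 0

    def __post_init__(self):
        if self.eps < 0:
            raise ValueError("prediction uncertainty must be non-negative")
        if self.x > self.y:
            raise ValueError("require x <= y")


@dataclass(frozen=True)
class KnownVariant:
    """A known variant: breakends (a, b) and reference uncertainty delta."""

    chrom: str
    a: int
    b: int
    delta: float = 0.0
    svtype: str = ""
    genotype: int | None = None
    id: str = ""

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("reference uncertainty must be non-negative")
        if self.a > self.b:
            raise ValueError("require a <= b")


def du_overlap(pred: PredictionRecord, known: KnownVariant) -> bool:
    """Double-uncertainty match: both breakend uncertainty intervals intersect."""
    if pred.chrom != known.chrom:
        return False
    left = (pred.x - pred.eps <= known.a + known.delta
            and known.a - known.delta <= pred.x + pred.eps)
    right = (pred.y - pred.eps <= known.b + known.delta
             and known.b - known.delta <= pred.y + pred.eps)
    return left and right


def match_calls(calls: list[PredictionRecord], truth: list[KnownVariant],
                match_svtype: bool = True) -> list[list[int]]:
    """For each call, the indices of truth variants it matches."""
    out = []
    for c in calls:
        hits = []
        for t_idx, t in enumerate(truth):
            if match_svtype and c.svtype and t.svtype and c.svtype != t.svtype:
                continue
            if du_overlap(c, t):
                hits.append(t_idx)
        out.append(hits)
    return out


def roc_table(calls: list[PredictionRecord], truth: list[KnownVariant],
              match_svtype: bool = True) -> pd.DataFrame:
    """(threshold, true positives, novel predictions) at each score cut.

    At a threshold, a truth variant counts as one true positive when at least
    one call at or above the threshold matches it; calls matching no truth
    variant are novel predictions. Calls are assumed already pruned.
    """
    if not truth:
        import warnings

        warnings.warn("empty truth set: every call is a novel prediction")
    hits = match_calls(calls, truth, match_svtype)
    scores = np.array([c.score for c in calls])
    rows = []
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        matched_truth = set()
        novel = 0
        for i in np.flatnonzero(sel):
            if hits[i]:
                matched_truth.update(hits[i])
            else:
                novel += 1
        rows.append({"threshold": thr, "tp": len(matched_truth),
                     "novel": novel, "n_calls": int(sel.sum())})
    return pd.DataFrame(rows, columns=["threshold", "tp", "novel", "n_calls"])


def evaluate_calls(calls: list[PredictionRecord], truth: list[KnownVariant],
                   match_svtype: bool = True) -> dict:
    """Summary metrics at the full call set (no threshold)."""
    hits = match_calls(calls, truth, match_svtype)
    matched_truth: dict[int, int] = {}  # truth idx -> best call idx
    novel = 0
    for i, h in enumerate(hits):
        if not h:
            novel += 1
            continue
        for t_idx in h:
            if (t_idx not in matched_truth
                    or calls[i].score > calls[matched_truth[t_idx]].score):
                matched_truth[t_idx] = i
    n_truth = len(truth)
    tp = len(matched_truth)
    geno_total = geno_correct = 0
    for t_idx, c_idx in matched_truth.items():
        t = truth[t_idx]
        if t.genotype is not None and calls[c_idx].copy_call in (1, 2):
            geno_total += 1
            geno_correct += int(calls[c_idx].copy_call == t.genotype)
    return {
        "n_calls": len(calls),
        "n_truth": n_truth,
        "tp": tp,
        "novel": novel,
        "sensitivity": tp / n_truth if n_truth else float("nan"),
        "novel_rate": novel / len(calls) if calls else 0.0,
        "genotype_checked": geno_total,
        "genotype_correct": geno_correct,
        "genotype_accuracy": (geno_correct / geno_total if geno_total
                              else float("nan")),
    }
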