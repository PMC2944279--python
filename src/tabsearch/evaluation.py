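"""ROC/AUC benchmarking of ranked search output against gold-standard
labels, with Hanley–McNeil confidence intervals, plus the SSM-style Q
score for converting (aligned residues, RMSD) pairs into a match score.

Scores from multiple queries are pooled into one labelled list (after
normalization, which the search already applies): self-comparisons are
dropped, and gold-standard pairs for which a method produced no score are
assigned a value strictly below the lowest provided score so they rank
last.  AUC is the probability that a random positive outscores a random
negative (ties count half), computed from ranks; the standard error uses
the Hanley–McNeil closed form with Q1 = A/(2−A) and Q2 = 2A²/(1+A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError

__all__ = ["LabeledScore", "ROCResult", "pool_scores", "roc_auc", "roc_points", "q_score"]

#: Empirical RMSD scale (Å) in the Q score denominator.
R0 = 3.0


@dataclass(frozen=True)
class LabeledScore:
    """One (query, database entry) comparison with its gold-standard label."""

    query_id: str
    db_id: str
    score: float
    positive: bool


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def pool_scores(
    scores: Iterable[tuple[str, str, float]],
    labels: Mapping[tuple[str, str], bool],
    fill_missing: bool = True,
) -> list[LabeledScore]:
    """Pool per-query score lists into one labelled list.

    Parameters
    ----------
    scores:
        (query_id, db_id, score) triples from one or more queries.
    labels:
        Gold standard: (query_id, db_id) → positive?  Every scored pair
        must be labelled.
    fill_missing:
        If true, labelled pairs with no score are assigned
        min(provided scores) − 1, so they rank below everything a method
        did score.

    Self-comparisons (query_id == db_id) are excluded from both sides.
    Duplicate scored pairs are an error.
    """
    seen: dict[tuple[str, str], float] = {}
    for qid, did, s in scores:
        if qid == did:
            continue
        key = (qid, did)
        if key in seen:
            raise ValidationError(f"duplicate score for pair {key}")
        seen[key] = float(s)

    for key in seen:
        if key not in labels:
            raise ValidationError(f"scored pair {key} has no gold-standard label")

    pooled = [
        LabeledScore(q, d, s, bool(labels[(q, d)])) for (q, d), s in seen.items()
    ]
    if fill_missing:
        if not seen:
            raise ValidationError("cannot fill missing scores: no scores provided")
        fill = min(seen.values()) - 1.0
        for (qid, did), lab in labels.items():
            if qid != did and (qid, did) not in seen:
                pooled.append(LabeledScore(qid, did, fill, bool(lab)))
    return pooled


def roc_auc(pooled: Iterable[LabeledScore]) -> ROCResult:
    """AUC with Hanley–McNeil standard error and 95% confidence interval.

    AUC = P(score_pos > score_neg) + ½·P(tie), computed by the rank
    (Mann–Whitney) statistic; equivalent to the trapezoidal area under the
    TPR-vs-FPR curve swept over all thresholds.  The interval is
    AUC ± 1.96·SE, clipped to [0, 1].
    """
    pooled = list(pooled)
    y = np.array([p.positive for p in pooled], dtype=bool)
    s = np.array([p.score for p in pooled], dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"AUC undefined: need both classes (n_pos={n_pos}, n_neg={n_neg})"
        )
    ranks = rankdata(s)  # average ranks on ties → half-credit AUC
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    return ROCResult(
        auc=float(auc),
        se=se,
        ci_low=max(0.0, float(auc) - 1.96 * se),
        ci_high=min(1.0, float(auc) + 1.96 * se),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def roc_points(pooled: Iterable[LabeledScore]) -> list[tuple[float, float, float]]:
    """(FPR, TPR, threshold) sweep over all score thresholds, for plotting.

    The curve starts at (0, 0) (threshold above every score) and ends at
    (1, 1); thresholds are the distinct scores in decreasing order.
    """
    pooled = list(pooled)
    y = np.array([p.positive for p in pooled], dtype=bool)
    s = np.array([p.score for p in pooled], dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC curve undefined with a single class")
    order = np.argsort(-s, kind="stable")
    s = s[order]
    y = y[order]
    points = [(0.0, 0.0, math.inf)]
    tp = fp = 0
    k = 0
    n = len(s)
    while k < n:
        thr = s[k]
        while k < n and s[k] == thr:
            if y[k]:
                tp += 1
            else:
                fp += 1
            k += 1
        points.append((fp / n_neg, tp / n_pos, float(thr)))
    return points


def q_score(n_align: int, rmsd: float, n1: int, n2: int) -> float:
    """SSM-style alignment quality: N_align² / ((1 + (RMSD/R0)²)·N1·N2).

    R0 = 3.0 Å.  Equals 1 for a complete zero-RMSD alignment of two
    equal-length structures and 0 when nothing aligns.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("structure sizes must be ≥ 1")
    if n_align < 0 or rmsd < 0:
        raise ValidationError("n_align and rmsd must be non-negative")
    return (n_align * n_align) / ((1.0 + (rmsd / R0) ** 2) * n1 * n2)
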