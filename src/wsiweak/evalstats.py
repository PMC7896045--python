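"""Slide-level evaluation: ROC AUC, DeLong variance/CI, paired DeLong
test, and bootstrap AUC distributions.

AUC is the Mann-Whitney statistic (ties counted 1/2).  Confidence
intervals and paired model comparisons use DeLong's structural-components
estimator: for positives ``x_1..x_m`` and negatives ``y_1..y_n`` define
``psi(x, y)`` = 1 if x > y, 1/2 if x == y, 0 otherwise; the components

    V10_i = mean_j psi(x_i, y_j)        (one per positive)
    V01_j = mean_i psi(x_i, y_j)        (one per negative)

have sample variances/covariances that combine into
``var(AUC) = S10/m + S01/n``, giving a normal-approximation CI and, for two
models scored on the same cases, a two-sided z-test on the AUC difference.

Per-class scores from the ternary classifier are binarised one-vs-rest:
the score for class c is the softmax probability of c, the label is 1 iff
the slide's label is c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "ScoredCase",
    "AUCResult",
    "BootstrapSummary",
    "auc",
    "delong_components",
    "delong_ci",
    "delong_test",
    "auc_vs_chance",
    "bootstrap_auc",
    "one_vs_rest",
]


@dataclass(frozen=True)
class ScoredCase:
    slide_id: str
    true_binary_label: int
    score: float


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass
class BootstrapSummary:
    aucs: np.ndarray
    q1: float
    q2: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_iter: int


def _as_arrays(cases, scores=None):
    if scores is not None:
        y = np.asarray(cases, dtype=int)
        s = np.asarray(scores, dtype=float)
    else:
        y = np.asarray([c.true_binary_label for c in cases], dtype=int)
        s = np.asarray([c.score for c in cases], dtype=float)
    if y.size == 0:
        raise ValueError("no cases")
    if y.min() == y.max():
        raise ValueError("AUC needs at least one positive and one negative")
    return y, s


def auc(cases, scores=None) -> float:
    """Mann-Whitney AUC; call as ``auc(y, scores)`` or ``auc(scored_cases)``."""
    y, s = _as_arrays(cases, scores)
    pos = s[y == 1]
    neg = s[y == 0]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    m = len(pos)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * len(neg)))


def delong_components(y, scores) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the structural components V10 (positives) and V01 (negatives).

    Vectorised midrank formulation, O((m+n) log(m+n)).
    """
    y = np.asarray(y, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    a = float(v10.mean())
    return a, v10, v01


def _delong_var(v10, v01) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_ci(cases, scores=None, level: float = 0.95) -> AUCResult:
    """Normal-approximation CI from the DeLong variance, clipped to [0, 1]."""
    y, s = _as_arrays(cases, scores)
    a, v10, v01 = delong_components(y, s)
    var = _delong_var(v10, v01)
    if var <= 0:
        warnings.warn(
            "zero DeLong variance (perfect or degenerate separation); "
            "returning a width-0 interval"
        )
        return AUCResult(a, a, a, level)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return AUCResult(a, max(0.0, a - half), min(1.0, a + half), level)


def delong_test(y, scores_a, scores_b) -> float:
    """Two-sided DeLong test comparing two models' AUCs on the same cases.

    ``y`` is the shared binary label vector; the paired covariance of the
    structural components enters the variance of the AUC difference.
    """
    y = np.asarray(y, dtype=int)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if not (len(y) == len(sa) == len(sb)):
        raise ValueError("paired scores must align with the shared labels")
    a1, v10a, v01a = delong_components(y, sa)
    a2, v10b, v01b = delong_components(y, sb)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = a1 - a2
    if var <= 0:
        if abs(diff) < 1e-12:
            return 1.0
        warnings.warn("zero variance with nonzero AUC difference")
        return 0.0
    z = diff / np.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))


def auc_vs_chance(y, scores) -> float:
    """Two-sided p-value of H0: AUC = 0.5 (a dummy model scoring 0.5).

    Uses the DeLong variance of the single model's AUC; a constant-score
    dummy contributes neither variance nor covariance.
    """
    a, v10, v01 = delong_components(np.asarray(y, int),
                                    np.asarray(scores, float))
    var = _delong_var(v10, v01)
    if var <= 0:
        return 0.0 if abs(a - 0.5) > 1e-12 else 1.0
    z = (a - 0.5) / np.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))


def bootstrap_auc(y, scores, n_iter: int = 100,
                  seed: int = 0) -> BootstrapSummary:
    """Bootstrap the AUC over ``n_iter`` case resamples.

    Resamples missing one of the classes are redrawn so exactly ``n_iter``
    AUCs are produced.  Box-whisker fields follow the Q2 +/- 1.5*(Q3-Q1)
    convention with whiskers clipped to observed values.
    """
    y = np.asarray(y, dtype=int)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = np.empty(n_iter)
    for i in range(n_iter):
        while True:
            idx = rng.integers(0, n, size=n)
            if y[idx].min() != y[idx].max():
                break
        aucs[i] = auc(y[idx], s[idx])
    q1, q2, q3 = np.percentile(aucs, [25, 50, 75])
    iqr = q3 - q1
    lo_limit, hi_limit = q2 - 1.5 * iqr, q2 + 1.5 * iqr
    within = aucs[(aucs >= lo_limit) & (aucs <= hi_limit)]
    if within.size == 0:
        within = aucs
    return BootstrapSummary(
        aucs=aucs, q1=float(q1), q2=float(q2), q3=float(q3),
        whisker_low=float(within.min()), whisker_high=float(within.max()),
        n_iter=n_iter,
    )


def one_vs_rest(probs, labels, target: str,
                class_order: Sequence[str] = ("NC", "ADC", "SqCC"),
                slide_ids: Optional[Sequence[str]] = None):
    """Binarise ternary predictions for one target class.

    Returns ``(y, scores)`` arrays; scores are the raw target-class
    probabilities (no renormalisation).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != len(class_order):
        raise ValueError("probs must be (n_cases, n_classes)")
    ti = list(class_order).index(target)
    y = np.asarray([1 if l == target else 0 for l in labels], dtype=int)
    return y, probs[:, ti]
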