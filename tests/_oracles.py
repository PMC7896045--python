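"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from wsiweak.evalstats import auc


def permutation_p_value(y, scores_a, scores_b, n_perm=2000, seed=0):
    """Paired swap-permutation test of equal AUCs (two-sided).

    Under the null the two models' scores are exchangeable per case, so
    each permutation swaps the paired scores of a random case subset and
    recomputes the absolute AUC difference.
    """
    y = np.asarray(y)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    observed = abs(auc(y, a) - auc(y, b))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        swap = rng.integers(0, 2, len(y)).astype(bool)
        aa = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        if abs(auc(y, aa) - auc(y, bb)) >= observed - 1e-12:
            count += 1
    return count / n_perm


def brute_force_bag_max(scores):
    """Slide probabilities by explicit per-class maximisation loops."""
    scores = np.asarray(scores, dtype=float)
    best_adc = max(row[1] for row in scores)
    best_sqcc = max(row[2] for row in scores)
    nc = min(row[0] for row in scores)
    raw = [nc, best_adc, best_sqcc]
    total = sum(raw)
    return np.array([v / total for v in raw])


def brute_force_topk(values, k):
    """Indices of the k largest values by exhaustive sorted enumeration."""
    pairs = sorted(enumerate(values), key=lambda p: (-p[1], p[0]))
    return [i for i, _ in pairs[: min(k, len(pairs))]]
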