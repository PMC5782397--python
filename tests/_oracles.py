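"""Independent reference implementations used only to check the package.

Everything here is deliberately written the slow, obvious way (double loops,
exhaustive enumeration) so it cannot share a bug with the vectorized or
incremental code paths it validates.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_objective(S, labels) -> float:
    """Double-loop evaluation of f(A) = sum over co-clustered (i,j) of 1-2*S_ij."""
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                total += 1.0 - 2.0 * S[i, j]
    return total


def frobenius_gap(S, labels) -> float:
    """||S - A A^T||_F^2 by explicit matrix arithmetic."""
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    A = (labels[:, None] == np.unique(labels)[None, :]).astype(float)
    R = S - A @ A.T
    return float((R**2).sum())


def all_partitions(n: int):
    """Yield every set partition of range(n) as a label tuple.

    Uses restricted-growth strings, so each partition appears exactly once.
    """

    def rec(prefix, maxlab):
        i = len(prefix)
        if i == n:
            yield tuple(prefix)
            return
        for lab in range(maxlab + 2):
            yield from rec(prefix + [lab], max(maxlab, lab))

    yield from rec([0], 0)


def pair_f1_reference(truth, pred) -> float:
    """Pair-level F1 by explicit enumeration of all object pairs."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    tp = fp = fn = 0
    for i, j in combinations(range(len(truth)), 2):
        same_t = truth[i] == truth[j]
        same_p = pred[i] == pred[j]
        tp += same_t and same_p
        fp += (not same_t) and same_p
        fn += same_t and (not same_p)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def best_match_correct(truth, pred) -> int:
    """Objects correctly assigned under the optimal cluster matching."""
    from scipy.optimize import linear_sum_assignment

    truth = np.asarray(truth)
    pred = np.asarray(pred)
    t_ids = np.unique(truth)
    p_ids = np.unique(pred)
    table = np.zeros((t_ids.size, p_ids.size), dtype=int)
    for a, t in enumerate(t_ids):
        for b, p in enumerate(p_ids):
            table[a, b] = int(((truth == t) & (pred == p)).sum())
    ri, ci = linear_sum_assignment(-table)
    return int(table[ri, ci].sum())
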