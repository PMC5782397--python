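"""External clustering accuracy metrics.

All metrics compare a predicted partition against a reference partition via
their contingency table and are invariant to relabeling of either side:
normalized mutual information (arithmetic-mean normalization), the plain
Rand index (pair-agreement fraction), the pair-counting F1 score, and exact
recovery (equality up to a bijective relabeling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import shrinkage_cluster
from .simulate import add_noise, make_assignment, similarity_from_assignment

__all__ = [
    "ContingencyTable",
    "MetricsReport",
    "contingency",
    "nmi",
    "rand_index",
    "pairwise_f1",
    "exact_recovery",
    "score",
    "recovery_curve",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Co-occurrence counts between two partitions of the same objects."""

    counts: np.ndarray  # R x C integer matrix
    row_totals: np.ndarray
    col_totals: np.ndarray
    n: int


def contingency(truth, pred) -> ContingencyTable:
    """Cross-tabulate two label vectors over the same ``N`` objects."""
    t = np.asarray(truth)
    p = np.asarray(pred)
    if t.ndim != 1 or p.ndim != 1 or t.size != p.size:
        raise ValueError(
            f"label vectors must be 1-D and equal length, got {t.shape} vs {p.shape}"
        )
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    r, c = ti.max() + 1, pi.max() + 1
    counts = np.bincount(ti * c + pi, minlength=r * c).reshape(r, c)
    return ContingencyTable(
        counts=counts,
        row_totals=counts.sum(axis=1),
        col_totals=counts.sum(axis=0),
        n=int(t.size),
    )


def _entropy(totals: np.ndarray, n: int) -> float:
    p = totals[totals > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(table: ContingencyTable) -> float:
    """Normalized mutual information, arithmetic-mean normalization.

    ``I(T; P) / ((H(T) + H(P)) / 2)``.  Returns 1 when both partitions are
    the single-cluster partition (they are then identical), and 0 when one
    side is trivial but the other is not (MI is 0).
    """
    if table.n < 1:
        raise ValueError("empty contingency table")
    ht = _entropy(table.row_totals, table.n)
    hp = _entropy(table.col_totals, table.n)
    if ht == 0.0 and hp == 0.0:
        return 1.0
    nz = table.counts > 0
    pij = table.counts[nz] / table.n
    pi = (table.row_totals / table.n)[np.nonzero(nz)[0]]
    pj = (table.col_totals / table.n)[np.nonzero(nz)[1]]
    mi = float((pij * np.log(pij / (pi * pj))).sum())
    val = mi / ((ht + hp) / 2.0)
    return float(min(max(val, 0.0), 1.0))


def _pairs(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def rand_index(table: ContingencyTable) -> float:
    """Plain (unadjusted) Rand index: fraction of agreeing object pairs.

    A pair agrees when it is co-clustered in both partitions or separated in
    both.
    """
    if table.n < 2:
        raise ValueError("Rand index needs at least 2 objects")
    total = _pairs(table.n)
    same_both = _pairs(table.counts).sum()
    same_t = _pairs(table.row_totals).sum()
    same_p = _pairs(table.col_totals).sum()
    agree = total + 2.0 * same_both - same_t - same_p
    return float(agree / total)


def pairwise_f1(table: ContingencyTable) -> float:
    """Pair-counting F1: harmonic mean of pair precision and recall.

    A "positive" is a co-clustered pair; TP are pairs co-clustered in both
    partitions.  Returns 0 when there are no true positives; if the
    reference has no co-clustered pairs at all (all singletons), recall is
    undefined and 0 is returned with a warning.
    """
    if table.n < 2:
        raise ValueError("pairwise F1 needs at least 2 objects")
    tp = _pairs(table.counts).sum()
    pred_pos = _pairs(table.col_totals).sum()
    true_pos = _pairs(table.row_totals).sum()
    if true_pos == 0.0:
        warnings.warn(
            "reference partition has no co-clustered pairs; F1 reported as 0",
            stacklevel=2,
        )
        return 0.0
    if tp == 0.0 or pred_pos == 0.0:
        return 0.0
    precision = tp / pred_pos
    recall = tp / true_pos
    return float(2.0 * precision * recall / (precision + recall))


def exact_recovery(truth, pred) -> bool:
    """True iff ``pred`` equals ``truth`` up to a bijective relabeling.

    Holds exactly when the contingency table is a permuted diagonal: every
    true cluster maps onto one predicted cluster and vice versa.
    """
    table = contingency(truth, pred)
    nz = table.counts > 0
    return bool(
        table.counts.shape[0] == table.counts.shape[1]
        and (nz.sum(axis=0) == 1).all()
        and (nz.sum(axis=1) == 1).all()
    )


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy summary of a predicted partition against a reference."""

    nmi: float
    rand: float
    f1: float
    k_pred: int
    exact: bool


def score(truth, pred) -> MetricsReport:
    """All accuracy metrics in one report."""
    table = contingency(truth, pred)
    return MetricsReport(
        nmi=nmi(table),
        rand=rand_index(table),
        f1=pairwise_f1(table),
        k_pred=int((table.col_totals > 0).sum()),
        exact=exact_recovery(truth, pred),
    )


def recovery_curve(
    sizes: Sequence[int],
    sigma_grid: Sequence[float],
    reps: int,
    seed: int = 0,
    k0: Optional[int] = None,
    omega: int = 0,
    max_iter: int = 10_000,
    restarts: int = 1,
) -> dict[float, float]:
    """Exact-recovery fraction of the solver per noise level.

    For each ``sigma`` in ``sigma_grid``, builds ``reps`` noisy similarity
    matrices from the block structure given by ``sizes`` (distinct noise and
    initialization seeds per replicate, derived from ``seed``), runs the
    solver on each, and records the fraction of replicates whose final
    partition matches the truth exactly up to relabeling.

    Returns
    -------
    dict
        ``sigma -> recovery fraction`` in run order of ``sigma_grid``.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    truth = make_assignment(sizes)
    S0 = similarity_from_assignment(truth)
    rng = np.random.default_rng(seed)
    out: dict[float, float] = {}
    for sigma in sigma_grid:
        sub = rng.integers(0, 2**31 - 1, size=(reps, 2))
        hits = 0
        for noise_seed, solver_seed in sub:
            S = add_noise(S0, float(sigma), seed=int(noise_seed)) if sigma > 0 else S0
            res = shrinkage_cluster(
                S,
                k0=k0,
                omega=omega,
                max_iter=max_iter,
                seed=int(solver_seed),
                restarts=restarts,
                validate=False,
            )
            hits += exact_recovery(truth, res.labels)
        out[float(sigma)] = hits / reps
    return out
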