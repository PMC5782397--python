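"""The shrinkage clustering solver.

Given an ``N x N`` similarity matrix ``S`` with entries in ``[0, 1]``, a hard
clustering into ``K`` clusters can be written as a binary assignment matrix
``A`` (one 1 per row); ``A A^T`` is then the binary similarity the partition
implies.  Clustering is posed as the symmetric factorization problem

    min_A  || S - A A^T ||_F^2

which, because ``A`` is a hard assignment, is equivalent (up to the constant
``sum_ij S_ij^2``) to minimizing

    f(A) = sum_i sum_{j : same cluster} (1 - 2 S_ij)

with self-pairs included.  The solver starts from a random partition into a
deliberately generous number of clusters and repeats two steps: drop clusters
that have fallen below the admissible size (empty clusters for the base
algorithm), then apply the single membership change with the most negative
cost

    delta_f(i, k -> k') = 2 * ( sum_{j in k', j != i} (1 - 2 S_ij)
                              - sum_{j in k,  j != i} (1 - 2 S_ij) ).

Because every applied move strictly decreases ``f`` and ``f`` is bounded
below by ``-sum_ij S_ij^2``, the iteration converges to a local optimum.
Clusters empty out and disappear along the way, so the surviving cluster
count at convergence is the selected number of clusters: no external model
selection is required.

A minimum cluster size ``omega`` generalizes the empty-cluster removal:
clusters smaller than ``omega`` are dissolved during iteration and their
members folded into the surviving clusters, yielding a partition whose
clusters all hold at least ``omega`` objects (whenever that is feasible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .similarity import gaussian_similarity, standardize_features, validate_similarity

__all__ = [
    "SolverState",
    "ShrinkageClustering",
    "ShrinkageResults",
    "compute_objective",
    "delta_f",
    "best_move",
    "apply_move",
    "remove_small_clusters",
    "initialize_partition",
    "shrinkage_cluster",
]

DEFAULT_K0 = 20
DEFAULT_MAX_ITER = 10_000


def compute_objective(sim, labels) -> float:
    """Evaluate the clustering objective ``f(A)``.

    ``f(A) = sum_i sum_{j : labels[i] == labels[j]} (1 - 2 S_ij)``, with the
    self-pair ``j == i`` included.  Up to the partition-independent constant
    ``sum_ij S_ij^2`` this equals ``||S - A A^T||_F^2``.

    Parameters
    ----------
    sim : array_like
        ``N x N`` similarity matrix.
    labels : array_like
        Length-``N`` integer cluster labels.

    Returns
    -------
    float
    """
    S = np.asarray(sim, dtype=float)
    labels = np.asarray(labels)
    n = labels.shape[0] if labels.ndim == 1 else -1
    if labels.ndim != 1 or S.shape != (n, n):
        raise ValueError(
            f"similarity of shape {S.shape} and {labels.ndim}-D label vector "
            f"of length {labels.shape[0] if labels.ndim else 0} do not match"
        )
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        block = S[np.ix_(idx, idx)]
        total += idx.size**2 - 2.0 * block.sum()
    return float(total)


def initialize_partition(n: int, k0: int, seed: int) -> np.ndarray:
    """Assign ``n`` objects uniformly at random to ``k0`` cluster ids.

    Some of the ``k0`` clusters may receive no objects by chance; they are
    removed during the solver's first sweep.  Reproducible given ``seed``.
    """
    if not 1 <= k0 <= n:
        raise ValueError(f"k0 must be in [1, {n}], got {k0}")
    rng = np.random.default_rng(seed)
    return rng.integers(0, k0, size=n).astype(np.intp)


class SolverState:
    """Mutable solver state with caches for O(N*K) move evaluation.

    Attributes
    ----------
    S : numpy.ndarray
        The (validated) similarity matrix.
    labels : numpy.ndarray
        Current cluster label per object, in ``0..k-1``.
    k : int
        Number of cluster slots currently tracked (some may be empty until
        the next removal sweep).
    cluster_sizes : numpy.ndarray
        Object count per cluster slot.
    cluster_sums : numpy.ndarray
        ``V[i, c] = sum_{j in c, j != i} (1 - 2 S_ij)``, the per-object
        insertion/removal cost accumulator; kept incrementally consistent
        across moves and rebuilt on cluster removal.
    omega : int
        Minimum admissible cluster size (0 means empty-cluster removal only).
    iteration : int
        Iterations performed so far.
    """

    def __init__(self, sim, labels, n_clusters: Optional[int] = None, omega: int = 0):
        S = np.asarray(sim, dtype=float)
        labels = np.asarray(labels, dtype=np.intp).copy()
        n = S.shape[0]
        if S.ndim != 2 or S.shape != (n, n) or labels.shape != (n,):
            raise ValueError("similarity matrix and labels have mismatched shapes")
        k = int(n_clusters) if n_clusters is not None else int(labels.max()) + 1
        if labels.min() < 0 or labels.max() >= k:
            raise ValueError("labels out of range for the declared cluster count")
        if omega < 0:
            raise ValueError(f"omega must be non-negative, got {omega}")
        self.S = S
        self.n = n
        self.W = 1.0 - 2.0 * S
        self._wdiag = np.diag(self.W).copy()
        self.labels = labels
        self.k = k
        self.omega = int(omega)
        self.iteration = 0
        self.removed_last_sweep = False
        self.orphaned_last_sweep = False
        self.cluster_sizes = np.bincount(labels, minlength=k).astype(np.intp)
        self._rebuild_sums()

    def _rebuild_sums(self) -> None:
        M = np.zeros((self.n, self.k))
        M[np.arange(self.n), self.labels] = 1.0
        V = self.W @ M
        V[np.arange(self.n), self.labels] -= self._wdiag
        self.cluster_sums = V

    # -- consistency helpers (used by tests) ---------------------------------
    def brute_force_sums(self) -> np.ndarray:
        """Recompute ``cluster_sums`` directly from the definition."""
        V = np.zeros((self.n, self.k))
        for c in range(self.k):
            members = np.flatnonzero(self.labels == c)
            for i in range(self.n):
                others = members[members != i]
                V[i, c] = self.W[i, others].sum()
        return V


def delta_f(state: SolverState, i: int, target: int) -> float:
    """Objective change from moving object ``i`` into cluster ``target``.

    Equals ``f(A') - f(A)`` exactly, where ``A'`` is the partition after the
    single move.  Sums over the source and target clusters exclude the
    self-pair ``j == i``, whose contribution cancels between ``f(A')`` and
    ``f(A)``.  Moving an object into its own cluster costs 0.
    """
    if not 0 <= i < state.n:
        raise ValueError(f"object index {i} out of range")
    if not 0 <= target < state.k:
        raise ValueError(f"unknown cluster id {target}")
    k = state.labels[i]
    if target == k:
        return 0.0
    V = state.cluster_sums
    return float(2.0 * (V[i, target] - V[i, k]))


def best_move(state: SolverState):
    """Find the membership change that most decreases the objective.

    Scans all objects against all non-empty clusters other than their own.
    Returns ``(i, target, delta)`` with the minimum ``delta_f``, breaking
    ties by lowest object index then lowest cluster id, or ``None`` when no
    move strictly decreases the objective (the convergence signal).
    """
    V = state.cluster_sums
    idx = np.arange(state.n)
    cur = V[idx, state.labels][:, None]
    D = 2.0 * (V - cur)
    D[idx, state.labels] = np.inf
    empty = state.cluster_sizes == 0
    if empty.any():
        D[:, empty] = np.inf
    flat = int(np.argmin(D))  # row-major: lowest object index, then cluster id
    i, c = divmod(flat, state.k)
    d = D[i, c]
    if not d < 0.0:
        return None
    return int(i), int(c), float(d)


def apply_move(state: SolverState, i: int, target: int) -> None:
    """Move object ``i`` to cluster ``target``, updating caches in O(N)."""
    k = state.labels[i]
    if target == k:
        return
    w = state.W[i]
    V = state.cluster_sums
    V[:, k] -= w
    V[:, target] += w
    V[i, k] += state._wdiag[i]
    V[i, target] -= state._wdiag[i]
    state.cluster_sizes[k] -= 1
    state.cluster_sizes[target] += 1
    state.labels[i] = target


def _drop_clusters(state: SolverState, drop: np.ndarray) -> None:
    """Delete cluster slots ``drop``, reassigning any orphaned members.

    Surviving clusters keep their relative order (labels are compacted to
    ``0..k'-1``).  Objects of a dissolved non-empty cluster are reassigned
    one at a time in ascending object-index order, each to the surviving
    cluster with the smallest insertion cost ``sum_{j in c} (1 - 2 S_ij)``
    given the assignments made so far (ties: lowest cluster id).
    """
    keep = np.setdiff1d(np.arange(state.k), drop)
    remap = np.full(state.k, -1, dtype=np.intp)
    remap[keep] = np.arange(keep.size)
    new_labels = remap[state.labels]
    orphans = np.flatnonzero(new_labels < 0)

    state.k = int(keep.size)
    state.labels = new_labels
    assigned = new_labels >= 0
    M = np.zeros((state.n, state.k))
    M[assigned, new_labels[assigned]] = 1.0
    V = state.W @ M
    V[assigned, new_labels[assigned]] -= state._wdiag[assigned]
    state.cluster_sums = V
    state.cluster_sizes = np.bincount(
        new_labels[assigned], minlength=state.k
    ).astype(np.intp)

    for i in orphans:  # ascending index order
        c = int(np.argmin(V[i]))  # i is unassigned: V[i, c] is the insertion cost
        state.labels[i] = c
        state.cluster_sizes[c] += 1
        V[:, c] += state.W[i]
        V[i, c] -= state._wdiag[i]


def remove_small_clusters(state: SolverState) -> SolverState:
    """One removal sweep: drop empty clusters, dissolve one undersized one.

    All empty clusters are deleted outright (this never changes the
    objective).  If the minimum size ``omega`` is in force and some surviving
    cluster holds fewer than ``max(omega, 1)`` objects, the smallest such
    cluster (ties: lowest id) is dissolved and its members are folded into
    the remaining clusters by greedy insertion cost — unless the current
    globally best move would move an object *into* that cluster, in which
    case the cluster is still actively assembling and is spared for this
    sweep.  Dissolving at most one cluster per sweep, and never a cluster
    the optimization is growing, lets the constrained solver merge structure
    gradually instead of collapsing the partition while every early cluster
    is still below the floor.  If only one cluster remains and it is still
    undersized (``omega > N``), it is retained with a warning.

    Returns the (mutated) state; ``state.removed_last_sweep`` records
    whether anything was deleted.
    """
    removed = False
    orphaned = False
    if (state.cluster_sizes == 0).any():
        _drop_clusters(state, np.flatnonzero(state.cluster_sizes == 0))
        removed = True
    floor = max(state.omega, 1)
    small = np.flatnonzero(state.cluster_sizes < floor)
    if small.size:
        if state.k > 1:
            c = int(small[int(np.argmin(state.cluster_sizes[small]))])
            move = best_move(state)
            if move is None or move[1] != c:
                _drop_clusters(state, np.asarray([c]))
                removed = True
                orphaned = True
        else:
            warnings.warn(
                f"minimum cluster size omega={state.omega} cannot be met: "
                "a single undersized cluster remains and is retained",
                stacklevel=2,
            )
    state.removed_last_sweep = removed
    state.orphaned_last_sweep = orphaned
    return state


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


@dataclass
class ShrinkageResults:
    """Outcome of a shrinkage clustering run.

    Attributes
    ----------
    labels : numpy.ndarray
        Final hard assignment, integer labels in ``0..k_final-1``.
    k_final : int
        Number of clusters at termination.
    objective : float
        Final value of ``f(A)``.
    path : numpy.ndarray
        ``n_iterations x 3`` array of ``(iteration, k, objective)`` — the
        shrinkage path.  ``k`` counts non-empty clusters.
    n_iterations : int
        Iterations performed (including the final convergence check).
    converged : bool
        True when the run stopped because no strictly improving move
        remained; False when ``max_iter`` was exhausted.
    seed : int
        Seed of the initialization that produced this run.
    omega : int
        Minimum cluster size in force.
    """

    labels: np.ndarray
    k_final: int
    objective: float
    path: np.ndarray
    n_iterations: int
    converged: bool
    seed: int
    omega: int = 0
    model: Optional["ShrinkageClustering"] = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.k_final

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k_final)

    def summary(self) -> str:
        """Human-readable run summary."""
        sizes = ", ".join(str(s) for s in self.cluster_sizes)
        lines = [
            "Shrinkage Clustering Results",
            "=" * 34,
            f"objects:            {self.labels.size}",
            f"clusters (K):       {self.k_final}",
            f"objective f(A):     {self.objective:.6g}",
            f"iterations:         {self.n_iterations}",
            f"converged:          {self.converged}",
            f"seed:               {self.seed}",
            f"min cluster size:   {self.omega}",
            f"cluster sizes:      {sizes}",
        ]
        return "\n".join(lines)

    def plot_path(self, ax=None):
        """Plot the shrinkage path (cluster count per iteration)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.path[:, 0], self.path[:, 1], where="post")
        ax.set_xlabel("iteration")
        ax.set_ylabel("number of clusters")
        ax.set_title("shrinkage path")
        return ax


def _single_run(
    S: np.ndarray, k0: int, omega: int, max_iter: int, seed: int
) -> ShrinkageResults:
    n = S.shape[0]
    labels0 = initialize_partition(n, k0, seed)
    state = SolverState(S, labels0, n_clusters=k0, omega=omega)
    f = compute_objective(S, state.labels)
    path = []
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        state.iteration = it
        remove_small_clusters(state)
        if state.orphaned_last_sweep:
            # dissolving a non-empty cluster changes f; recompute
            f = compute_objective(S, state.labels)
        move = best_move(state)
        if move is not None:
            i, c, d = move
            apply_move(state, i, c)
            f += d
        k_nonempty = int((state.cluster_sizes > 0).sum())
        path.append((it, k_nonempty, f))
        if move is None and not state.removed_last_sweep:
            converged = True
            break

    # compact away any empty slots left by a max_iter stop
    if (state.cluster_sizes == 0).any():
        _drop_clusters(state, np.flatnonzero(state.cluster_sizes == 0))

    return ShrinkageResults(
        labels=state.labels.copy(),
        k_final=int(state.k),
        objective=compute_objective(S, state.labels),
        path=np.asarray(path, dtype=float),
        n_iterations=it,
        converged=converged,
        seed=seed,
        omega=omega,
    )


def shrinkage_cluster(
    sim,
    k0: Optional[int] = None,
    omega: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    restarts: int = 1,
    validate: bool = True,
) -> ShrinkageResults:
    """Cluster a similarity matrix by shrinkage clustering.

    Parameters
    ----------
    sim : array_like
        ``N x N`` similarity matrix, entries in ``[0, 1]``.
    k0 : int, optional
        Initial number of random clusters; clusters only ever disappear, so
        ``k0`` should exceed the number of clusters expected in the data.
        Defaults to ``min(N, 20)``.
    omega : int
        Minimum admissible cluster size; 0 gives the base algorithm.
    max_iter : int
        Iteration cap; one membership change is applied per iteration.
    seed : int
        Seed for the random initialization; restart ``r`` uses ``seed + r``.
    restarts : int
        Number of independent restarts; the run with the lowest final
        objective is returned (ties: earliest restart).
    validate : bool
        Validate/canonicalize ``sim`` first (recommended).

    Returns
    -------
    ShrinkageResults
    """
    S = validate_similarity(sim) if validate else np.asarray(sim, dtype=float)
    n = S.shape[0]
    if n == 1:
        return ShrinkageResults(
            labels=np.zeros(1, dtype=np.intp),
            k_final=1,
            objective=compute_objective(S, np.zeros(1, dtype=np.intp)),
            path=np.empty((0, 3)),
            n_iterations=0,
            converged=True,
            seed=seed,
            omega=omega,
        )
    if k0 is None:
        k0 = min(n, DEFAULT_K0)
    if restarts < 1:
        raise ValueError(f"restarts must be >= 1, got {restarts}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")

    best: Optional[ShrinkageResults] = None
    for r in range(restarts):
        res = _single_run(S, k0=k0, omega=omega, max_iter=max_iter, seed=seed + r)
        if best is None or res.objective < best.objective:
            best = res
    assert best is not None
    return best


class ShrinkageClustering:
    """Shrinkage clustering model over a similarity matrix.

    Parameters
    ----------
    similarity : array_like
        ``N x N`` similarity matrix with entries in ``[0, 1]``.
    omega : int
        Minimum admissible cluster size (0 disables the constraint).
    validate : bool
        Canonicalize the input (symmetrize, clip, unit diagonal).

    Examples
    --------
    >>> import numpy as np
    >>> from shrinkclust import ShrinkageClustering
    >>> S = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
    >>> res = ShrinkageClustering(S).fit(k0=3, seed=0)
    >>> res.k_final
    2
    """

    def __init__(self, similarity, omega: int = 0, validate: bool = True):
        self.similarity = (
            validate_similarity(similarity)
            if validate
            else np.asarray(similarity, dtype=float)
        )
        self.omega = int(omega)
        self.n_objects = self.similarity.shape[0]
        self.kernel_params = None

    @classmethod
    def from_features(
        cls, features, omega: int = 0, standardize: bool = False
    ) -> "ShrinkageClustering":
        """Build the model from an objects-by-features table.

        Features are optionally standardized (per-column mean 0, sd 1) and
        converted to similarities with the distance-distribution Gaussian
        kernel (see :func:`shrinkclust.similarity.gaussian_similarity`).
        """
        X = np.asarray(features, dtype=float)
        if standardize:
            X = standardize_features(X)
        S, params = gaussian_similarity(X)
        model = cls(S, omega=omega, validate=False)
        model.kernel_params = params
        return model

    def fit(
        self,
        k0: Optional[int] = None,
        max_iter: int = DEFAULT_MAX_ITER,
        seed: int = 0,
        restarts: int = 1,
    ) -> ShrinkageResults:
        """Run the solver; see :func:`shrinkage_cluster` for parameters."""
        res = shrinkage_cluster(
            self.similarity,
            k0=k0,
            omega=self.omega,
            max_iter=max_iter,
            seed=seed,
            restarts=restarts,
            validate=False,
        )
        res.model = self
        return res
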