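"""Synthetic inputs for exercising the solver.

Three generators cover the study conditions used throughout the package's
tests: (i) a binary block similarity matrix built from a known assignment
(``S = A A^T``), the noiseless ideal case; (ii) folded-Gaussian perturbation
of such a binary matrix, which smears the two similarity modes toward each
other until, at high noise, similarity relationships start to flip; and
(iii) two-dimensional Gaussian blobs with identity covariance, the simplest
feature-space input for the kernel-conversion pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SimulationSpec",
    "make_assignment",
    "similarity_from_assignment",
    "add_noise",
    "gaussian_blobs",
]

#: folded-Gaussian noise above this sd flips more than ~32% of relationships
#: and the block structure becomes unrecoverable; larger values are allowed
#: but flagged.
MAX_FAITHFUL_SIGMA = 0.5


def make_assignment(sizes: Sequence[int]) -> np.ndarray:
    """Contiguous block assignment from cluster sizes.

    The first ``sizes[0]`` objects go to cluster 0, the next ``sizes[1]`` to
    cluster 1, and so on.

    Parameters
    ----------
    sizes : sequence of int
        Positive cluster sizes; their sum is the number of objects.

    Returns
    -------
    numpy.ndarray
        Integer label vector of length ``sum(sizes)``.
    """
    sizes = np.asarray(sizes, dtype=np.intp)
    if sizes.size == 0:
        raise ValueError("cluster sizes must be non-empty")
    if (sizes < 1).any():
        raise ValueError(f"cluster sizes must all be >= 1, got {sizes.tolist()}")
    return np.repeat(np.arange(sizes.size, dtype=np.intp), sizes)


def similarity_from_assignment(labels) -> np.ndarray:
    """Binary similarity implied by a partition: ``S = A A^T``.

    ``S_ij = 1`` iff ``labels[i] == labels[j]``, so the diagonal is 1 and,
    under a block ordering, ``S`` is block diagonal.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty 1-D sequence")
    return (labels[:, None] == labels[None, :]).astype(float)


def add_noise(sim, sigma: float, seed: int, symmetrize: bool = True) -> np.ndarray:
    """Perturb a binary similarity matrix with folded-Gaussian noise.

    Each off-diagonal entry becomes ``|eps|`` where it was 0 and
    ``1 - |eps|`` where it was 1, with an independent ``eps ~ N(0, sigma^2)``
    per entry (the noise model is entrywise, so the two copies of an
    unordered pair receive independent draws).  The diagonal is structural
    self-similarity and is left at 1.  Entries are clipped to ``[0, 1]``
    (draws with ``|eps| > 1`` are rare for ``sigma <= 0.5``).

    With ``symmetrize=True`` (default) the entrywise-noisy matrix is
    averaged with its transpose, yielding the symmetric matrix the solver
    consumes — the same matrix the objective effectively sees anyway, since
    ``f`` sums ``S_ij`` and ``S_ji`` over every co-clustered pair.  Pass
    ``symmetrize=False`` to obtain the raw entrywise matrix, e.g. to study
    the marginal entry distribution: at ``sigma = 0.5`` roughly 32% of raw
    entries cross 0.5 and are effectively reversed.

    Parameters
    ----------
    sim : array_like
        Binary (0/1) square similarity matrix.
    sigma : float
        Noise standard deviation.
    seed : int
        Seed for the noise draws.
    symmetrize : bool
        Average the noisy matrix with its transpose (default True).

    Returns
    -------
    numpy.ndarray
    """
    S = np.asarray(sim, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"similarity matrix must be square, got shape {S.shape}")
    if not np.isin(S, (0.0, 1.0)).all():
        raise ValueError("noise model is defined only on binary similarity matrices")
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma > MAX_FAITHFUL_SIGMA:
        warnings.warn(
            f"sigma={sigma} exceeds {MAX_FAITHFUL_SIGMA}; block structure is "
            "unlikely to be recoverable",
            stacklevel=2,
        )
    n = S.shape[0]
    rng = np.random.default_rng(seed)
    eps = np.abs(rng.normal(0.0, sigma, size=(n, n))) if sigma > 0 else np.zeros((n, n))
    out = np.where(S == 1.0, 1.0 - eps, eps)
    np.clip(out, 0.0, 1.0, out=out)
    if symmetrize:
        out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def gaussian_blobs(
    centers: Sequence[Sequence[float]], n_per: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample 2-D Gaussian blobs with identity covariance.

    Parameters
    ----------
    centers : sequence of (x, y)
        Blob centers.
    n_per : int
        Points drawn per center.
    seed : int
        Seed for the draws.

    Returns
    -------
    (numpy.ndarray, numpy.ndarray)
        ``(len(centers) * n_per) x 2`` feature matrix and the ground-truth
        block labels.
    """
    C = np.asarray(centers, dtype=float)
    if C.ndim != 2 or C.shape[1] != 2 or C.shape[0] == 0:
        raise ValueError("centers must be a non-empty sequence of 2-D coordinates")
    if n_per < 1:
        raise ValueError(f"n_per must be >= 1, got {n_per}")
    rng = np.random.default_rng(seed)
    labels = make_assignment([n_per] * C.shape[0])
    X = C[labels] + rng.standard_normal((labels.size, 2))
    return X, labels


@dataclass
class SimulationSpec:
    """Bundle of simulation parameters with convenience realizers.

    Attributes
    ----------
    cluster_sizes : sequence of int
        Block sizes for the similarity-matrix experiments.
    noise_sigma : float
        Folded-Gaussian noise sd (0 keeps the matrix binary).
    blob_centers : sequence of (x, y), optional
        Centers for the 2-D blob generator.
    n_per_blob : int
        Points per blob center.
    seed : int
        Seed shared by the realizers.
    """

    cluster_sizes: Sequence[int] = (15, 17, 20, 24, 24)
    noise_sigma: float = 0.0
    blob_centers: Optional[Sequence[Sequence[float]]] = None
    n_per_blob: int = 50
    seed: int = 0

    def realize_similarity(self) -> tuple[np.ndarray, np.ndarray]:
        """Block similarity (optionally noisy) and its truth labels."""
        truth = make_assignment(self.cluster_sizes)
        S = similarity_from_assignment(truth)
        if self.noise_sigma > 0:
            S = add_noise(S, self.noise_sigma, seed=self.seed)
        return S, truth

    def realize_blobs(self) -> tuple[np.ndarray, np.ndarray]:
        """Blob features and their truth labels."""
        if self.blob_centers is None:
            raise ValueError("blob_centers not set")
        return gaussian_blobs(self.blob_centers, self.n_per_blob, seed=self.seed)
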