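"""Construction and normalization of similarity matrices.

A similarity matrix ``S`` is square and symmetric with entries in ``[0, 1]``
and a unit diagonal; larger ``S_ij`` means objects *i* and *j* resemble each
other more.  Feature tables (objects x features) are converted to
similarities with a Gaussian kernel on Euclidean distances whose bandwidth is
set from the distance distribution itself, so the conversion has no free
parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "KernelParams",
    "validate_similarity",
    "gaussian_similarity",
    "normalize_skewed_similarity",
    "standardize_features",
]

#: symmetry violations above this trigger a warning before averaging
SYMMETRY_ATOL = 1e-8


@dataclass(frozen=True)
class KernelParams:
    """Bandwidth statistics of the distance-based Gaussian kernel.

    Attributes
    ----------
    sigma_d : float
        Standard deviation of the pairwise Euclidean distances
        (population moment over off-diagonal entries of the full
        distance matrix).  Distance units.
    beta : float
        ``E(D^2) / sigma_d^2``, unitless.  ``nan`` in the degenerate
        all-coincident case.
    """

    sigma_d: float
    beta: float

    @property
    def bandwidth(self) -> float:
        """The kernel length scale ``beta * sigma_d``."""
        return self.beta * self.sigma_d


def validate_similarity(sim, *, copy: bool = True) -> np.ndarray:
    """Validate a similarity matrix and coerce it to the canonical form.

    Symmetry is enforced by averaging ``(S + S.T) / 2`` (with a warning when
    the maximal asymmetry exceeds ``1e-8``), entries are clipped to
    ``[0, 1]`` (with a warning when any fall outside), and the diagonal is
    set to 1.

    Parameters
    ----------
    sim : array_like
        Square matrix of pairwise similarities.

    Returns
    -------
    numpy.ndarray
        Validated ``N x N`` float matrix.
    """
    S = np.array(sim, dtype=float, copy=copy)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"similarity matrix must be square, got shape {S.shape}")
    if not np.isfinite(S).all():
        raise ValueError("similarity matrix contains non-finite entries")
    asym = np.abs(S - S.T).max() if S.size else 0.0
    if asym > SYMMETRY_ATOL:
        warnings.warn(
            f"similarity matrix is asymmetric (max |S - S.T| = {asym:.3g}); "
            "symmetrizing by averaging",
            stacklevel=2,
        )
    S = (S + S.T) / 2.0
    if S.size and (S.min() < 0.0 or S.max() > 1.0):
        warnings.warn(
            "similarity entries outside [0, 1]; clipping",
            stacklevel=2,
        )
        np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def _offdiag(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return M[mask]


def gaussian_similarity(features) -> tuple[np.ndarray, KernelParams]:
    """Convert a feature matrix to a similarity matrix.

    Uses ``S = exp(-(D / (beta * sigma))^2)`` where ``D`` is the Euclidean
    distance matrix, ``sigma`` the (population) standard deviation of the
    pairwise distances and ``beta = E(D^2) / sigma^2``.  Both statistics are
    computed over the off-diagonal entries of the full symmetric distance
    matrix; the structural zero diagonal is excluded.

    Parameters
    ----------
    features : array_like
        ``N x p`` matrix, one object per row, ``N >= 2``.

    Returns
    -------
    (numpy.ndarray, KernelParams)
        The ``N x N`` similarity matrix (unit diagonal, entries in
        ``(0, 1]``) and the kernel statistics used.

    Notes
    -----
    If every pairwise distance is zero (all objects coincide), or the
    distances have zero spread (``sigma = 0``, e.g. two objects), the kernel
    is degenerate; an all-ones matrix is returned with a warning, which is
    the limit of the kernel as the spread vanishes.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
    n = X.shape[0]
    if n < 2:
        raise ValueError("similarity construction needs at least 2 objects")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite entries")

    D = squareform(pdist(X))
    off = _offdiag(D)
    sigma_d = float(off.std())  # population moment
    if sigma_d == 0.0:
        if off.max() == 0.0:
            warnings.warn(
                "all pairwise distances are zero; returning an all-ones "
                "similarity matrix",
                stacklevel=2,
            )
            params = KernelParams(sigma_d=0.0, beta=float("nan"))
        else:
            warnings.warn(
                "pairwise distances have zero spread; kernel bandwidth is "
                "undefined, returning the all-ones limit",
                stacklevel=2,
            )
            params = KernelParams(sigma_d=0.0, beta=float("inf"))
        return np.ones((n, n)), params

    beta = float((off**2).mean() / sigma_d**2)
    S = np.exp(-((D / (beta * sigma_d)) ** 2))
    np.fill_diagonal(S, 1.0)
    return S, KernelParams(sigma_d=sigma_d, beta=beta)


def normalize_skewed_similarity(sim) -> np.ndarray:
    """Recenter a skewed similarity matrix around 0.5.

    Shifts all entries so the off-diagonal median moves to 0.5, clips the
    result to ``[0, 1]`` and resets the diagonal to 1.  Useful when raw
    similarity scores pile up near one end of the scale (as integrated
    multi-omic sample similarities tend to do), which otherwise leaves
    little contrast for the clustering objective.

    Parameters
    ----------
    sim : array_like
        Square symmetric similarity matrix.

    Returns
    -------
    numpy.ndarray
        Normalized similarity matrix satisfying the standard invariants.
    """
    S = np.array(sim, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"similarity matrix must be square, got shape {S.shape}")
    if S.shape[0] > 1:
        shift = float(np.median(_offdiag(S))) - 0.5
        S = S - shift
    np.clip(S, 0.0, 1.0, out=S)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def standardize_features(features) -> np.ndarray:
    """Scale each feature column to mean 0 and standard deviation 1.

    Constant columns (zero variance) are centered and left at zero with a
    warning, since they carry no distance information.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant feature(s) standardized to zero",
            stacklevel=2,
        )
    sd = np.where(zero, 1.0, sd)
    return (X - mu) / sd
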