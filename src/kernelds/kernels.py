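"""Kernel and Gram-matrix algebra shared by the test families.

Distances become similarity kernels either through a Gaussian
transformation with a median-heuristic bandwidth (score-test path) or
through Gower double-centering into an inner-product Gram matrix
(distance-regression path).  A clamped eigendecomposition provides the
positive-semidefinite matrix square root used by the square-root pseudo-F
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DistanceMatrix

__all__ = [
    "KernelMatrix",
    "CenteredGram",
    "EigenSqrt",
    "median_bandwidth",
    "gaussian_kernel",
    "gower_center",
    "matrix_sqrt_psd",
]


@dataclass
class KernelMatrix:
    """Gaussian similarity kernel; symmetric with unit diagonal."""

    entries: np.ndarray
    rho: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.rho <= 0:
            raise ValueError("rho must be positive")


@dataclass
class CenteredGram:
    """Gower double-centered Gram matrix: rows and columns sum to zero."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)


@dataclass
class EigenSqrt:
    """Eigendecomposition-based PSD square root of a symmetric matrix."""

    eigenvalues: np.ndarray  # descending, negative values clamped to 0
    eigenvectors: np.ndarray  # columns match eigenvalues
    sqrt_matrix: np.ndarray


def median_bandwidth(D: DistanceMatrix) -> tuple[float, bool]:
    """Median-heuristic bandwidth for the Gaussian kernel.

    Returns ``rho`` as the median of the positive squared off-diagonal
    distances, so the median subject pair receives kernel value
    ``exp(-1)``.  When every off-diagonal distance is zero the matrix
    carries no information; ``rho = 1`` is returned together with a
    degeneracy flag.
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least two subjects")
    iu = np.triu_indices(n, k=1)
    d = D.entries[iu]
    d = d[d > 0]
    if d.size == 0:
        return 1.0, True
    return float(np.median(d**2)), False


def gaussian_kernel(D: DistanceMatrix, rho: float) -> KernelMatrix:
    """Gaussian kernel ``K_ij = exp(-d_ij^2 / rho)``."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    entries = np.exp(-(D.entries**2) / rho)
    np.fill_diagonal(entries, 1.0)
    return KernelMatrix(entries=entries, rho=float(rho), degenerate=D.degenerate)


def gower_center(D: DistanceMatrix) -> CenteredGram:
    """Gower double-centering ``G = H (-D∘D/2) H`` with ``H = I - E/n``.

    Converts squared distances into an inner-product (Gram) matrix whose
    rows and columns sum to zero; for a Euclidean (or more generally
    negative-type) distance the result is positive semidefinite.
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least two subjects")
    A = -0.5 * D.entries**2
    H = np.eye(n) - np.ones((n, n)) / n
    G = H @ A @ H
    return CenteredGram(entries=(G + G.T) / 2)


def matrix_sqrt_psd(M: np.ndarray | CenteredGram | KernelMatrix) -> EigenSqrt:
    """PSD square root via eigendecomposition with small-eigenvalue clamping.

    Eigenvalues below ``1e-10 * max(lambda)`` (and all negative ones) are
    clamped to zero before taking the square root; this projects away the
    slightly negative eigenvalues produced by finite-grid JSD estimates.
    """
    entries = M if isinstance(M, np.ndarray) else M.entries
    entries = np.asarray(entries, dtype=float)
    if not np.allclose(entries, entries.T, atol=1e-8):
        raise ValueError("matrix square root requires a symmetric input")
    entries = (entries + entries.T) / 2
    vals, vecs = np.linalg.eigh(entries)
    vmax = vals.max() if vals.size else 0.0
    tol = 1e-10 * max(vmax, 0.0)
    vals = np.where(vals < tol, 0.0, vals)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    sqrt = (vecs * np.sqrt(vals)) @ vecs.T
    return EigenSqrt(eigenvalues=vals, eigenvectors=vecs, sqrt_matrix=(sqrt + sqrt.T) / 2)
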