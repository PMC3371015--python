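"""Per-view Gaussian kernels and their weighted combination."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist


def gaussian_gram(X: np.ndarray, theta: float, Z: np.ndarray | None = None) -> np.ndarray:
    """Gaussian (RBF) kernel matrix k(x, z) = exp(-||x - z||^2 / (2 theta^2)).

    With ``Z is None`` returns the n x n Gram matrix of ``X`` with an
    exact unit diagonal; otherwise the n x m cross-kernel against ``Z``.
    """
    if theta <= 0:
        raise ValueError(f"bandwidth theta must be positive, got {theta}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in X")
    if Z is None:
        d2 = cdist(X, X, "sqeuclidean")
        K = np.exp(-d2 / (2.0 * theta**2))
        np.fill_diagonal(K, 1.0)
        return (K + K.T) / 2.0
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    d2 = cdist(X, Z, "sqeuclidean")
    return np.exp(-d2 / (2.0 * theta**2))


def median_bandwidth(X: np.ndarray) -> float:
    """Median of the nonzero pairwise Euclidean distances.

    The standard data-driven bandwidth for an RBF kernel; computed once
    per view on the training inputs and then frozen.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for a median bandwidth")
    d = pdist(X)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError(
            "all points identical: median bandwidth undefined, set one manually"
        )
    return float(np.median(d))


@dataclass
class KernelStack:
    """Per-view Gram matrices with their bandwidths.

    Each Gram matrix is symmetric PSD with unit diagonal (a Gaussian
    kernel of a point with itself is 1).
    """

    grams: list[np.ndarray]
    bandwidths: list[float]
    view_names: list[str]

    def __post_init__(self) -> None:
        if not (len(self.grams) == len(self.bandwidths) == len(self.view_names)):
            raise ValueError("grams, bandwidths and view_names must align")
        n = self.grams[0].shape[0]
        for name, K in zip(self.view_names, self.grams):
            if K.shape != (n, n):
                raise ValueError(f"view {name!r}: Gram shape {K.shape} != ({n},{n})")
            if np.abs(K - K.T).max() > 1e-10:
                raise ValueError(f"view {name!r}: Gram not symmetric")

    @property
    def n_samples(self) -> int:
        return self.grams[0].shape[0]

    @property
    def n_views(self) -> int:
        return len(self.grams)

    @classmethod
    def from_views(cls, views, bandwidths=None) -> "KernelStack":
        """Build Grams from :class:`FeatureView` objects; bandwidths
        default to the per-view median heuristic."""
        if bandwidths is None:
            bandwidths = [median_bandwidth(v.matrix) for v in views]
        grams = [gaussian_gram(v.matrix, th) for v, th in zip(views, bandwidths)]
        return cls(grams=grams, bandwidths=[float(b) for b in bandwidths],
                   view_names=[v.name for v in views])


def combine(stack: KernelStack, a: np.ndarray) -> np.ndarray:
    """Weighted sum of the per-view Grams, sum_j a_j K_j.

    A nonnegative combination of PSD matrices, hence PSD.  All-zero
    weights would make the prior degenerate and raise.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (stack.n_views,):
        raise ValueError(f"expected {stack.n_views} view weights, got {a.shape}")
    if np.any(a < 0):
        raise ValueError("view weights must be nonnegative")
    if not np.any(a > 0):
        raise ValueError("all view weights are zero: degenerate prior")
    K = np.zeros((stack.n_samples, stack.n_samples))
    for aj, Kj in zip(a, stack.grams):
        K += aj * Kj
    return K


def jittered_cholesky(K: np.ndarray, jitter: float = 1e-8):
    """Cholesky with escalating diagonal jitter.

    Starts at ``jitter * mean(diag)`` and retries x10 up to 1e-4 times
    the mean diagonal before giving up.
    """
    scale = float(np.mean(np.diag(K)))
    if scale <= 0:
        scale = 1.0
    eps = jitter
    while eps <= 1e-4:
        try:
            return np.linalg.cholesky(K + eps * scale * np.eye(K.shape[0]))
        except np.linalg.LinAlgError:
            eps *= 10
    raise np.linalg.LinAlgError(
        "kernel matrix not positive definite even with jitter 1e-4"
    )
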