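"""Log-Euclidean covariance matrix (LECM) features.

The covariance matrix C of an epoch's time-frequency matrix is symmetric
positive definite (SPD), so it lives on a curved manifold rather than in a
flat vector space.  The log-Euclidean framework maps it to a vector space
through the matrix logarithm: with the eigendecomposition C = U Λ Uᵀ,

    log C = U · Diag(log λ₁, …, log λ_d) · Uᵀ,

after which Euclidean operations (and ordinary classifiers) are valid.
The feature vector is the half-vectorization of log C — the diagonal and
above-diagonal entries read column by column:

    v = [logC₁₁, logC₁₂, logC₂₂, logC₁₃, logC₂₃, logC₃₃, …, logC_dd],

of length d(d+1)/2 (6 for a 3×3 covariance, 45 for 9×9).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .vmd import TFMatrix, VMDConfig, build_tf_matrix, decompose

__all__ = [
    "CovarianceMatrix",
    "covariance",
    "matrix_log",
    "matrix_exp",
    "half_vectorize",
    "unvectorize",
    "lecm_features",
    "feature_length",
]


@dataclass(frozen=True)
class CovarianceMatrix:
    """A symmetric positive-definite covariance matrix with its dimension."""

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("covariance must be square")
        object.__setattr__(self, "C", C)

    @property
    def d(self) -> int:
        return self.C.shape[0]


def covariance(tf: TFMatrix | np.ndarray, ridge_scale: float = 1e-10) -> CovarianceMatrix:
    """Sample covariance of the time-frequency matrix columns.

    Column means are removed and the (n-1) divisor is used.  A tiny ridge
    ``ridge_scale * trace(C)/d`` is added to the diagonal so the matrix is
    strictly positive definite even when columns are collinear, which keeps
    the matrix logarithm well-defined.
    """
    values = tf.values if isinstance(tf, TFMatrix) else np.asarray(tf, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n, d = values.shape
    if n < 2:
        raise ValueError(f"need at least 2 rows to estimate a covariance, got {n}")
    centered = values - values.mean(axis=0, keepdims=True)
    C = centered.T @ centered / (n - 1)
    C = (C + C.T) / 2.0
    trace = float(np.trace(C))
    eps = ridge_scale * (trace / d if trace > 0 else 1.0)
    C += eps * np.eye(d)
    return CovarianceMatrix(C)


def matrix_log(C: CovarianceMatrix | np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix via its eigendecomposition."""
    A = C.C if isinstance(C, CovarianceMatrix) else np.asarray(C, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix_log expects a square matrix")
    eigvals, U = np.linalg.eigh((A + A.T) / 2.0)
    if eigvals[0] <= 0:
        raise ValueError(
            f"matrix is not positive definite (min eigenvalue {eigvals[0]:.3e})"
        )
    logC = (U * np.log(eigvals)) @ U.T
    return (logC + logC.T) / 2.0


def matrix_exp(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (inverse of the log map)."""
    S = np.asarray(S, dtype=float)
    eigvals, U = np.linalg.eigh((S + S.T) / 2.0)
    E = (U * np.exp(eigvals)) @ U.T
    return (E + E.T) / 2.0


def half_vectorize(logC: np.ndarray) -> np.ndarray:
    """Column-wise upper-triangle half-vectorization of a symmetric matrix.

    Order: C11, C12, C22, C13, C23, C33, …, Cdd — for each column j, the
    entries C[0..j, j].  Length d(d+1)/2.
    """
    S = np.asarray(logC, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("half_vectorize expects a square matrix")
    d = S.shape[0]
    return np.concatenate([S[: j + 1, j] for j in range(d)])


def unvectorize(v: Sequence[float]) -> np.ndarray:
    """Rebuild the symmetric matrix from its half-vectorization."""
    v = np.asarray(v, dtype=float)
    d = int(round((np.sqrt(8 * v.size + 1) - 1) / 2))
    if d * (d + 1) // 2 != v.size:
        raise ValueError(f"length {v.size} is not a triangular number")
    S = np.zeros((d, d))
    pos = 0
    for j in range(d):
        S[: j + 1, j] = v[pos : pos + j + 1]
        pos += j + 1
    return S + np.triu(S, 1).T


def feature_length(n_channels: int, n_selected: int) -> int:
    """Length of the LECM feature: d(d+1)/2 with d = n_channels * n_selected."""
    d = n_channels * n_selected
    return d * (d + 1) // 2


def lecm_features(
    epoch: np.ndarray,
    fs: float,
    vmd_config: VMDConfig,
    selected_indices: Sequence[int],
) -> np.ndarray:
    """Full feature extraction for one epoch: VMD -> covariance -> log -> vec.

    ``epoch`` is ``(epoch_samples, n_channels)``; each channel is decomposed
    independently and the selected modes of all channels form the
    time-frequency matrix whose log-covariance is half-vectorized.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[0] == 1:
        epoch = epoch.T
    if np.ptp(epoch) == 0:
        raise ValueError("epoch is constant: covariance features undefined")
    vmfsets = [decompose(epoch[:, ch], fs, vmd_config) for ch in range(epoch.shape[1])]
    tf = build_tf_matrix(vmfsets, selected_indices)
    return half_vectorize(matrix_log(covariance(tf)))
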