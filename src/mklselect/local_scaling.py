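"""Local-scaling bandwidths and locally-scaled Gaussian kernels.

Instead of one global Gaussian bandwidth, each sample i gets its own
sigma_i = Euclidean distance to its K-th nearest neighbour (self excluded),
so the kernel adapts to local density.  The kernel between samples i and j is

    K(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 sigma_i sigma_j)).

This kernel is not guaranteed positive semi-definite; ``clip_psd`` repairs a
combined training Gram by zeroing negative eigenvalues when the spectrum dips
meaningfully below zero.

Three strategies assign bandwidths to unseen samples at prediction time:

1. K-th-nearest-training-sample distance (needs the whole training set);
2. the stored sigma of the nearest support vector;
3. the nearest support vector's *mean* sigma, where each SV's mean pools its
   own sigma with those of the non-SV training samples closest to it.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ParameterError, StateError

__all__ = [
    "DEFAULT_FLOOR",
    "compute_local_sigmas",
    "local_gaussian_gram",
    "assign_sigmas_alg1",
    "assign_sigmas_alg2",
    "compute_mean_sv_sigmas",
    "assign_sigmas_alg3",
    "clip_psd",
]

logger = logging.getLogger(__name__)

#: Minimum bandwidth; keeps the kernel well-defined when duplicates collapse
#: a nearest-neighbour distance to zero.
DEFAULT_FLOOR = 1e-12


def compute_local_sigmas(X, K: int, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """Per-sample bandwidths: distance to the K-th nearest *other* sample.

    Parameters
    ----------
    X : (N, D) array
    K : int
        Neighbour index, 1 <= K < N.
    floor : float
        Lower bound applied to every bandwidth.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 1 <= K < n:
        raise ParameterError(f"K must satisfy 1 <= K < N={n}, got {K}")
    d = cdist(X, X)
    d.sort(axis=1)  # column 0 is the self distance (0.0)
    return np.maximum(d[:, K], floor)


def local_gaussian_gram(Xa, Xb, sigmas_a, sigmas_b) -> np.ndarray:
    """Locally-scaled Gaussian Gram: entry (i,j) = exp(-d_ij^2 / (2 s_i s_j))."""
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    sa = np.asarray(sigmas_a, dtype=float).ravel()
    sb = np.asarray(sigmas_b, dtype=float).ravel()
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ParameterError("bandwidths must be strictly positive")
    if sa.shape[0] != Xa.shape[0] or sb.shape[0] != Xb.shape[0]:
        raise ParameterError("bandwidth vector lengths must match sample counts")
    d2 = cdist(Xa, Xb, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * np.outer(sa, sb)))


def assign_sigmas_alg1(train_X, test_X, K: int, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """Algorithm 1: each test sample's sigma is the distance to its K-th
    nearest training sample (training set as-is, duplicates included)."""
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    n_train = train_X.shape[0]
    if n_train == 0:
        raise StateError("empty training set")
    if not 1 <= K <= n_train:
        raise ParameterError(f"K must satisfy 1 <= K <= N_train={n_train}, got {K}")
    d = cdist(test_X, train_X)
    d.sort(axis=1)
    return np.maximum(d[:, K - 1], floor)


def _nearest_index(ref_X, query_X) -> np.ndarray:
    """Index of the nearest reference row per query row; ties -> lowest index."""
    d = cdist(query_X, ref_X)
    return np.argmin(d, axis=1)  # argmin returns the first (lowest) minimizer


def assign_sigmas_alg2(sv_X, sv_sigmas, test_X) -> np.ndarray:
    """Algorithm 2: each test sample takes the stored sigma of its nearest SV."""
    sv_X = np.atleast_2d(np.asarray(sv_X, dtype=float))
    sv_sigmas = np.asarray(sv_sigmas, dtype=float).ravel()
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    if sv_X.shape[0] == 0:
        raise StateError("empty support-vector set")
    return sv_sigmas[_nearest_index(sv_X, test_X)]


def compute_mean_sv_sigmas(train_X, train_sigmas, sv_indices) -> np.ndarray:
    """Mean sigma per support vector for Algorithm 3.

    Each non-SV training sample is attached to its nearest SV (ties -> lowest
    SV index); an SV's mean sigma averages its own sigma with those of its
    attached samples.  SVs with no attached samples keep their own sigma.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_sigmas = np.asarray(train_sigmas, dtype=float).ravel()
    sv_indices = np.asarray(sv_indices, dtype=int).ravel()
    if sv_indices.size == 0:
        raise StateError("empty support-vector set")
    n = train_X.shape[0]
    non_sv = np.setdiff1d(np.arange(n), sv_indices)
    sums = train_sigmas[sv_indices].copy()
    counts = np.ones(sv_indices.size)
    if non_sv.size:
        owner = _nearest_index(train_X[sv_indices], train_X[non_sv])
        np.add.at(sums, owner, train_sigmas[non_sv])
        np.add.at(counts, owner, 1.0)
    return sums / counts


def assign_sigmas_alg3(sv_X, mean_sv_sigmas, test_X) -> np.ndarray:
    """Algorithm 3: nearest-SV lookup as Algorithm 2, but with mean sigmas."""
    return assign_sigmas_alg2(sv_X, mean_sv_sigmas, test_X)


def clip_psd(K, rel_tol: float = 1e-8) -> np.ndarray:
    """Spectrally clip a symmetric Gram matrix to positive semi-definiteness.

    If the minimum eigenvalue is below ``-rel_tol * max_eigenvalue``, negative
    eigenvalues are zeroed and the matrix reconstructed (a warning is logged);
    otherwise the input passes through untouched.
    """
    K = np.asarray(K, dtype=float)
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    w_max = max(w[-1], 0.0)
    if w[0] < -rel_tol * max(w_max, 1.0):
        logger.warning(
            "combined Gram is indefinite (min eig %.3e); clipping negative spectrum",
            w[0],
        )
        w = np.clip(w, 0.0, None)
        return (V * w) @ V.T
    return K
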