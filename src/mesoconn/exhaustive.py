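"""Exact-but-exponential reference computations for small instances.

These enumerate every set partition of the node set (Bell-number many) and
evaluate the quality function directly, independently of the Louvain path.
They exist so that heuristic optimizers can be checked against the true
optimum on instances small enough to enumerate (Bell(10) = 115,975).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.typing import NDArray


def set_partitions(n: int) -> NDArray[np.int8]:
    """All set partitions of n elements as restricted-growth label strings.

    Returns an array of shape (Bell(n), n); row k is a canonical labeling
    (first element always 0, labels contiguous).
    """
    out: list[list[int]] = []

    def grow(prefix: list[int], max_label: int) -> None:
        if len(prefix) == n:
            out.append(prefix.copy())
            return
        for lab in range(max_label + 2):
            prefix.append(lab)
            grow(prefix, max(max_label, lab))
            prefix.pop()

    grow([0], 0)
    return np.array(out, dtype=np.int8)


@lru_cache(maxsize=4)
def _comembership_stack(n: int) -> tuple[NDArray[np.int8], NDArray[np.float64]]:
    """Partitions plus their flattened co-membership indicators (diagonal
    excluded), cached because they depend only on n."""
    parts = set_partitions(n)
    same = (parts[:, :, None] == parts[:, None, :]).astype(np.float64)
    eye = np.eye(n, dtype=bool)
    same[:, eye] = 0.0
    return parts, same.reshape(parts.shape[0], n * n)


def max_modularity_exhaustive(
    B: NDArray[np.float64],
) -> tuple[float, NDArray[np.int8]]:
    """Maximum of Q = sum_{i != j} B_ij delta(g_i, g_j) over all partitions.

    ``B`` is any square matrix (e.g. A - gamma); the diagonal is ignored.
    """
    b = np.asarray(B, dtype=float).copy()
    np.fill_diagonal(b, 0.0)
    n = b.shape[0]
    parts, same = _comembership_stack(n)
    scores = same @ b.reshape(-1)
    k = int(np.argmax(scores))
    return float(scores[k]), parts[k]


def supra_matrix(
    layer_weights: list[NDArray[np.float64]], gamma: float, omega: float
) -> NDArray[np.float64]:
    """Supra-modularity matrix assembled by direct loops (oracle-side)."""
    t = len(layer_weights)
    n = layer_weights[0].shape[0]
    supra = np.zeros((n * t, n * t))
    for s in range(t):
        for i in range(n):
            for j in range(n):
                if i != j:
                    supra[s * n + i, s * n + j] = layer_weights[s][i, j] - gamma
    for i in range(n):
        for s in range(t):
            for r in range(t):
                if s != r:
                    supra[s * n + i, r * n + i] = omega
    return supra


def max_multilayer_modularity_exhaustive(
    layer_weights: list[NDArray[np.float64]], gamma: float, omega: float
) -> tuple[float, NDArray[np.int8]]:
    """Exhaustive maximum of the multilayer quality function over all
    labelings of the N*T supra-nodes."""
    supra = supra_matrix(layer_weights, gamma, omega)
    return max_modularity_exhaustive(supra)


def modularity_naive(A: NDArray[np.float64], labels: NDArray, gamma: float) -> float:
    """Double-loop evaluation of Q for cross-checking the vectorized score."""
    a = np.asarray(A, dtype=float)
    n = a.shape[0]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and labels[i] == labels[j]:
                q += a[i, j] - gamma
    return q


def multilayer_modularity_naive(
    layer_weights: list[NDArray[np.float64]],
    labels: NDArray,
    gamma: float,
    omega: float,
) -> float:
    """Quadruple-loop evaluation of the multilayer quality function.

    ``labels`` has shape (n_nodes, n_layers).
    """
    t = len(layer_weights)
    n = layer_weights[0].shape[0]
    q = 0.0
    for s in range(t):
        for i in range(n):
            for j in range(n):
                if i != j and labels[i, s] == labels[j, s]:
                    q += layer_weights[s][i, j] - gamma
    for i in range(n):
        for s in range(t):
            for r in range(t):
                if s != r and labels[i, s] == labels[i, r]:
                    q += omega
    return q
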