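"""p-nearest-neighbor sparsification of similarity matrices and graph Laplacians.

The graph-regularized models do not use the raw similarity matrices directly:
each is first sparsified through a p-nearest-neighbor indicator ``N`` that
keeps mutual neighbors at full weight, one-sided neighbors at half weight, and
zeroes everything else::

    N_ij = 1    if j in N_p(i) and i in N_p(j)
           0    if j not in N_p(i) and i not in N_p(j)
           0.5  otherwise

where ``N_p(i)`` is the set of the p indices (excluding i itself) with the
largest similarity to i.  The sparsified matrix ``S_hat = N * S`` then yields
the degree matrix D, the combinatorial Laplacian ``L = D - S_hat`` and the
symmetric normalized Laplacian ``L_norm = D^{-1/2} L D^{-1/2}``; the models
penalize ``Tr(A^T L_norm A)``, pulling the latent rows of similar entities
together.

Conventions: a node is never its own neighbor (``N_ii = 0``); ties at the
p-th neighbor are broken by smallest index; isolated nodes (zero degree after
sparsification) get all-zero rows/columns in ``L_norm``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SparsifiedGraph", "pnn_indicator", "sparsify", "laplacians", "build_graph"]


@dataclass
class SparsifiedGraph:
    """All derived quantities of a p-NN sparsified similarity graph."""

    N: np.ndarray  # indicator over {0, 0.5, 1}, zero diagonal
    S_hat: np.ndarray  # N * S elementwise
    D: np.ndarray  # diagonal degree matrix of S_hat
    L: np.ndarray  # combinatorial Laplacian D - S_hat
    L_norm: np.ndarray  # D^{-1/2} L D^{-1/2}, zero rows for isolated nodes
    p: int


def pnn_indicator(S: np.ndarray, p: int) -> np.ndarray:
    """p-nearest-neighbor indicator matrix of a symmetric similarity matrix.

    ``N_p(i)`` holds the p indices j != i with the largest ``S_ij`` (ties
    broken toward the smaller index); entries are 1 for mutual neighbors,
    0.5 for one-sided ones, 0 otherwise, and the diagonal is 0.
    """
    S = np.asarray(S, dtype=float)
    size = S.shape[0]
    if S.ndim != 2 or S.shape[1] != size:
        raise ValueError(f"S must be square, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if not 1 <= p <= size - 1:
        raise ValueError(f"p must be in [1, {size - 1}], got {p}")
    # membership[i, j] = True iff j is among i's p nearest neighbors.
    # Sort by (-similarity, index): stable tie-break toward smaller index.
    membership = np.zeros((size, size), dtype=bool)
    for i in range(size):
        order = np.lexsort((np.arange(size), -S[i]))
        order = order[order != i]
        membership[i, order[:p]] = True
    N = (membership.astype(float) + membership.T.astype(float)) / 2.0
    np.fill_diagonal(N, 0.0)
    return N


def sparsify(S: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Elementwise product ``S_hat = N * S``."""
    S = np.asarray(S, dtype=float)
    N = np.asarray(N, dtype=float)
    if S.shape != N.shape:
        raise ValueError(f"shape mismatch: S {S.shape} vs N {N.shape}")
    return N * S


def laplacians(S_hat: np.ndarray):
    """Degree, combinatorial and normalized Laplacian of a sparsified graph.

    Returns ``(D, L, L_norm)`` with ``D_ii = sum_j S_hat_ij``,
    ``L = D - S_hat`` and ``L_norm = D^{-1/2} L D^{-1/2}``.  Rows/columns of
    isolated nodes (zero degree) are defined as 0 in ``L_norm`` so downstream
    updates stay finite.
    """
    S_hat = np.asarray(S_hat, dtype=float)
    if (S_hat < 0).any():
        raise ValueError("sparsified similarity has negative entries")
    deg = S_hat.sum(axis=1)
    D = np.diag(deg)
    L = D - S_hat
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = deg[nz] ** -0.5
    L_norm = inv_sqrt[:, None] * L * inv_sqrt[None, :]
    return D, L, L_norm


def build_graph(S: np.ndarray, p: int) -> SparsifiedGraph:
    """Chain indicator -> sparsify -> Laplacians into a :class:`SparsifiedGraph`."""
    N = pnn_indicator(S, p)
    S_hat = sparsify(S, N)
    D, L, L_norm = laplacians(S_hat)
    return SparsifiedGraph(N=N, S_hat=S_hat, D=D, L=L, L_norm=L_norm, p=p)
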