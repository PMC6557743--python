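"""Independent brute-force oracles used to pin the implementation.

These deliberately re-derive each quantity from its definition by literal
enumeration or naive iteration, sharing no code with the package internals.
"""

import numpy as np


def brute_force_pnn(S: np.ndarray, p: int) -> np.ndarray:
    """Literal three-case enumeration of the p-NN indicator definition."""
    size = S.shape[0]

    def neighbors(i):
        others = [j for j in range(size) if j != i]
        # largest similarity first, ties toward the smaller index
        others.sort(key=lambda j: (-S[i, j], j))
        return set(others[:p])

    nbr = [neighbors(i) for i in range(size)]
    N = np.zeros((size, size))
    for i in range(size):
        for j in range(size):
            if i == j:
                continue
            if j in nbr[i] and i in nbr[j]:
                N[i, j] = 1.0
            elif j not in nbr[i] and i not in nbr[j]:
                N[i, j] = 0.0
            else:
                N[i, j] = 0.5
    return N


def ridge_als(Y: np.ndarray, k: int, lam: float, A0, B0, n_iter: int):
    """Plain alternating ridge regression; the lambda_d=lambda_t=lambda_s=0
    limit of every engine.  Returns the per-iterate (A, B) trajectory."""
    A, B = A0.copy(), B0.copy()
    Ik = np.eye(k)
    traj = []
    for _ in range(n_iter):
        A = np.linalg.solve(B.T @ B + lam * Ik, (Y @ B).T).T
        B = np.linalg.solve(A.T @ A + lam * Ik, (Y.T @ A).T).T
        traj.append((A.copy(), B.copy()))
    return traj


def brute_force_aupr(scores, labels) -> float:
    """Step-wise AUPR by enumerating every distinct threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    P = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    area, r_prev = 0.0, 0.0
    for t in thresholds:
        pred = scores >= t
        tp = float((pred * labels).sum())
        prec = tp / pred.sum()
        rec = tp / P
        area += (rec - r_prev) * prec
        r_prev = rec
    return area


def brute_force_auc(scores, labels) -> float:
    """Mann-Whitney pairwise comparison, ties counted 0.5."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def triple_loop_product(A, B):
    """Elementwise triple-loop A @ B.T."""
    n, k = A.shape
    m = B.shape[0]
    out = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            for c in range(k):
                out[i, j] += A[i, c] * B[j, c]
    return out
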