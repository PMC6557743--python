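"""Matrix-factorization engines for drug-target interaction prediction.

All five engines approximate the interaction matrix ``Y ~ A B^T`` with latent
factors ``A (n x k)`` for drugs and ``B (m x k)`` for targets, and differ in
how side information enters the objective:

* **CMF** (collaborative matrix factorization) fits the similarity matrices
  directly: ``||Y - AB^T||_F^2 + lambda_l(||A||^2 + ||B||^2)
  + lambda_d ||Sd - AA^T||_F^2 + lambda_t ||St - BB^T||_F^2``.
* **GRMF** replaces the similarity-fitting terms with graph regularization on
  p-NN sparsified, normalized Laplacians: ``lambda_d Tr(A^T L~d A) +
  lambda_t Tr(B^T L~t B)`` — the manifold assumption that similar drugs
  (targets) have nearby latent rows.
* **WGRMF** adds a binary weight matrix W to the data term,
  ``||W o (Y - AB^T)||_F^2``, so unknown entries exert no pull; its updates
  are per-row least squares.
* **L21GRMF / L21WGRMF** add a row-sparsity penalty ``lambda_s ||B||_{2,1}``
  (sum of the Euclidean norms of B's rows) that can switch entire target rows
  off, handled by iteratively reweighted least squares: per-row weights
  ``d_jj = 1/(2 max(||b_j||_2, eps_row))`` enter the B update as an extra
  ridge term.

All engines start from a truncated-SVD initialization ``A = U S_k^{1/2}``,
``B = V S_k^{1/2}`` and alternate closed-form least-squares updates in which
the Laplacian (and IRLS) contributions are lagged at the previous iterate,
until the relative change of the objective drops below ``tol``.

The engines are scikit-learn style estimators (``fit`` / ``predict`` /
``get_params``); the module-level ``fit_*`` functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .graph import SparsifiedGraph, build_graph

__all__ = [
    "HyperParams",
    "LatentFactors",
    "svd_initialize",
    "l21_norm",
    "l21_row_weights",
    "objective",
    "CMF",
    "GRMF",
    "WGRMF",
    "L21GRMF",
    "L21WGRMF",
    "ENGINES",
    "make_engine",
    "fit_cmf",
    "fit_grmf",
    "fit_wgrmf",
    "fit_l21grmf",
    "fit_l21wgrmf",
    "predict_scores",
]


@dataclass
class HyperParams:
    """Hyperparameters shared by all engines.

    ``lambda_s`` is the L2,1 coefficient; ``None`` couples it to ``lambda_l``
    (the printed form of the model) while still letting sparsity be tuned
    independently.  ``p`` is the neighbor count of the graph construction;
    ``eps_row`` guards the IRLS weights against exactly-zero rows.
    """

    k: int = 50
    lambda_l: float = 0.5
    lambda_d: float = 0.1
    lambda_t: float = 0.1
    lambda_s: float | None = None
    p: int = 5
    max_iter: int = 200
    tol: float = 1e-4
    eps_row: float = 1e-8
    seed: int = 0

    def resolved_lambda_s(self) -> float:
        return self.lambda_l if self.lambda_s is None else self.lambda_s

    def validate(self, n: int, m: int) -> "HyperParams":
        if not 1 <= self.k <= min(n, m):
            raise ValueError(f"k must be in [1, {min(n, m)}], got {self.k}")
        for name in ("lambda_l", "lambda_d", "lambda_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lambda_s is not None and self.lambda_s < 0:
            raise ValueError("lambda_s must be >= 0")
        if self.tol <= 0 or self.eps_row <= 0:
            raise ValueError("tol and eps_row must be > 0")
        return self


@dataclass
class LatentFactors:
    """Fitted factor pair; ``A @ B.T`` is the predicted score matrix."""

    A: np.ndarray
    B: np.ndarray
    trace: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


def svd_initialize(Y: np.ndarray, k: int):
    """Rank-k truncated-SVD initialization ``A = U S_k^{1/2}, B = V S_k^{1/2}``.

    The sign of each singular pair is fixed (largest-magnitude entry of the
    left singular vector made positive) so the result is deterministic.
    k may not exceed min(n, m), the number of singular values of Y.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k must be in [1, min(n, m)={min(n, m)}], got {k}")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    root = np.sqrt(s)
    return U * root, Vt.T * root


def l21_norm(B: np.ndarray) -> float:
    """L2,1 norm: sum over rows of the row's Euclidean norm."""
    B = np.asarray(B, dtype=float)
    return float(np.linalg.norm(B, axis=1).sum())


def l21_row_weights(B: np.ndarray, eps_row: float = 1e-8) -> np.ndarray:
    """IRLS weights ``d_jj = 1 / (2 max(||b_j||_2, eps_row))`` per row of B."""
    norms = np.linalg.norm(np.asarray(B, dtype=float), axis=1)
    return 1.0 / (2.0 * np.maximum(norms, eps_row))


def _graph_penalty(L_norm: np.ndarray, X: np.ndarray) -> float:
    return float(np.trace(X.T @ L_norm @ X))


def objective(model, dataset, graphs, W, A, B, hp: HyperParams) -> float:
    """Value of the selected engine's objective at (A, B).

    ``graphs`` is a ``(SparsifiedGraph, SparsifiedGraph)`` pair for the
    graph-regularized models and ignored for CMF; ``W`` is required by the
    weighted models.
    """
    Y = np.asarray(dataset.Y, dtype=float)
    lam_l, lam_d, lam_t = hp.lambda_l, hp.lambda_d, hp.lambda_t
    lam_s = hp.resolved_lambda_s()
    R = Y - A @ B.T
    if model in ("wgrmf", "l21wgrmf"):
        if W is None:
            raise ValueError(f"model {model!r} requires a weight matrix W")
        data = float(np.sum((W * R) ** 2))
    elif model in ("cmf", "grmf", "l21grmf"):
        if model == "cmf" and W is not None:
            data = float(np.sum((W * R) ** 2))
        else:
            data = float(np.sum(R**2))
    else:
        raise ValueError(f"unknown model {model!r}")
    obj = data + lam_l * (np.sum(A**2) + np.sum(B**2))
    if model == "cmf":
        obj += lam_d * np.sum((dataset.Sd - A @ A.T) ** 2)
        obj += lam_t * np.sum((dataset.St - B @ B.T) ** 2)
    else:
        gd, gt = graphs
        obj += lam_d * _graph_penalty(gd.L_norm, A)
        obj += lam_t * _graph_penalty(gt.L_norm, B)
    if model in ("l21grmf", "l21wgrmf"):
        obj += lam_s * l21_norm(B)
    return float(obj)


def _solve_spd(M: np.ndarray, RHS: np.ndarray) -> np.ndarray:
    """Solve X @ M = RHS for symmetric positive (semi)definite k-by-k M,
    falling back to least squares when M is singular."""
    try:
        return np.linalg.solve(M, RHS.T).T
    except np.linalg.LinAlgError:
        warnings.warn("singular k-by-k system; using least-squares fallback", stacklevel=2)
        return np.linalg.lstsq(M, RHS.T, rcond=None)[0].T


def _rowwise_ridge_solve(G: np.ndarray, ridge: np.ndarray, RHS: np.ndarray) -> np.ndarray:
    """Solve row j of X from ``x_j (G + ridge_j I) = rhs_j`` for all j at once
    via the eigendecomposition of the shared symmetric Gram matrix G."""
    evals, Q = np.linalg.eigh(G)
    RQ = RHS @ Q
    return (RQ / (evals[None, :] + ridge[:, None])) @ Q.T


def _batched_row_solve(lhs: np.ndarray, RHS: np.ndarray) -> np.ndarray:
    """Solve x_i lhs_i = rhs_i for a stack of symmetric k-by-k systems."""
    try:
        return np.linalg.solve(lhs, RHS[..., None])[..., 0]
    except np.linalg.LinAlgError:
        warnings.warn("singular row system; using least-squares fallback", stacklevel=2)
        out = np.empty_like(RHS)
        for i in range(RHS.shape[0]):
            out[i] = np.linalg.lstsq(lhs[i], RHS[i], rcond=None)[0]
        return out


class _MFBase(BaseEstimator):
    """Shared alternating-least-squares machinery.

    Subclasses set ``model_name`` plus the ``_uses_graph`` / ``_weighted`` /
    ``_l21`` switches; ``fit`` validates, builds graphs where needed,
    initializes by SVD and iterates the engine-specific updates.
    """

    model_name: str = ""
    _uses_graph = True
    _weighted = False
    _l21 = False

    def __init__(
        self,
        k: int = 50,
        lambda_l: float = 0.5,
        lambda_d: float = 0.1,
        lambda_t: float = 0.1,
        lambda_s: float | None = None,
        p: int = 5,
        max_iter: int = 200,
        tol: float = 1e-4,
        eps_row: float = 1e-8,
        seed: int = 0,
    ):
        self.k = k
        self.lambda_l = lambda_l
        self.lambda_d = lambda_d
        self.lambda_t = lambda_t
        self.lambda_s = lambda_s
        self.p = p
        self.max_iter = max_iter
        self.tol = tol
        self.eps_row = eps_row
        self.seed = seed

    # -- engine-specific pieces -------------------------------------------
    def _update_A(self, Y, W, A, B, ctx):
        raise NotImplementedError

    def _update_B(self, Y, W, A, B, ctx):
        raise NotImplementedError

    def _objective(self, dataset, W, A, B, hp):
        graphs = getattr(self, "_graphs", None)
        Wobj = W if (self._weighted or (self.model_name == "cmf" and self._W_given)) else None
        return objective(self.model_name, dataset, graphs, Wobj, A, B, hp)

    # ----------------------------------------------------------------------
    def _hyperparams(self) -> HyperParams:
        return HyperParams(
            k=self.k,
            lambda_l=self.lambda_l,
            lambda_d=self.lambda_d,
            lambda_t=self.lambda_t,
            lambda_s=self.lambda_s if self._l21 else 0.0,
            p=self.p,
            max_iter=self.max_iter,
            tol=self.tol,
            eps_row=self.eps_row,
            seed=self.seed,
        )

    def fit(self, dataset, W: np.ndarray | None = None):
        """Fit the factors to ``dataset`` (an :class:`InteractionDataset`).

        ``W`` is the binary known-entry mask for the weighted engines (and
        optionally CMF); it defaults to all ones.
        """
        dataset.validate()
        Y = np.asarray(dataset.Y, dtype=float)
        n, m = Y.shape
        hp = self._hyperparams().validate(n, m)
        self._W_given = W is not None
        if W is not None:
            W = np.asarray(W, dtype=float)
            if W.shape != Y.shape:
                raise ValueError(f"W shape {W.shape} does not match Y {Y.shape}")
            if not np.isin(W, (0.0, 1.0)).all():
                raise ValueError("W must be binary")
            if not (self._weighted or self.model_name == "cmf"):
                raise ValueError(f"{self.model_name} does not accept a weight matrix")
        elif self._weighted:
            W = np.ones_like(Y)

        if self._uses_graph:
            self._graphs = (build_graph(dataset.Sd, hp.p), build_graph(dataset.St, hp.p))
            self.graph_d_, self.graph_t_ = self._graphs
        else:
            self._graphs = None

        A, B = svd_initialize(Y, hp.k)
        ctx = {
            "hp": hp,
            "Sd": dataset.Sd,
            "St": dataset.St,
            "Ld": self._graphs[0].L_norm if self._graphs else None,
            "Lt": self._graphs[1].L_norm if self._graphs else None,
            "lam_s": hp.resolved_lambda_s() if self._l21 else 0.0,
        }
        trace = [self._objective(dataset, W, A, B, hp)]
        converged = False
        it = 0
        for it in range(1, hp.max_iter + 1):
            A = self._update_A(Y, W, A, B, ctx)
            B = self._update_B(Y, W, A, B, ctx)
            obj = self._objective(dataset, W, A, B, hp)
            if not np.isfinite(obj):
                raise FloatingPointError(
                    f"{self.model_name}: objective became non-finite at iteration {it}"
                )
            trace.append(obj)
            if abs(trace[-1] - trace[-2]) <= hp.tol * max(abs(trace[-2]), 1e-12):
                converged = True
                break
        self.A_, self.B_ = A, B
        self.objective_trace_ = trace
        self.n_iter_ = it
        self.converged_ = converged
        self._fit_W = W
        return self

    def predict(self, dataset=None) -> np.ndarray:
        """Predicted score matrix ``A_ @ B_.T`` (n_drugs x n_targets)."""
        if not hasattr(self, "A_"):
            raise AttributeError("estimator is not fitted")
        return self.A_ @ self.B_.T

    def factors_(self) -> LatentFactors:
        return LatentFactors(
            A=self.A_,
            B=self.B_,
            trace=list(self.objective_trace_),
            iterations_run=self.n_iter_,
            converged=self.converged_,
        )

    def stationarity_residuals(self, dataset) -> tuple[float, float]:
        """Frobenius norms of the frozen-coefficient normal-equation residuals
        of the A and B updates, evaluated at the fitted (A_, B_).

        At an exact fixed point of the lagged iteration both residuals are
        zero; they quantify how close the stopping rule left the fit to
        stationarity.
        """
        Y = np.asarray(dataset.Y, dtype=float)
        hp = self._hyperparams()
        A, B, W = self.A_, self.B_, self._fit_W
        lam_l, lam_d, lam_t = hp.lambda_l, hp.lambda_d, hp.lambda_t
        lam_s = hp.resolved_lambda_s() if self._l21 else 0.0
        Ik = np.eye(hp.k)
        if self.model_name == "cmf":
            if self._W_given:
                lhsA = np.einsum("ij,ja,jb->iab", W, B, B) + lam_l * Ik + lam_d * (A.T @ A)
                RA = (A[:, None, :] @ lhsA)[:, 0, :] - ((W * Y) @ B + lam_d * dataset.Sd @ A)
                lhsB = np.einsum("ij,ia,ib->jab", W, A, A) + lam_l * Ik + lam_t * (B.T @ B)
                RB = (B[:, None, :] @ lhsB)[:, 0, :] - ((W * Y).T @ A + lam_t * dataset.St @ B)
            else:
                RA = A @ (B.T @ B + lam_l * Ik + lam_d * (A.T @ A)) - (
                    Y @ B + lam_d * dataset.Sd @ A
                )
                RB = B @ (A.T @ A + lam_l * Ik + lam_t * (B.T @ B)) - (
                    Y.T @ A + lam_t * dataset.St @ B
                )
            return float(np.linalg.norm(RA)), float(np.linalg.norm(RB))
        Ld, Lt = self._graphs[0].L_norm, self._graphs[1].L_norm
        d = l21_row_weights(B, hp.eps_row) if self._l21 else np.zeros(B.shape[0])
        if self._weighted:
            lhsA = np.einsum("ij,ja,jb->iab", W, B, B) + lam_l * Ik
            RA = (A[:, None, :] @ lhsA)[:, 0, :] - ((W * Y) @ B - lam_d * Ld @ A)
            lhsB = (
                np.einsum("ij,ia,ib->jab", W, A, A)
                + (lam_l + lam_s * d)[:, None, None] * Ik
            )
            RB = (B[:, None, :] @ lhsB)[:, 0, :] - ((W * Y).T @ A - lam_t * Lt @ B)
        else:
            RA = A @ (B.T @ B + lam_l * Ik) - (Y @ B - lam_d * Ld @ A)
            RB = B @ (A.T @ A + lam_l * Ik) + (lam_s * d)[:, None] * B - (
                Y.T @ A - lam_t * Lt @ B
            )
        return float(np.linalg.norm(RA)), float(np.linalg.norm(RB))


class CMF(_MFBase):
    """Collaborative matrix factorization: fits Sd ~ AA^T and St ~ BB^T as
    regularizers alongside the data term.  No graph construction."""

    model_name = "cmf"
    _uses_graph = False

    def _update_A(self, Y, W, A, B, ctx):
        hp = ctx["hp"]
        Ik = np.eye(hp.k)
        if W is None:
            M = B.T @ B + hp.lambda_l * Ik + hp.lambda_d * (A.T @ A)
            return _solve_spd(M, Y @ B + hp.lambda_d * ctx["Sd"] @ A)
        lhs = (
            np.einsum("ij,ja,jb->iab", W, B, B)
            + hp.lambda_l * Ik
            + hp.lambda_d * (A.T @ A)
        )
        rhs = (W * Y) @ B + hp.lambda_d * ctx["Sd"] @ A
        return _batched_row_solve(lhs, rhs)

    def _update_B(self, Y, W, A, B, ctx):
        hp = ctx["hp"]
        Ik = np.eye(hp.k)
        if W is None:
            M = A.T @ A + hp.lambda_l * Ik + hp.lambda_t * (B.T @ B)
            return _solve_spd(M, Y.T @ A + hp.lambda_t * ctx["St"] @ B)
        lhs = (
            np.einsum("ij,ia,ib->jab", W, A, A)
            + hp.lambda_l * Ik
            + hp.lambda_t * (B.T @ B)
        )
        rhs = (W * Y).T @ A + hp.lambda_t * ctx["St"] @ B
        return _batched_row_solve(lhs, rhs)


class _GraphMF(_MFBase):
    """Graph-regularized family; covers matrix updates (GRMF, L2,1-GRMF) and
    weighted row updates (WGRMF, L2,1-WGRMF) with an optional IRLS L2,1 term."""

    def _update_A(self, Y, W, A, B, ctx):
        hp = ctx["hp"]
        Ik = np.eye(hp.k)
        if not self._weighted:
            M = B.T @ B + hp.lambda_l * Ik
            return _solve_spd(M, Y @ B - hp.lambda_d * ctx["Ld"] @ A)
        lhs = np.einsum("ij,ja,jb->iab", W, B, B) + hp.lambda_l * Ik
        rhs = (W * Y) @ B - hp.lambda_d * ctx["Ld"] @ A
        return _batched_row_solve(lhs, rhs)

    def _update_B(self, Y, W, A, B, ctx):
        hp = ctx["hp"]
        Ik = np.eye(hp.k)
        lam_s = ctx["lam_s"]
        d = l21_row_weights(B, hp.eps_row) if lam_s > 0 else np.zeros(B.shape[0])
        if not self._weighted:
            RHS = Y.T @ A - hp.lambda_t * ctx["Lt"] @ B
            return _rowwise_ridge_solve(A.T @ A, hp.lambda_l + lam_s * d, RHS)
        lhs = (
            np.einsum("ij,ia,ib->jab", W, A, A)
            + (hp.lambda_l + lam_s * d)[:, None, None] * Ik
        )
        rhs = (W * Y).T @ A - hp.lambda_t * ctx["Lt"] @ B
        return _batched_row_solve(lhs, rhs)


class GRMF(_GraphMF):
    """Graph-regularized matrix factorization (matrix updates, no W)."""

    model_name = "grmf"


class WGRMF(_GraphMF):
    """Weighted GRMF: masked data term, per-row updates."""

    model_name = "wgrmf"
    _weighted = True


class L21GRMF(_GraphMF):
    """GRMF plus an L2,1 row-sparsity penalty on the target factors."""

    model_name = "l21grmf"
    _l21 = True


class L21WGRMF(_GraphMF):
    """Weighted variant of L2,1-GRMF (Eq-by-row updates with mask W)."""

    model_name = "l21wgrmf"
    _weighted = True
    _l21 = True


ENGINES: dict[str, type[_MFBase]] = {
    "cmf": CMF,
    "grmf": GRMF,
    "wgrmf": WGRMF,
    "l21grmf": L21GRMF,
    "l21wgrmf": L21WGRMF,
}


def make_engine(name: str, hp: HyperParams | None = None, **overrides) -> _MFBase:
    """Instantiate an engine by name from a :class:`HyperParams`."""
    if name not in ENGINES:
        raise ValueError(f"unknown engine {name!r}; choose from {sorted(ENGINES)}")
    hp = hp or HyperParams()
    params = dict(
        k=hp.k,
        lambda_l=hp.lambda_l,
        lambda_d=hp.lambda_d,
        lambda_t=hp.lambda_t,
        lambda_s=hp.lambda_s,
        p=hp.p,
        max_iter=hp.max_iter,
        tol=hp.tol,
        eps_row=hp.eps_row,
        seed=hp.seed,
    )
    params.update(overrides)
    return ENGINES[name](**params)


def _fit(name, dataset, W, hp) -> LatentFactors:
    est = make_engine(name, hp)
    est.fit(dataset, W=W)
    return est.factors_()


def fit_cmf(dataset, W=None, hp: HyperParams | None = None) -> LatentFactors:
    return _fit("cmf", dataset, W, hp)


def fit_grmf(dataset, hp: HyperParams | None = None) -> LatentFactors:
    return _fit("grmf", dataset, None, hp)


def fit_wgrmf(dataset, W=None, hp: HyperParams | None = None) -> LatentFactors:
    return _fit("wgrmf", dataset, W, hp)


def fit_l21grmf(dataset, hp: HyperParams | None = None) -> LatentFactors:
    return _fit("l21grmf", dataset, None, hp)


def fit_l21wgrmf(dataset, W=None, hp: HyperParams | None = None) -> LatentFactors:
    return _fit("l21wgrmf", dataset, W, hp)


def predict_scores(factors) -> np.ndarray:
    """Score matrix ``A @ B.T`` from a :class:`LatentFactors` (or fitted engine)."""
    A = getattr(factors, "A", None)
    B = getattr(factors, "B", None)
    if A is None:
        A, B = factors.A_, factors.B_
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("factors contain non-finite entries")
    return A @ B.T
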