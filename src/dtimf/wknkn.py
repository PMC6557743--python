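"""WKNKN: weighted K-nearest-known-neighbor imputation of the interaction matrix.

A 0 in the interaction matrix Y is ambiguous: a verified non-interaction or
simply an untested pair.  WKNKN replaces those zeros with interaction
likelihoods borrowed from the K most similar *known* neighbors — a drug (or
target) is "known" when it has at least one recorded interaction.  For drug d
with known neighbors d_(1..K) ordered by decreasing similarity::

    Yd(d, :) = (1/Z_d) * sum_l  eta^(l-1) * Sd(d, d_(l)) * Y(d_(l), :),
    Z_d      = sum_l Sd(d, d_(l))

and analogously Yt on the target side via St.  The two sides are averaged and
merged with the original matrix by an elementwise maximum, so known 1s are
always preserved and the output dominates the input elementwise.

The decay eta in (0, 1] discounts farther neighbors; eta -> 0 recovers the
single-nearest-neighbor rule.  Defaults K=5, eta=0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["WKNKNConfig", "wknkn_impute", "WKNKNImputer"]


@dataclass
class WKNKNConfig:
    """Neighbor count K >= 1 and decay eta in (0, 1]."""

    K: int = 5
    eta: float = 0.7

    def __post_init__(self):
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if not 0 < self.eta <= 1:
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")


def _side_estimate(Y: np.ndarray, S: np.ndarray, K: int, eta: float) -> np.ndarray:
    """Row-side estimate: for every row of Y, the decayed similarity-weighted
    average of its K nearest known rows (rows with at least one interaction)."""
    n = Y.shape[0]
    known = np.flatnonzero(Y.sum(axis=1) > 0)
    out = np.zeros_like(Y, dtype=float)
    if known.size == 0:
        return out
    if known.size < K:
        warnings.warn(
            f"only {known.size} known entities available for K={K}; using all",
            stacklevel=3,
        )
    for i in range(n):
        cand = known[known != i]
        if cand.size == 0:
            continue
        sims = S[i, cand]
        # order by similarity descending, ties toward the smaller index
        order = np.lexsort((cand, -sims))[: min(K, cand.size)]
        picked = cand[order]
        w = eta ** np.arange(picked.size) * S[i, picked]
        Z = S[i, picked].sum()
        if Z <= 0:
            continue
        out[i] = w @ Y[picked] / Z
    return out


def wknkn_impute(dataset, config: WKNKNConfig | None = None, *, K=None, eta=None) -> np.ndarray:
    """Impute unknown zeros of a dataset's interaction matrix.

    Parameters
    ----------
    dataset : InteractionDataset
        Binary Y with valid Sd/St.
    config : WKNKNConfig, optional
        K and eta; keyword overrides ``K=``/``eta=`` are also accepted.

    Returns
    -------
    ndarray
        Imputed matrix in [0, 1], elementwise >= the input Y.
    """
    if config is None:
        config = WKNKNConfig()
    if K is not None or eta is not None:
        config = WKNKNConfig(
            K=K if K is not None else config.K,
            eta=eta if eta is not None else config.eta,
        )
    Y = np.asarray(dataset.Y, dtype=float)
    Yd = _side_estimate(Y, dataset.Sd, config.K, config.eta)
    Yt = _side_estimate(Y.T, dataset.St, config.K, config.eta).T
    imputed = np.maximum(Y, (Yd + Yt) / 2.0)
    return np.clip(imputed, 0.0, 1.0)


class WKNKNImputer(BaseEstimator, TransformerMixin):
    """Transformer wrapper: ``transform(dataset)`` returns a new dataset whose
    Y is WKNKN-imputed.  Stateless (fit is a no-op), provided so preprocessing
    composes with the estimator API."""

    def __init__(self, K: int = 5, eta: float = 0.7):
        self.K = K
        self.eta = eta

    def fit(self, dataset, y=None):
        WKNKNConfig(self.K, self.eta)  # validate
        return self

    def transform(self, dataset):
        Y = wknkn_impute(dataset, WKNKNConfig(self.K, self.eta))
        return dataset.copy_with(Y)
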