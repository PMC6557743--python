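"""Reading, writing, validating and simulating drug-target interaction datasets.

A dataset is the triple (Y, Sd, St): a binary drug-target adjacency matrix
``Y`` (n drugs x m targets), a drug-drug chemical-structure similarity matrix
``Sd`` (n x n) and a target-target sequence similarity matrix ``St`` (m x m),
all with values in [0, 1].  Files follow the gold-standard convention: UTF-8
tab-delimited labeled matrices with one header row of column identifiers and a
leading column of row identifiers (the first header cell may be empty).

The public gold-standard ``_admat_dgc`` adjacency files store targets in rows,
so :func:`read_interaction_matrix` exposes an ``orientation`` flag; internally
everything is drugs x targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "InteractionDataset",
    "FormatError",
    "read_interaction_matrix",
    "read_similarity_matrix",
    "align_dataset",
    "generate_synthetic_dataset",
    "write_score_matrix",
    "write_labeled_matrix",
]

#: tolerance under which similarity asymmetry / diagonal deviation is repaired
SYMMETRY_TOL = 1e-6


class FormatError(ValueError):
    """A file does not conform to the tab-delimited labeled-matrix format."""


@dataclass
class InteractionDataset:
    """A drug-target interaction matrix with aligned similarity matrices.

    Attributes
    ----------
    drug_ids, target_ids : list of str
        Row / column identifiers of ``Y`` in order.
    Y : ndarray of shape (n_drugs, n_targets)
        Interaction matrix; {0, 1} on ingest, values in [0, 1] after WKNKN.
    Sd : ndarray of shape (n_drugs, n_drugs)
        Drug-drug similarity, symmetric with unit diagonal.
    St : ndarray of shape (n_targets, n_targets)
        Target-target similarity, symmetric with unit diagonal.
    true_factors : optional (A, B) pair
        Planted ground-truth latent factors; only set by the synthetic
        generator, for recovery experiments.
    """

    drug_ids: list[str]
    target_ids: list[str]
    Y: np.ndarray
    Sd: np.ndarray
    St: np.ndarray
    true_factors: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def validate(self) -> "InteractionDataset":
        """Check shape/range invariants; raise ``ValueError`` on violation."""
        n, m = self.n_drugs, self.n_targets
        if self.Y.shape != (n, m):
            raise ValueError(f"Y has shape {self.Y.shape}, expected {(n, m)}")
        if self.Sd.shape != (n, n):
            raise ValueError(f"Sd has shape {self.Sd.shape}, expected {(n, n)}")
        if self.St.shape != (m, m):
            raise ValueError(f"St has shape {self.St.shape}, expected {(m, m)}")
        for name, S in (("Sd", self.Sd), ("St", self.St)):
            if not np.allclose(S, S.T, atol=SYMMETRY_TOL):
                raise ValueError(f"{name} is not symmetric")
            if S.min() < -SYMMETRY_TOL or S.max() > 1 + SYMMETRY_TOL:
                raise ValueError(f"{name} has values outside [0, 1]")
        if self.Y.min() < 0 or self.Y.max() > 1:
            raise ValueError("Y has values outside [0, 1]")
        return self

    def copy_with(self, Y: np.ndarray) -> "InteractionDataset":
        """A shallow copy sharing ids/similarities but with a new Y."""
        return InteractionDataset(
            self.drug_ids, self.target_ids, Y, self.Sd, self.St, self.true_factors
        )


def _read_labeled_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: not a rectangular tab-delimited matrix: {exc}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column ids {dup}")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or empty cells detected")
    return df


def read_interaction_matrix(path, orientation: str = "targets_in_rows"):
    """Read a binary interaction matrix file.

    Parameters
    ----------
    path : str or Path
        Tab-delimited labeled matrix of 0/1 cells.
    orientation : {"drugs_in_rows", "targets_in_rows"}
        How the file is laid out.  The gold-standard ``_admat_dgc`` files are
        targets-in-rows (the default); the returned matrix is always
        drugs x targets.

    Returns
    -------
    (Y, drug_ids, target_ids)
    """
    if orientation not in ("drugs_in_rows", "targets_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_labeled_matrix(path)
    values = np.empty(df.shape, dtype=float)
    for i, (rid, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: cell ({rid!r}, {df.columns[j]!r}) is not numeric: {cell!r}"
                )
            if v not in (0.0, 1.0):
                raise ValueError(
                    f"{path}: cell ({rid!r}, {df.columns[j]!r}) = {cell!r} is not in {{0,1}}"
                )
            values[i, j] = v
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "targets_in_rows":
        return values.T.copy(), col_ids, row_ids
    return values, row_ids, col_ids


def read_similarity_matrix(path):
    """Read and validate a square similarity matrix file.

    Mild asymmetry (<= 1e-6) is repaired by averaging with the transpose and a
    near-unit diagonal is snapped to 1; anything grosser is an error.

    Returns
    -------
    (S, ids)
    """
    df = _read_labeled_matrix(path)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: similarity matrix is not square {df.shape}")
    try:
        S = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}")
    if S.min() < -SYMMETRY_TOL or S.max() > 1 + SYMMETRY_TOL:
        bad = np.unravel_index(np.argmax(np.abs(S - 0.5)), S.shape)
        raise ValueError(
            f"{path}: similarity value {S[bad]} at {bad} outside [0, 1]"
        )
    asym = np.abs(S - S.T).max()
    if asym > SYMMETRY_TOL:
        raise ValueError(f"{path}: similarity matrix asymmetric (max |S-S^T| = {asym:g})")
    S = (S + S.T) / 2.0
    diag_dev = np.abs(np.diag(S) - 1.0).max()
    if diag_dev > SYMMETRY_TOL:
        raise ValueError(f"{path}: diagonal deviates from 1 by {diag_dev:g}")
    np.fill_diagonal(S, 1.0)
    S = np.clip(S, 0.0, 1.0)
    return S, [str(x) for x in df.index]


def align_dataset(y_fragment, sd_fragment, st_fragment, verbose: bool = False):
    """Assemble an :class:`InteractionDataset` from the three file fragments.

    Reorders the similarity matrices to Y's identifier order; similarity
    entries for ids absent from Y are dropped.  Ids of Y missing from a
    similarity file are an error.
    """
    Y, drug_ids, target_ids = y_fragment
    Sd, sd_ids = sd_fragment
    St, st_ids = st_fragment

    def _perm(wanted: Sequence[str], have: Sequence[str], what: str) -> np.ndarray:
        pos = {v: i for i, v in enumerate(have)}
        missing = [v for v in wanted if v not in pos]
        if missing:
            raise ValueError(f"{what} ids missing from similarity matrix: {missing}")
        return np.array([pos[v] for v in wanted], dtype=int)

    pd_idx = _perm(drug_ids, sd_ids, "drug")
    pt_idx = _perm(target_ids, st_ids, "target")
    dropped_d = len(sd_ids) - len(drug_ids)
    dropped_t = len(st_ids) - len(target_ids)
    if verbose and (dropped_d or dropped_t):
        import sys

        print(
            f"align_dataset: dropped {dropped_d} drug and {dropped_t} target "
            "similarity entries absent from Y",
            file=sys.stderr,
        )
    ds = InteractionDataset(
        list(drug_ids),
        list(target_ids),
        np.asarray(Y, dtype=float),
        Sd[np.ix_(pd_idx, pd_idx)],
        St[np.ix_(pt_idx, pt_idx)],
    )
    return ds.validate()


def _rbf_similarity(X: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    """RBF kernel on rows of X, bandwidth = median pairwise distance,
    min-max rescaled to [0, 1], noised, symmetrized, unit diagonal."""
    d = pdist(X)
    sigma = np.median(d)
    if sigma <= 0:
        sigma = 1.0
    S = np.exp(-squareform(d) ** 2 / sigma**2)
    lo = S.min()
    if lo < 1.0:  # rescale so values span [0, 1]; diagonal stays exactly 1
        S = (S - lo) / (1.0 - lo)
    if noise > 0:
        E = rng.normal(0.0, noise, size=S.shape)
        S = S + (E + E.T) / 2.0
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_synthetic_dataset(
    n: int,
    m: int,
    k_true: int = 4,
    density: float = 0.1,
    noise: float = 0.1,
    seed: int = 0,
) -> InteractionDataset:
    """Simulate a dataset with planted low-rank interaction structure.

    Latent factors ``A* (n x k_true)`` and ``B* (m x k_true)`` are standard
    Gaussian; the interaction matrix gets 1s at the ``ceil(density*n*m)``
    largest entries of ``A* B*^T``, so with ``noise=0`` every interacting pair
    scores above every non-interacting pair.  Similarities are RBF kernels on
    the latent rows (similar drugs share latent structure, hence targets),
    which is exactly the manifold assumption the graph-regularized models
    exploit.  ``noise`` is the standard deviation of truncated Gaussian noise
    added to the similarities.

    The ground truth ``(A*, B*)`` is returned in ``dataset.true_factors``.
    Identical arguments give bit-identical output.  Drugs or targets that end
    up with no interactions are kept — they model never-tested entities, the
    very situation CVd/CVt simulates; only a completely empty Y triggers a
    re-draw (up to 10 seed-derived attempts) before erroring.
    """
    if not 0 < density < 0.5:
        raise ValueError(f"density must be in (0, 0.5), got {density}")
    if k_true > min(n, m):
        raise ValueError(f"k_true={k_true} exceeds min(n, m)={min(n, m)}")
    n_ones = int(np.ceil(density * n * m))
    for attempt in range(10):
        rng = np.random.default_rng((seed + attempt * 10007) % 2**31)
        A = rng.standard_normal((n, k_true))
        B = rng.standard_normal((m, k_true))
        scores = A @ B.T
        thresh = np.sort(scores, axis=None)[-n_ones]
        Y = (scores >= thresh).astype(float)
        if Y.sum() > 0:
            break
    else:
        raise ValueError(
            f"could not draw a non-empty Y in 10 attempts "
            f"(n={n}, m={m}, density={density})"
        )
    Sd = _rbf_similarity(A, noise, rng)
    St = _rbf_similarity(B, noise, rng)
    ds = InteractionDataset(
        drug_ids=[f"d{i}" for i in range(n)],
        target_ids=[f"t{j}" for j in range(m)],
        Y=Y,
        Sd=Sd,
        St=St,
        true_factors=(A, B),
    )
    return ds.validate()


def write_labeled_matrix(M: np.ndarray, row_ids, col_ids, path) -> None:
    """Write a labeled matrix as tab-delimited text (17 significant digits,
    so numeric round-trips are exact to well below 1e-12)."""
    M = np.asarray(M)
    if not np.isfinite(M).all():
        raise ValueError("matrix contains non-finite values")
    pd.DataFrame(M, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def write_score_matrix(scores: np.ndarray, drug_ids, target_ids, path) -> None:
    """Write a predicted drug x target score matrix to ``path``."""
    write_labeled_matrix(scores, drug_ids, target_ids, path)


def read_score_matrix(path):
    """Read back a score matrix written by :func:`write_score_matrix`."""
    df = _read_labeled_matrix(path)
    return df.to_numpy(dtype=float), [str(x) for x in df.index], [str(x) for x in df.columns]
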