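"""Evaluation protocol: CVd/CVt cross-validation, AUPR/AUC, case studies.

Interaction prediction is evaluated by hiding whole entities, not random
cells: **CVd** removes entire drug rows (can the model rank targets for a new
drug?) and **CVt** removes entire target columns (new targets).  The dataset
is split into ten folds, every fold is masked and scored once, the ten fold
AUPRs are averaged, and the whole procedure is repeated five times with fresh
partitions; the reported figure is the mean of the five repeat means, with the
standard deviation across repeats.

The primary metric is AUPR — the area under the precision-recall curve,
computed step-wise (non-interpolated) over distinct score thresholds with
tied scores grouped — because interactions are rare and AUPR punishes false
positives among the top ranks far harder than AUC does.  AUC (Mann-Whitney,
ties at 0.5) is reported alongside.

Hyperparameters are chosen per outer fold by an inner cross-validation on the
training block only, and WKNKN imputation is likewise refit inside each fold
on the masked training matrix, so no information about the held-out rows or
columns leaks into training.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

from .datasets import InteractionDataset
from .models import HyperParams, make_engine, ENGINES
from .wknkn import WKNKNConfig, wknkn_impute

__all__ = [
    "CVConfig",
    "CVSummary",
    "CaseStudyResult",
    "make_folds",
    "mask_test_block",
    "precision_recall_points",
    "aupr",
    "auc",
    "run_cross_validation",
    "case_study_mask_and_rank",
    "export_pr_curve",
    "DEFAULT_LAMBDA_L_GRID",
]

#: the grid searched for the Tikhonov coefficient
DEFAULT_LAMBDA_L_GRID = [0.25, 0.5, 1.0, 2.0]

WEIGHTED_ENGINES = {"wgrmf", "l21wgrmf"}


@dataclass
class CVConfig:
    """Cross-validation protocol parameters.

    ``grid`` maps hyperparameter names (``lambda_l``, ``lambda_d``,
    ``lambda_t``, ``lambda_s``, ``k``) to candidate lists; the default
    searches only ``lambda_l`` over {2^-2, 2^-1, 2^0, 2^1}.  A grid with a
    single combination skips the inner CV entirely.
    """

    scenario: str = "CVt"
    folds: int = 10
    repeats: int = 5
    seed: int = 0
    grid: dict[str, list] | None = None
    inner_folds: int = 3

    def __post_init__(self):
        if self.scenario not in ("CVd", "CVt"):
            raise ValueError(f"scenario must be 'CVd' or 'CVt', got {self.scenario!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.grid is not None and any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid lists must be non-empty")


@dataclass
class CVSummary:
    """Per-fold and aggregated cross-validation results."""

    scenario: str
    method: str
    use_wknkn: bool
    fold_aupr: list[list[float]]  # [repeat][fold], skipped folds omitted
    fold_auc: list[list[float]]
    chosen_params: list[list[dict]]
    repeat_mean_aupr: list[float] = field(default_factory=list)
    repeat_mean_auc: list[float] = field(default_factory=list)
    mean_aupr: float = float("nan")
    std_aupr: float = float("nan")
    mean_auc: float = float("nan")
    std_auc: float = float("nan")
    skipped_folds: list[tuple[int, int]] = field(default_factory=list)

    def finalize(self) -> "CVSummary":
        self.repeat_mean_aupr = [float(np.mean(r)) for r in self.fold_aupr if r]
        self.repeat_mean_auc = [float(np.mean(r)) for r in self.fold_auc if r]
        self.mean_aupr = float(np.mean(self.repeat_mean_aupr))
        self.std_aupr = float(np.std(self.repeat_mean_aupr))
        self.mean_auc = float(np.mean(self.repeat_mean_auc))
        self.std_auc = float(np.std(self.repeat_mean_auc))
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def make_folds(ids_count: int, folds: int, seed, scenario: str = "CVd"):
    """Seeded random partition of ``range(ids_count)`` into near-equal blocks.

    Under CVd the indices are drug rows, under CVt target columns.
    """
    if ids_count < folds:
        raise ValueError(f"cannot split {ids_count} items into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids_count)
    return [np.sort(b) for b in np.array_split(perm, folds)]


def mask_test_block(Y: np.ndarray, block, scenario: str):
    """Zero the test block's rows (CVd) or columns (CVt) of Y.

    Returns ``(train_Y, test_entries)`` where ``test_entries`` is a list of
    ``(i, j, true_label)`` for every cell of the masked rows/columns.
    """
    Y = np.asarray(Y, dtype=float)
    train_Y = Y.copy()
    block = np.asarray(block, dtype=int)
    entries = []
    if scenario == "CVd":
        train_Y[block, :] = 0.0
        for i in block:
            for j in range(Y.shape[1]):
                entries.append((int(i), int(j), float(Y[i, j])))
    elif scenario == "CVt":
        train_Y[:, block] = 0.0
        for j in block:
            for i in range(Y.shape[0]):
                entries.append((int(i), int(j), float(Y[i, j])))
    else:
        raise ValueError(f"scenario must be 'CVd' or 'CVt', got {scenario!r}")
    return train_Y, entries


def precision_recall_points(scores, labels):
    """(recall, precision) at every distinct score threshold, descending.

    Tied scores are grouped into a single threshold point; precision is
    TP/(TP+FP) and recall TP/P at each cut.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and labels must be equal-length 1-D, non-empty")
    P = labels.sum()
    if P == 0:
        raise ValueError("AUPR undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    npred = np.arange(1, s.size + 1)
    # last index of each tied group = the threshold points
    cut = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    return [(float(tp[i] / P), float(tp[i] / npred[i])) for i in cut]


def aupr(scores, labels) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve:
    ``sum_i (R_i - R_{i-1}) * P_i`` over the threshold points, R_0 = 0."""
    pts = precision_recall_points(scores, labels)
    area, r_prev = 0.0, 0.0
    for r, p in pts:
        area += (r - r_prev) * p
        r_prev = r
    return float(area)


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties counted 0.5)."""
    labels = np.asarray(labels, dtype=float)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _subset(dataset: InteractionDataset, rows=None, cols=None) -> InteractionDataset:
    rows = np.arange(dataset.n_drugs) if rows is None else np.asarray(rows, dtype=int)
    cols = np.arange(dataset.n_targets) if cols is None else np.asarray(cols, dtype=int)
    return InteractionDataset(
        [dataset.drug_ids[i] for i in rows],
        [dataset.target_ids[j] for j in cols],
        dataset.Y[np.ix_(rows, cols)],
        dataset.Sd[np.ix_(rows, rows)],
        dataset.St[np.ix_(cols, cols)],
    )


def _mask_weight(shape, block, scenario) -> np.ndarray:
    W = np.ones(shape)
    if scenario == "CVd":
        W[np.asarray(block, dtype=int), :] = 0.0
    else:
        W[:, np.asarray(block, dtype=int)] = 0.0
    return W


def _fit_and_score(dataset, train_Y, block, scenario, method, use_wknkn,
                   wknkn_config, hp: HyperParams, test_entries):
    """Fit one engine on a masked training matrix and score the test block."""
    train_ds = dataset.copy_with(train_Y)
    if use_wknkn:
        train_ds = train_ds.copy_with(wknkn_impute(train_ds, wknkn_config))
    W = _mask_weight(train_Y.shape, block, scenario) if method in WEIGHTED_ENGINES else None
    est = make_engine(method, hp)
    est.fit(train_ds, W=W)
    scores = est.predict()
    ii = np.array([e[0] for e in test_entries])
    jj = np.array([e[1] for e in test_entries])
    labels = np.array([e[2] for e in test_entries])
    return scores[ii, jj], labels


def _grid_combos(grid: dict[str, list]):
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _grid_search(train_ds, method, use_wknkn, wknkn_config, scenario,
                 inner_folds, combos, base_hp: HyperParams, seed) -> dict:
    """Pick the grid combination maximizing mean inner-CV AUPR (ties: first)."""
    count = train_ds.n_drugs if scenario == "CVd" else train_ds.n_targets
    blocks = make_folds(count, inner_folds, seed, scenario)
    masked = [mask_test_block(train_ds.Y, b, scenario) for b in blocks]
    best_combo, best_score = combos[0], -np.inf
    for combo in combos:
        hp = _apply_combo(base_hp, combo, train_ds)
        vals = []
        for block, (inner_Y, entries) in zip(blocks, masked):
            labels = np.array([e[2] for e in entries])
            if labels.sum() == 0:
                continue
            s, lab = _fit_and_score(
                train_ds, inner_Y, block, scenario, method,
                use_wknkn, wknkn_config, hp, entries,
            )
            vals.append(aupr(s, lab))
        score = float(np.mean(vals)) if vals else -np.inf
        if score > best_score:
            best_combo, best_score = combo, score
    return best_combo


def _apply_combo(base_hp: HyperParams, combo: dict, dataset) -> HyperParams:
    hp = HyperParams(**{**asdict(base_hp), **combo})
    hp.k = int(min(hp.k, dataset.n_drugs, dataset.n_targets))
    return hp


def run_cross_validation(
    dataset: InteractionDataset,
    method: str,
    use_wknkn: bool = False,
    cv: CVConfig | None = None,
    base_hp: HyperParams | None = None,
    wknkn_config: WKNKNConfig | None = None,
) -> CVSummary:
    """Full CVd/CVt protocol for one engine.

    For each repeat and fold: mask the test rows/columns, optionally impute
    the training matrix with WKNKN, select hyperparameters by inner CV on the
    training block, fit on the full masked matrix, and score the held-out
    cells with ``A B^T``.  Folds whose test block has no positive label are
    skipped with a warning (AUPR is undefined there).
    """
    if method not in ENGINES:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(ENGINES)}")
    cv = cv or CVConfig()
    base_hp = base_hp or HyperParams()
    wknkn_config = wknkn_config or WKNKNConfig()
    grid = cv.grid if cv.grid is not None else {"lambda_l": list(DEFAULT_LAMBDA_L_GRID)}
    combos = _grid_combos(grid)
    count = dataset.n_drugs if cv.scenario == "CVd" else dataset.n_targets
    summary = CVSummary(cv.scenario, method, use_wknkn, [], [], [])
    for rep in range(cv.repeats):
        rep_seed = np.random.SeedSequence([int(cv.seed), rep])
        blocks = make_folds(count, cv.folds, rep_seed, cv.scenario)
        rep_aupr, rep_auc, rep_params = [], [], []
        for fi, block in enumerate(blocks):
            train_Y, entries = mask_test_block(dataset.Y, block, cv.scenario)
            labels = np.array([e[2] for e in entries])
            if labels.sum() == 0:
                warnings.warn(
                    f"repeat {rep} fold {fi}: no positive test entry; fold skipped"
                )
                summary.skipped_folds.append((rep, fi))
                continue
            if len(combos) > 1:
                keep = np.setdiff1d(np.arange(count), block)
                inner_ds = (
                    _subset(dataset, rows=keep)
                    if cv.scenario == "CVd"
                    else _subset(dataset, cols=keep)
                )
                chosen = _grid_search(
                    inner_ds, method, use_wknkn, wknkn_config, cv.scenario,
                    cv.inner_folds, combos,
                    base_hp, np.random.SeedSequence([int(cv.seed), rep, fi]),
                )
            else:
                chosen = combos[0]
            hp = _apply_combo(base_hp, chosen, dataset)
            s, lab = _fit_and_score(
                dataset, train_Y, block, cv.scenario, method,
                use_wknkn, wknkn_config, hp, entries,
            )
            rep_aupr.append(aupr(s, lab))
            rep_auc.append(auc(s, lab))
            rep_params.append(dict(chosen))
        summary.fold_aupr.append(rep_aupr)
        summary.fold_auc.append(rep_auc)
        summary.chosen_params.append(rep_params)
    return summary.finalize()


@dataclass
class CaseStudyResult:
    """Outcome of a mask-known-interactions-then-rank simulation."""

    entity: str
    axis: str  # "drug" or "target"
    hidden: list[str]  # ids of the hidden interaction partners
    ranking: list[tuple[str, float, bool]]  # (partner_id, score, was_hidden)
    hidden_ranks: list[int]  # 1-based positions of hidden partners
    recovered_top_n: int  # hidden partners found within the first n_hide ranks

    def recovered_in_top(self, top: int) -> int:
        return sum(1 for r in self.hidden_ranks if r <= top)


def case_study_mask_and_rank(
    dataset: InteractionDataset,
    entity: str,
    n_hide: int,
    method: str = "l21grmf",
    hp: HyperParams | None = None,
    seed: int = 0,
    use_wknkn: bool = False,
    wknkn_config: WKNKNConfig | None = None,
) -> CaseStudyResult:
    """Hide ``n_hide`` known interactions of one drug/target, refit, re-rank.

    The entity's non-training partners (everything not a 1 in the training
    matrix) are ranked by predicted score, descending, ties broken by index;
    the result records where the hidden true partners land.
    """
    hp = hp or HyperParams()
    if entity in dataset.drug_ids:
        axis, idx = "drug", dataset.drug_ids.index(entity)
        partner_ids = dataset.target_ids
    elif entity in dataset.target_ids:
        axis, idx = "target", dataset.target_ids.index(entity)
        partner_ids = dataset.drug_ids
    else:
        raise ValueError(f"unknown entity {entity!r}")
    Y = np.asarray(dataset.Y, dtype=float)
    profile = Y[idx, :] if axis == "drug" else Y[:, idx]
    known = np.flatnonzero(profile == 1)
    if n_hide > known.size:
        raise ValueError(f"n_hide={n_hide} exceeds {known.size} known interactions")
    rng = np.random.default_rng(seed)
    hidden_idx = np.sort(rng.choice(known, size=n_hide, replace=False))
    train_Y = Y.copy()
    if axis == "drug":
        train_Y[idx, hidden_idx] = 0.0
    else:
        train_Y[hidden_idx, idx] = 0.0
    train_ds = dataset.copy_with(train_Y)
    if use_wknkn:
        train_ds = train_ds.copy_with(wknkn_impute(train_ds, wknkn_config))
    W = np.ones_like(Y) if method in WEIGHTED_ENGINES else None
    est = make_engine(method, hp)
    est.fit(train_ds, W=W)
    scores = est.predict()
    row = scores[idx, :] if axis == "drug" else scores[:, idx]
    train_profile = train_Y[idx, :] if axis == "drug" else train_Y[:, idx]
    candidates = np.flatnonzero(train_profile != 1)
    order = candidates[np.lexsort((candidates, -row[candidates]))]
    hidden_set = set(int(h) for h in hidden_idx)
    ranking = [(partner_ids[j], float(row[j]), int(j) in hidden_set) for j in order]
    hidden_ranks = [r + 1 for r, (_, _, h) in enumerate(ranking) if h]
    return CaseStudyResult(
        entity=entity,
        axis=axis,
        hidden=[partner_ids[int(h)] for h in hidden_idx],
        ranking=ranking,
        hidden_ranks=hidden_ranks,
        recovered_top_n=sum(1 for r in hidden_ranks if r <= max(n_hide, 1)),
    )


def export_pr_curve(points, path) -> None:
    """Write (recall, precision) pairs as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("recall\tprecision\n")
        for r, p in points:
            fh.write(f"{r:.17g}\t{p:.17g}\n")
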