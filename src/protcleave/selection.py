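"""Two-step feature selection.

Step 1 ranks all feature columns by the greedy mRMR criterion (MID form:
relevance minus mean redundancy, mutual information on 3-level discretized
codes) and keeps the top candidates. Step 2 walks the ranking prefix by
prefix, scoring each prefix with 5-fold cross-validated AUC of the SVR
pipeline, and keeps the smallest prefix achieving the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import logging

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR

log = logging.getLogger("protcleave")

N_CANDIDATES = 100  # optimal feature candidates kept after mRMR


@dataclass
class MrmrRanking:
    """Ordered column ids with per-step relevance/redundancy/score."""

    order: list[int]
    relevance: list[float]
    redundancy: list[float]
    score: list[float]

    def __len__(self) -> int:
        return len(self.order)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tcolumn\trelevance\tredundancy\tscore\n")
            for r, (c, rel, red, sc) in enumerate(
                zip(self.order, self.relevance, self.redundancy, self.score), 1
            ):
                fh.write(f"{r}\t{c}\t{rel:.6g}\t{red:.6g}\t{sc:.6g}\n")


@dataclass
class SelectionCurve:
    """Per-prefix cross-validated AUC; the chosen subset is the smallest
    prefix reaching the maximum AUC."""

    n_features: list[int]
    cv_auc: list[float]
    best_k: int
    selected: list[int]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("n_features\tcv_auc\tchosen\n")
            for k, auc in zip(self.n_features, self.cv_auc):
                fh.write(f"{k}\t{auc:.6g}\t{int(k == self.best_k)}\n")


# ---------------------------------------------------------------------------
# Discretization and mutual information
# ---------------------------------------------------------------------------


def discretize(column: np.ndarray) -> np.ndarray:
    """3-level codes {-1, 0, +1} split at mean +/- one standard deviation
    (the classic mRMR discretization). Constant columns code to all zeros."""
    column = np.asarray(column, dtype=float)
    if not np.all(np.isfinite(column)):
        raise ValueError("discretize requires finite values")
    if column.max() == column.min():  # constant column
        return np.zeros(len(column), dtype=np.int8)
    mu, sd = column.mean(), column.std()
    # Inclusive thresholds so two-valued columns (e.g. one-hot bits) keep
    # two distinct levels instead of collapsing into the middle band.
    codes = np.zeros(len(column), dtype=np.int8)
    codes[column >= mu + sd] = 1
    codes[column <= mu - sd] = -1
    return codes


def _discretize_matrix(X: np.ndarray) -> np.ndarray:
    """Column-wise 3-level codes shifted to {0, 1, 2}."""
    constant = X.max(axis=0) == X.min(axis=0)
    mu = X.mean(axis=0)
    sd = np.where(constant, 1.0, X.std(axis=0))
    codes = np.ones(X.shape, dtype=np.int8)  # level 0 -> code 1
    codes[X >= mu + sd] = 2
    codes[X <= mu - sd] = 0
    codes[:, constant] = 1
    return codes


def _mi_one_vs_all(
    z: np.ndarray, codes: np.ndarray, z_levels: int = 3, code_levels: int = 3
) -> np.ndarray:
    """Mutual information (nats) between one code column and every column
    of ``codes``, from empirical joint frequencies with 0*log0 = 0."""
    n, _ = codes.shape
    joint = np.zeros((z_levels, code_levels, codes.shape[1]))
    for a in range(z_levels):
        rows = z == a
        if not rows.any():
            continue
        sub = codes[rows]
        for b in range(code_levels):
            joint[a, b] = (sub == b).sum(axis=0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pa * pb))
    return np.nansum(terms, axis=(0, 1))


def mutual_information(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """MI (nats) between two discrete code vectors, empirical frequencies."""
    xs, x = np.unique(x_codes, return_inverse=True)
    ys, y = np.unique(y_codes, return_inverse=True)
    joint = np.zeros((len(xs), len(ys)))
    np.add.at(joint, (x, y), 1.0)
    joint /= len(x)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pa * pb))
    return float(np.nansum(terms))


# ---------------------------------------------------------------------------
# mRMR ranking
# ---------------------------------------------------------------------------


def mrmr_rank(
    X: np.ndarray, y: np.ndarray, n_candidates: int = N_CANDIDATES
) -> MrmrRanking:
    """Greedy MID mRMR: the first feature maximizes I(f; y); each next
    maximizes I(f; y) - mean over selected s of I(f; s). Deterministic;
    ties resolve to the lowest column id."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    n_candidates = min(n_candidates, X.shape[1])

    codes = _discretize_matrix(X)  # levels {0,1,2}
    y_codes = np.searchsorted(classes, y)
    relevance = _mi_one_vs_all(y_codes, codes, z_levels=len(classes))

    selected: list[int] = []
    redundancy_sum = np.zeros(X.shape[1])
    available = np.ones(X.shape[1], dtype=bool)
    rel_list, red_list, score_list = [], [], []
    for _ in range(n_candidates):
        if selected:
            red = redundancy_sum / len(selected)
        else:
            red = np.zeros(X.shape[1])
        score = relevance - red
        score_masked = np.where(available, score, -np.inf)
        pick = int(np.argmax(score_masked))  # argmax takes the lowest id on ties
        selected.append(pick)
        available[pick] = False
        rel_list.append(float(relevance[pick]))
        red_list.append(float(red[pick]))
        score_list.append(float(score[pick]))
        redundancy_sum += _mi_one_vs_all(codes[:, pick], codes)
    return MrmrRanking(
        order=selected, relevance=rel_list, redundancy=red_list, score=score_list
    )


# ---------------------------------------------------------------------------
# Forward feature selection
# ---------------------------------------------------------------------------

DEFAULT_SVR_PARAMS = {"kernel": "rbf", "C": 1.0, "gamma": "scale", "epsilon": 0.1}


def _cv_folds(y: np.ndarray, folds: int, seed: int, groups=None):
    """Stratified CV splits; when ``groups`` (substrate ids) are given the
    folds are additionally group-disjoint, so overlapping windows from one
    substrate never straddle a train/validation boundary."""
    X0 = np.zeros(len(y))
    if groups is not None:
        groups = np.asarray(groups)
        if len(np.unique(groups)) >= folds:
            sgkf = StratifiedGroupKFold(
                n_splits=folds, shuffle=True, random_state=seed
            )
            return list(sgkf.split(X0, y, groups))
        log.warning(
            "fewer groups than folds; falling back to ungrouped stratified CV"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(X0, y))


def make_fold_data(
    X: np.ndarray,
    y: np.ndarray,
    splits,
    fold_patcher=None,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Materialize per-fold (X_train, y_train, X_val, y_val) tuples.

    ``fold_patcher(X_tr, X_va, train_idx, val_idx)`` may rewrite columns
    whose values depend on the training set — notably the KNN block, whose
    reference must be restricted to the fold-training windows so no
    validation label can reach a validation feature.
    """
    folds = []
    for train_idx, val_idx in splits:
        X_tr, X_va = X[train_idx].copy(), X[val_idx].copy()
        if fold_patcher is not None:
            X_tr, X_va = fold_patcher(X_tr, X_va, train_idx, val_idx)
        folds.append((X_tr, y[train_idx], X_va, y[val_idx]))
    return folds


def cv_auc_folds(
    fold_data,
    svr_params: dict | None = None,
    columns: list[int] | None = None,
) -> float:
    """Mean AUC of a scale-then-SVR pipeline over prebuilt fold data,
    optionally restricted to a column subset."""
    params = dict(DEFAULT_SVR_PARAMS, **(svr_params or {}))
    aucs = []
    for X_tr, y_tr, X_va, y_va in fold_data:
        if columns is not None:
            X_tr, X_va = X_tr[:, columns], X_va[:, columns]
        scaler = MinMaxScaler().fit(X_tr)
        model = SVR(**params).fit(scaler.transform(X_tr), y_tr)
        aucs.append(roc_auc_score(y_va, model.predict(scaler.transform(X_va))))
    return float(np.mean(aucs))


def cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    splits,
    svr_params: dict | None = None,
    fold_patcher=None,
) -> float:
    """Mean AUC of a scale-then-SVR pipeline over fixed CV splits."""
    return cv_auc_folds(make_fold_data(X, y, splits, fold_patcher), svr_params)


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    ranking: MrmrRanking,
    folds: int = 5,
    seed: int = 0,
    svr_params: dict | None = None,
    fold_patcher=None,
    groups=None,
) -> SelectionCurve:
    """Walk the mRMR ranking prefix by prefix with a fixed fold assignment
    and keep the smallest prefix at the maximum cross-validated AUC."""
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    y = np.asarray(y).ravel()
    splits = _cv_folds(y, folds, seed, groups=groups)
    fold_data = make_fold_data(X, y, splits, fold_patcher)
    ks, aucs = [], []
    for k in range(1, len(ranking) + 1):
        try:
            auc = cv_auc_folds(fold_data, svr_params, columns=ranking.order[:k])
        except Exception as exc:  # propagate with the step index
            raise RuntimeError(f"forward selection failed at step k={k}: {exc}") from exc
        ks.append(k)
        aucs.append(auc)
    best_k = ks[int(np.argmax(aucs))]  # smallest k on plateaus
    return SelectionCurve(
        n_features=ks,
        cv_auc=aucs,
        best_k=best_k,
        selected=ranking.order[:best_k],
    )
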