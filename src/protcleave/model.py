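"""Per-protease SVR training and scoring.

A cleavage-site model is an epsilon-SVR with RBF kernel regressing 0/1
labels; its raw output, clipped to [0, 1], is read as a cleavage
propensity score. Hyperparameters come from a grid search scored by mean
5-fold cross-validated AUC on the training windows; features are min-max
scaled to [0, 1] using training statistics only. The trained bundle
carries everything scoring needs: enabled schemes, the AAindex table
version, selected feature columns, scaling parameters, the KNN reference
snapshot and a specificity-threshold table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVR

from .dataset import SampleSet, SiteWindow
from .encoders import EncodingContext, KnnReference, encode_matrix
from .evaluation import threshold_at_specificity

log = logging.getLogger("protcleave")

BUNDLE_FORMAT_VERSION = "protcleave-bundle-1"

#: LibSVM-practice grid, trimmed to exponent steps of 2^2.
DEFAULT_GRID = {
    "C": [2.0**e for e in range(-5, 6, 2)],
    "gamma": [2.0**e for e in range(-7, 4, 2)],
    "epsilon": [0.01, 0.1],
}

#: One-point grid for quick smoke runs.
FAST_GRID = {"C": [1.0], "gamma": ["scale"], "epsilon": [0.1]}

SPECIFICITY_LEVELS = (0.90, 0.95, 0.99, 1.0)


@dataclass
class ModelBundle:
    protease_id: str
    schemes: tuple[str, ...]
    aaindex_version: str | None
    selected_columns: list[int]
    column_names: list[str]
    scale_min: np.ndarray
    scale_range: np.ndarray
    hyperparams: dict
    regressor: SVR
    knn_ref: KnnReference | None
    thresholds: dict[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.scale_min) != len(self.selected_columns):
            raise ValueError("scaling parameters must cover the selected columns")
        specs = sorted(self.thresholds)
        vals = [self.thresholds[s] for s in specs]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must be monotone in specificity")


def _scale(X: np.ndarray, lo: np.ndarray, rng: np.ndarray) -> np.ndarray:
    return (X - lo) / rng


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng = np.where(rng == 0, 1.0, rng)
    return lo, rng


def _grid_points(grid: dict) -> list[dict]:
    keys = sorted(grid)
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(grid[k] for k in keys))
    ]


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    fold_patcher=None,
    groups=None,
) -> tuple[dict, float, list[float]]:
    """Exhaustive grid search by mean CV AUC with stratified folds fixed by
    the seed (group-disjoint by substrate when ``groups`` are supplied);
    returns (best params, best mean AUC, per-fold AUCs at best).
    Deterministic: on AUC ties the earliest point in sorted-key product
    order wins. ``fold_patcher`` rewrites training-set-dependent columns
    (the KNN block) per fold; see :func:`selection.make_fold_data`."""
    from .selection import _cv_folds, make_fold_data

    grid = grid or DEFAULT_GRID
    splits = _cv_folds(y, folds, seed, groups=groups)
    fold_data = make_fold_data(X, y, splits, fold_patcher)
    best: tuple[float, dict, list[float]] | None = None
    for params in _grid_points(grid):
        fold_aucs = _fold_aucs(fold_data, params)
        mean_auc = float(np.mean(fold_aucs))
        if best is None or mean_auc > best[0]:
            best = (mean_auc, params, fold_aucs)
    assert best is not None
    return best[1], best[0], best[2]


def _fold_aucs(fold_data, params: dict) -> list[float]:
    aucs = []
    for X_tr, y_tr, X_va, y_va in fold_data:
        lo, rng = _fit_scaler(X_tr)
        model = SVR(kernel="rbf", **params).fit(_scale(X_tr, lo, rng), y_tr)
        aucs.append(
            float(roc_auc_score(y_va, model.predict(_scale(X_va, lo, rng))))
        )
    return aucs


def make_knn_fold_patcher(
    windows,
    labels: np.ndarray,
    column_names: list[str],
    selected_columns: list[int] | None = None,
    blosum=None,
    k_fractions: tuple[float, ...] = (0.01, 0.03, 0.05, 0.07, 0.09),
):
    """Fold patcher recomputing the KNN block against the fold-training
    reference only, so validation labels never reach validation features.

    Returns None when no KNN columns are present. Training-fold rows use
    leave-one-out self-exclusion against their own fold reference.
    """
    from .encoders import KnnReference, knn_feature_matrix

    cols = selected_columns or list(range(len(column_names)))
    knn_positions = [
        j for j, c in enumerate(cols) if column_names[c].startswith("KNN:")
    ]
    if not knn_positions:
        return None
    window_strings = [w.window for w in windows]
    labels = np.asarray(labels)

    def patcher(X_tr, X_va, train_idx, val_idx):
        ref = KnnReference(
            windows=[window_strings[i] for i in train_idx],
            labels=labels[train_idx],
            k_fractions=k_fractions,
        )
        X_tr[:, knn_positions] = knn_feature_matrix(
            ref.windows, ref, blosum, exclude_self=True
        )
        X_va[:, knn_positions] = knn_feature_matrix(
            [window_strings[i] for i in val_idx], ref, blosum
        )
        return X_tr, X_va

    return patcher


def train(
    samples: SampleSet,
    features: np.ndarray,
    labels: np.ndarray,
    context: EncodingContext,
    column_names: list[str] | None = None,
    selected_columns: list[int] | None = None,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> ModelBundle:
    """Fit a per-protease SVR bundle from a row-aligned feature matrix.

    ``selected_columns`` restricts training to a feature subset (e.g. the
    forward-selection output); scaling, grid search and the final refit
    all see only those columns.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).ravel()
    if features.shape[0] != len(samples.windows):
        raise ValueError("features must be row-aligned to the sample set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs both classes present")
    bad = np.where(~np.isfinite(features))
    if bad[0].size:
        col = int(bad[1][0])
        name = column_names[col] if column_names else str(col)
        raise ValueError(f"non-finite feature value in column {name}")

    column_names = column_names or [str(i) for i in range(features.shape[1])]
    if selected_columns is None:
        selected_columns = list(range(features.shape[1]))
    X = features[:, selected_columns]

    patcher = make_knn_fold_patcher(
        samples.windows,
        labels,
        column_names,
        selected_columns,
        blosum=context.blosum,
        k_fractions=context.knn_ref.k_fractions if context.knn_ref else (0.01, 0.03, 0.05, 0.07, 0.09),
    )
    groups = [w.substrate_id for w in samples.windows]
    params, grid_auc, _ = grid_search_cv(
        X, labels, grid=grid, folds=folds, seed=seed, fold_patcher=patcher,
        groups=groups,
    )
    # Report performance at the chosen grid point on fold splits disjoint
    # from those the search maximised over; quoting the search maximum
    # itself would be optimistically biased.
    from .selection import _cv_folds, make_fold_data

    eval_splits = _cv_folds(labels, folds, seed + 1000003, groups=groups)
    fold_aucs = _fold_aucs(
        make_fold_data(X, labels, eval_splits, patcher), params
    )
    cv_mean = float(np.mean(fold_aucs))
    lo, rng = _fit_scaler(X)
    regressor = SVR(kernel="rbf", **params).fit(_scale(X, lo, rng), labels)
    train_scores = np.clip(regressor.predict(_scale(X, lo, rng)), 0.0, 1.0)

    neg_scores = train_scores[labels == 0]
    thresholds = {
        s: threshold_at_specificity(neg_scores, s) for s in SPECIFICITY_LEVELS
    }
    return ModelBundle(
        protease_id=samples.protease_id,
        schemes=context.schemes,
        aaindex_version=context.aaindex.version if context.aaindex else None,
        selected_columns=list(selected_columns),
        column_names=[column_names[c] for c in selected_columns],
        scale_min=lo,
        scale_range=rng,
        hyperparams=params,
        regressor=regressor,
        knn_ref=context.knn_ref,
        thresholds=thresholds,
        provenance={
            "seed": seed,
            "folds": folds,
            "cv_auc": cv_mean,
            "grid_cv_auc": grid_auc,
            "fold_aucs": fold_aucs,
            "sample_provenance": samples.provenance,
            "training_scores": train_scores,
        },
    )


def score_features(bundle: ModelBundle, features: np.ndarray) -> np.ndarray:
    """Score a full-width feature matrix with a trained bundle; raw SVR
    outputs are clipped to [0, 1]."""
    X = np.asarray(features, dtype=float)[:, bundle.selected_columns]
    scaled = _scale(X, bundle.scale_min, bundle.scale_range)
    return np.clip(bundle.regressor.predict(scaled), 0.0, 1.0)


def predict_scores(
    bundle: ModelBundle,
    windows: list[SiteWindow],
    context: EncodingContext,
) -> np.ndarray:
    """Encode windows with the bundle's schemes (using its stored KNN
    reference snapshot) and score them. The context must supply every
    provider the bundle's schemes need, with a matching AAindex version."""
    eval_ctx = EncodingContext(
        schemes=bundle.schemes,
        blosum=context.blosum,
        aaindex=context.aaindex,
        knn_ref=bundle.knn_ref,
        profiles=context.profiles,
        tracks=context.tracks,
        cksaap_k=context.cksaap_k,
    )
    if "AAINDEX" in bundle.schemes:
        ctx_version = eval_ctx.aaindex.version if eval_ctx.aaindex else None
        if ctx_version != bundle.aaindex_version:
            raise ValueError(
                f"AAindex version mismatch: bundle was trained with "
                f"{bundle.aaindex_version!r}, context supplies {ctx_version!r}"
            )
    features, _ = encode_matrix(windows, eval_ctx)
    return score_features(bundle, features)


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    joblib.dump({"format": BUNDLE_FORMAT_VERSION, "bundle": bundle}, path)


def load_bundle(path: str | Path) -> ModelBundle:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read bundle {path}: corrupt or truncated file") from exc
    if not isinstance(payload, dict) or "format" not in payload:
        raise ValueError(f"{path} is not a model bundle")
    if payload["format"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format {payload['format']!r} not supported "
            f"(expected {BUNDLE_FORMAT_VERSION!r})"
        )
    return payload["bundle"]
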