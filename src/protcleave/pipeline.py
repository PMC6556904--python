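"""End-to-end orchestration: samples -> features -> (selection) -> model.

Thin glue shared by the CLI, the example scripts and the test fixtures;
all the substance lives in the per-stage modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import SampleSet, build_samples
from .encoders import (
    EncodingContext,
    SEQUENCE_SCHEMES,
    build_knn_reference,
    encode_matrix,
)
from .io import StructuralTracks, SubstrateRecord
from .model import ModelBundle, train
from .selection import MrmrRanking, SelectionCurve, forward_select, mrmr_rank

log = logging.getLogger("protcleave")


@dataclass
class TrainingResult:
    bundle: ModelBundle
    samples: SampleSet
    context: EncodingContext
    features: np.ndarray
    manifest: list[str]
    ranking: MrmrRanking | None = None
    curve: SelectionCurve | None = None


def make_context(
    schemes: tuple[str, ...],
    samples: SampleSet | None = None,
    tracks: dict[str, StructuralTracks] | None = None,
    profiles: dict | None = None,
    aaindex=None,
) -> EncodingContext:
    """Build an encoding context, deriving the KNN reference from the
    training samples when the KNN scheme is enabled."""
    knn_ref = None
    if "KNN" in schemes:
        if samples is None:
            raise ValueError("KNN scheme needs training samples for its reference")
        knn_ref = build_knn_reference(samples.windows)
    return EncodingContext(
        schemes=schemes,
        knn_ref=knn_ref,
        tracks=tracks,
        profiles=profiles,
        aaindex=aaindex,
    )


def fit_protease_model(
    substrates: list[SubstrateRecord],
    protease_id: str,
    schemes: tuple[str, ...] = SEQUENCE_SCHEMES,
    ratio_neg_per_pos: int = 3,
    seed: int = 0,
    grid: dict | None = None,
    folds: int = 5,
    select: bool = False,
    n_candidates: int = 100,
    sa_filter: dict[str, StructuralTracks] | None = None,
    tracks: dict[str, StructuralTracks] | None = None,
    profiles: dict | None = None,
    aaindex=None,
) -> TrainingResult:
    """Assemble samples, encode features, optionally run the two-step
    feature selection (mRMR to ``n_candidates`` candidates, then forward
    selection by cross-validated AUC), and train the SVR bundle."""
    samples = build_samples(
        substrates,
        protease_id,
        ratio_neg_per_pos=ratio_neg_per_pos,
        sa_filter=sa_filter,
        seed=seed,
    )
    context = make_context(
        schemes, samples=samples, tracks=tracks, profiles=profiles, aaindex=aaindex
    )
    features, manifest = encode_matrix(
        samples.windows, context, knn_exclude_self="KNN" in context.schemes
    )
    labels = samples.labels

    ranking = curve = None
    selected = None
    if select:
        from .model import make_knn_fold_patcher

        patcher = make_knn_fold_patcher(
            samples.windows, labels, manifest, blosum=context.blosum
        )
        ranking = mrmr_rank(features, labels, n_candidates=n_candidates)
        curve = forward_select(
            features, labels, ranking, folds=folds, seed=seed,
            fold_patcher=patcher,
            groups=[w.substrate_id for w in samples.windows],
        )
        selected = curve.selected
        log.info(
            "feature selection kept %d of %d candidates", len(selected), len(ranking)
        )
    bundle = train(
        samples,
        features,
        labels,
        context,
        column_names=manifest,
        selected_columns=selected,
        grid=grid,
        folds=folds,
        seed=seed,
    )
    return TrainingResult(
        bundle=bundle,
        samples=samples,
        context=context,
        features=features,
        manifest=manifest,
        ranking=ranking,
        curve=curve,
    )
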