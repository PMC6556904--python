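"""Full-sequence cleavage-site scanning.

Every bond position of a query sequence is a candidate P1 for every
loaded protease model; scores come from the same P8-P8' feature window
used in training, while the human-readable display segment is the shorter
P4-P4' stretch with '|' marking the scissile bond.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .dataset import SiteWindow, extract_window
from .encoders import EncodingContext
from .io import SequenceRecord
from .model import ModelBundle, predict_scores

log = logging.getLogger("protcleave")

FAMILY_BY_INITIAL = {
    "A": "aspartic",
    "C": "cysteine",
    "M": "metallo",
    "S": "serine",
}

DISPLAY_FLANK = 4  # P4-P4' display segment


@dataclass(frozen=True)
class PredictionRecord:
    """One scored candidate cleavage site."""

    sequence_id: str
    p1: int
    segment: str  # P4-P4' with '|' at the scissile bond (9 chars)
    score: float
    n_fragment_size: int
    c_fragment_size: int
    protease_id: str
    family: str

    def __post_init__(self) -> None:
        if len(self.segment) != 2 * DISPLAY_FLANK + 1:
            raise ValueError("display segment must be 9 characters including '|'")


def family_of(protease_id: str) -> str:
    """Catalytic family from the MEROPS-style identifier's initial letter
    (A=aspartic, C=cysteine, M=metallo, S=serine); anything else maps to
    'other' with a warning."""
    initial = protease_id[:1].upper()
    family = FAMILY_BY_INITIAL.get(initial)
    if family is None:
        log.warning(
            "protease id %r does not start with A/C/M/S; family set to 'other'",
            protease_id,
        )
        return "other"
    return family


def display_segment(sequence: str, p1: int) -> str:
    """P4-P4' display string with '|' at the bond, 'X'-padded at termini."""
    left = sequence[max(0, p1 - DISPLAY_FLANK) : p1]
    right = sequence[p1 : p1 + DISPLAY_FLANK]
    return (
        "X" * (DISPLAY_FLANK - len(left))
        + left
        + "|"
        + right
        + "X" * (DISPLAY_FLANK - len(right))
    )


def scan(
    record: SequenceRecord,
    bundles: list[ModelBundle],
    context: EncodingContext,
    min_score: float = 0.0,
) -> list[PredictionRecord]:
    """Score every candidate P1 (positions 1..L-1) with every bundle.

    Records with score >= ``min_score`` are returned grouped by protease
    (proteases in sorted-id order) and sorted by descending score within
    each protease, position ascending on ties. Output is therefore
    invariant to the order bundles are supplied.
    """
    if not bundles:
        raise ValueError("no model bundles supplied")
    if len(record) < 2:
        raise ValueError("sequence too short to contain a scissile bond")
    seq = record.sequence
    positions = list(range(1, len(seq)))
    out: list[PredictionRecord] = []
    for bundle in sorted(bundles, key=lambda b: b.protease_id):
        windows = [
            SiteWindow(record.id, p1, extract_window(seq, p1), 0, bundle.protease_id)
            for p1 in positions
        ]
        scores = predict_scores(bundle, windows, context)
        family = family_of(bundle.protease_id)
        hits = [
            PredictionRecord(
                sequence_id=record.id,
                p1=p1,
                segment=display_segment(seq, p1),
                score=float(s),
                n_fragment_size=p1,
                c_fragment_size=len(seq) - p1,
                protease_id=bundle.protease_id,
                family=family,
            )
            for p1, s in zip(positions, scores)
            if s >= min_score
        ]
        hits.sort(key=lambda r: (-r.score, r.p1))
        out.extend(hits)
    return out


RANKING_COLUMNS = (
    "sequence_id",
    "p1",
    "segment",
    "n_fragment_size",
    "c_fragment_size",
    "score",
    "protease_id",
    "family",
)


def write_ranking_tsv(records: list[PredictionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RANKING_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sequence_id}\t{r.p1}\t{r.segment}\t{r.n_fragment_size}\t"
                f"{r.c_fragment_size}\t{r.score:.6f}\t{r.protease_id}\t{r.family}\n"
            )


def write_ranking_json(records: list[PredictionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(r) for r in records], fh, indent=1)
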