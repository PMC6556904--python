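"""Training-set construction.

Homology reduction, substrate-level train/test splitting, P8-P8' window
extraction around candidate scissile bonds, and balanced positive/negative
sample assembly with 1:3 down-sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ALPHABET, SequenceRecord, StructuralTracks, SubstrateRecord

log = logging.getLogger("protcleave")

#: Residues on each side of the scissile bond in a feature window.
FLANK = 8
#: Total window length (P8..P1 | P1'..P8').
WINDOW_SIZE = 2 * FLANK


@dataclass(frozen=True)
class SiteWindow:
    """A 16-residue P8-P8' peptide around one candidate scissile bond.

    ``p1`` is the 1-based index of the P1 residue in the parent substrate;
    positions beyond either terminus are padded with 'X'. ``label`` is 1
    for an annotated cleavage site, 0 otherwise.
    """

    substrate_id: str
    p1: int
    window: str
    label: int
    protease_id: str

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_SIZE:
            raise ValueError(
                f"window must have exactly {WINDOW_SIZE} residues, "
                f"got {len(self.window)}"
            )
        if set(self.window) - set(ALPHABET):
            raise ValueError("window contains letters outside the alphabet")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class SampleSet:
    """Labelled windows for one protease, with split/seed provenance."""

    windows: list[SiteWindow]
    protease_id: str
    provenance: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    def positives(self) -> list[SiteWindow]:
        return [w for w in self.windows if w.label == 1]

    def negatives(self) -> list[SiteWindow]:
        return [w for w in self.windows if w.label == 0]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("substrate_id\tp1\twindow\tlabel\tprotease_id\n")
            for w in self.windows:
                fh.write(
                    f"{w.substrate_id}\t{w.p1}\t{w.window}\t{w.label}\t"
                    f"{w.protease_id}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"substrate_id": str})
        windows = [
            SiteWindow(
                substrate_id=row.substrate_id,
                p1=int(row.p1),
                window=row.window,
                label=int(row.label),
                protease_id=row.protease_id,
            )
            for row in df.itertuples(index=False)
        ]
        pids = {w.protease_id for w in windows}
        if len(pids) != 1:
            raise ValueError(f"sample TSV mixes proteases: {sorted(pids)}")
        return cls(windows=windows, protease_id=pids.pop())


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def extract_window(sequence: str, p1: int) -> str:
    """P8-P8' window around the bond between residues ``p1`` and ``p1+1``.

    1-based convention: the window covers residues p1-7..p1 then
    p1+1..p1+8; positions beyond either terminus are filled with 'X'.
    """
    n = len(sequence)
    if not (1 <= p1 < n):
        raise ValueError(f"p1={p1} out of range 1..{n - 1}")
    left = sequence[max(0, p1 - FLANK) : p1]
    right = sequence[p1 : p1 + FLANK]
    return "X" * (FLANK - len(left)) + left + right + "X" * (FLANK - len(right))


# ---------------------------------------------------------------------------
# Homology reduction
# ---------------------------------------------------------------------------


def kmer_identity(a: str, b: str, k: int = 5) -> float:
    """Shared-k-mer identity estimate: fraction of distinct k-mers of the
    shorter sequence also present in the longer one (CD-HIT-like word
    filter)."""
    if len(a) > len(b):
        a, b = b, a
    if len(a) < k:
        return 1.0 if a in b else 0.0
    kmers_a = {a[i : i + k] for i in range(len(a) - k + 1)}
    kmers_b = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(kmers_a & kmers_b) / len(kmers_a)


def reduce_redundancy(
    records: list[SequenceRecord],
    identity_threshold: float = 0.70,
    seed: int | None = None,
    word_size: int = 5,
) -> list[SequenceRecord]:
    """Greedy incremental clustering, longest sequence first.

    A sequence joins an existing cluster when its estimated identity to the
    cluster representative reaches the threshold; one representative per
    cluster is returned (in original input order). Deterministic given the
    input order; ``seed`` is accepted for interface symmetry.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must lie in (0, 1]")
    order = sorted(
        range(len(records)), key=lambda i: (-len(records[i].sequence), i)
    )
    representatives: list[int] = []
    for i in order:
        seq = records[i].sequence
        if all(
            kmer_identity(seq, records[j].sequence, k=word_size)
            < identity_threshold
            for j in representatives
        ):
            representatives.append(i)
    kept = sorted(representatives)
    return [records[i] for i in kept]


def apply_cluster_file(
    records: list[SequenceRecord], path
) -> list[SequenceRecord]:
    """Homology reduction from a precomputed cluster table (e.g. exported
    from an exact clustering tool), substituting for the built-in k-mer
    estimator. TSV columns: sequence_id, cluster_id; the first member of
    each cluster in file order is kept as representative."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sequence_id", "cluster_id"} <= set(df.columns):
        raise ValueError("cluster file needs columns sequence_id, cluster_id")
    by_id = {r.id: r for r in records}
    unknown = set(df["sequence_id"]) - set(by_id)
    if unknown:
        raise ValueError(f"cluster file names unknown sequences: {sorted(unknown)[:5]}")
    keep: dict[str, str] = {}
    for row in df.itertuples(index=False):
        keep.setdefault(row.cluster_id, row.sequence_id)
    kept_ids = set(keep.values())
    return [r for r in records if r.id in kept_ids]


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


def split_train_test(
    substrates: list[SubstrateRecord],
    train_fraction: float = 5 / 6,
    seed: int = 0,
) -> tuple[list[SubstrateRecord], list[SubstrateRecord]]:
    """Random substrate-level split (never window-level); reproducible."""
    if len(substrates) < 2:
        raise ValueError("need at least 2 substrates to split")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(substrates))
    n_train = int(round(train_fraction * len(substrates)))
    n_train = min(max(n_train, 1), len(substrates) - 1)
    train_idx = sorted(perm[:n_train])
    test_idx = sorted(perm[n_train:])
    return (
        [substrates[i] for i in train_idx],
        [substrates[i] for i in test_idx],
    )


# ---------------------------------------------------------------------------
# Sample construction
# ---------------------------------------------------------------------------


def build_samples(
    substrates: list[SubstrateRecord],
    protease_id: str,
    ratio_neg_per_pos: int = 3,
    sa_filter: dict[str, StructuralTracks] | None = None,
    seed: int = 0,
    split_tag: str = "train",
) -> SampleSet:
    """Positive windows at annotated P1 sites plus down-sampled negatives.

    Positives are every annotated P1 for ``protease_id``. Candidate
    negatives are all other bond positions on the same substrates,
    excluding positions annotated for this protease (other proteases'
    sites may serve as negatives). When ``sa_filter`` supplies structural
    tracks, candidates are restricted to buried P1 residues, emulating the
    solvent-inaccessibility filter used to pick reliable non-cleavage
    sites; if that leaves no candidates the filter is dropped with a
    warning. Negatives are then down-sampled uniformly without replacement
    (pooled across substrates) to ``ratio_neg_per_pos`` per positive.
    """
    positives: list[SiteWindow] = []
    candidates: list[tuple[str, int, str]] = []  # (substrate_id, p1, window)
    for sub in substrates:
        annotated = sub.p1_positions(protease_id)
        seq = sub.sequence
        for p1 in sorted(annotated):
            positives.append(
                SiteWindow(sub.id, p1, extract_window(seq, p1), 1, protease_id)
            )
        tracks = sa_filter.get(sub.id) if sa_filter is not None else None
        for p1 in range(1, len(seq)):
            if p1 in annotated:
                continue
            if tracks is not None and tracks.sa_state[p1 - 1] != "B":
                continue
            candidates.append((sub.id, p1, extract_window(seq, p1)))
    if not positives:
        raise ValueError(f"no annotated cleavage sites for {protease_id!r}")

    sa_fallback = False
    if sa_filter is not None and not candidates:
        log.warning(
            "solvent-accessibility filter removed every negative candidate; "
            "falling back to unfiltered candidates"
        )
        sa_fallback = True
        for sub in substrates:
            annotated = sub.p1_positions(protease_id)
            for p1 in range(1, len(sub.sequence)):
                if p1 not in annotated:
                    candidates.append(
                        (sub.id, p1, extract_window(sub.sequence, p1))
                    )

    n_wanted = ratio_neg_per_pos * len(positives)
    rng = np.random.default_rng(seed)
    if len(candidates) <= n_wanted:
        if len(candidates) < n_wanted:
            log.warning(
                "only %d negative candidates available for %d requested; "
                "keeping all",
                len(candidates),
                n_wanted,
            )
        chosen = list(range(len(candidates)))
    else:
        chosen = sorted(rng.choice(len(candidates), size=n_wanted, replace=False))
    negatives = [
        SiteWindow(sid, p1, win, 0, protease_id)
        for sid, p1, win in (candidates[i] for i in chosen)
    ]
    return SampleSet(
        windows=positives + negatives,
        protease_id=protease_id,
        provenance={
            "split": split_tag,
            "seed": seed,
            "ratio_neg_per_pos": ratio_neg_per_pos,
            "sa_filtered": sa_filter is not None and not sa_fallback,
            "sa_fallback": sa_fallback,
            "n_pos": len(positives),
            "n_neg": len(negatives),
        },
    )
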