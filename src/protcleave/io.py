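"""Readers, writers and reference matrices.

Everything the pipeline consumes from disk comes through here: FASTA
substrate sequences, cleavage-site annotation tables, PSI-BLAST ASCII
profiles, aaindex1 flat files and per-residue structural track tables.
The BLOSUM62 substitution matrix ships with the package (via Biopython)
extended with an all-zero row/column for the gap-filling residue 'X'.

Coordinates are 1-based throughout: a cleavage event at ``p1`` means the
scissile bond lies between residues ``p1`` (P1) and ``p1 + 1`` (P1').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

log = logging.getLogger("protcleave")

#: The 20 standard amino acids, in the fixed alphabetical order used by
#: every positional encoder.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: 21-letter alphabet: the standard residues plus 'X' for unknown/padding.
ALPHABET = AA20 + "X"

_AA20_SET = frozenset(AA20)
_ALPHABET_SET = frozenset(ALPHABET)

#: Index of each alphabet letter, for fast vectorised lookups.
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


class InputError(ValueError):
    """Malformed or inconsistent user input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence over the 21-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise InputError(
                f"record {self.id!r}: characters {sorted(bad)} outside the "
                f"21-letter alphabet; normalize first"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SubstrateRecord:
    """A substrate sequence plus its annotated cleavage events.

    ``events`` holds ``(protease_id, p1)`` pairs with 1-based ``p1``;
    cleavage is between residues ``p1`` and ``p1 + 1``, so ``p1`` must
    leave at least one residue on the C-terminal side.
    """

    record: SequenceRecord
    events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.record)
        seen = set()
        for protease_id, p1 in self.events:
            if not (1 <= p1 < n):
                raise InputError(
                    f"substrate {self.record.id!r}: P1 position {p1} out of "
                    f"range 1..{n - 1} (P1' must exist)"
                )
            key = (protease_id, p1)
            if key in seen:
                raise InputError(
                    f"substrate {self.record.id!r}: duplicate event {key}"
                )
            seen.add(key)

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def sequence(self) -> str:
        return self.record.sequence

    def p1_positions(self, protease_id: str) -> set[int]:
        return {p for pid, p in self.events if pid == protease_id}


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Square residue-pair score table over an ordered alphabet."""

    alphabet: str
    scores: np.ndarray  # (len(alphabet), len(alphabet)), integer-valued

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError("score table shape does not match alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self.alphabet.index(a), self.alphabet.index(b)])


@dataclass
class ResidueProfile:
    """Per-residue position-specific scores (one 20-vector per residue).

    Rows follow the sequence; columns follow :data:`AA20` order.
    """

    sequence_id: str
    scores: np.ndarray  # (L, 20)

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("profile must have exactly 20 score columns")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class StructuralTracks:
    """Predicted per-residue structure: secondary structure (H/E/C),
    solvent accessibility state (B=buried / E=exposed) with optional real
    accessibility in [0, 1], and disorder probability in [0, 1]."""

    ss: str
    sa_state: str
    diso: np.ndarray
    sa_value: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ss)
        if len(self.sa_state) != n or len(self.diso) != n:
            raise ValueError("structural tracks must all have equal length")
        if self.sa_value is not None and len(self.sa_value) != n:
            raise ValueError("sa_value length mismatch")
        if set(self.ss) - set("HEC"):
            raise ValueError("secondary-structure states must be H/E/C")
        if set(self.sa_state) - set("BE"):
            raise ValueError("accessibility states must be B/E")
        if np.any((self.diso < 0) | (self.diso > 1)):
            raise ValueError("disorder probabilities must lie in [0, 1]")
        if self.sa_value is not None and np.any(
            (self.sa_value < 0) | (self.sa_value > 1)
        ):
            raise ValueError("accessibility values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ss)


# ---------------------------------------------------------------------------
# Sequence I/O
# ---------------------------------------------------------------------------

_REMAP = set("BZUOJ*-")


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase and map non-standard letters (B, Z, U, O, J, *, -) to 'X'.

    Unrecognized characters are also mapped to 'X'; every remap is logged.
    """
    seq = raw.upper()
    remapped = sorted({c for c in seq if c not in _ALPHABET_SET})
    if remapped:
        log.warning(
            "record %s: mapping non-standard characters %s to 'X'",
            record_id,
            remapped,
        )
        seq = "".join(c if c in _ALPHABET_SET else "X" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into normalized SequenceRecords."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise InputError(f"record {rec.id!r}: empty sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("substrate_id", "protease_id", "p1")


def read_annotations(
    path: str | Path, records: list[SequenceRecord]
) -> list[SubstrateRecord]:
    """Join a cleavage-annotation TSV against a FASTA record set.

    The TSV needs a header line with columns substrate_id, protease_id, p1
    (1-based P1 residue index). Rows naming unknown substrates or carrying
    out-of-range positions are rejected; duplicates are dropped with a
    warning. Returns one SubstrateRecord per annotated substrate, in FASTA
    order.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"substrate_id": str, "protease_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"annotation file missing columns: {sorted(missing)}")
    by_id = {r.id: r for r in records}
    events: dict[str, list[tuple[str, int]]] = {}
    seen: set[tuple[str, str, int]] = set()
    for row in df.itertuples(index=False):
        sid, pid, p1 = str(row.substrate_id), str(row.protease_id), int(row.p1)
        if sid not in by_id:
            raise InputError(f"annotation references unknown substrate {sid!r}")
        n = len(by_id[sid])
        if not (1 <= p1 < n):
            raise InputError(
                f"substrate {sid!r}: P1={p1} out of range 1..{n - 1} "
                f"(cleavage needs a P1' residue)"
            )
        key = (sid, pid, p1)
        if key in seen:
            log.warning("duplicate annotation row %s dropped", key)
            continue
        seen.add(key)
        events.setdefault(sid, []).append((pid, p1))
    return [
        SubstrateRecord(record=rec, events=events[rec.id])
        for rec in records
        if rec.id in events
    ]


def write_annotations(substrates: list[SubstrateRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for sub in substrates:
            for pid, p1 in sub.events:
                fh.write(f"{sub.id}\t{pid}\t{p1}\n")


# ---------------------------------------------------------------------------
# Reference matrices and profiles
# ---------------------------------------------------------------------------


def load_blosum62() -> SubstitutionMatrix:
    """Standard BLOSUM62 over the 20 residues, plus an all-zero 'X' row
    and column so scoring is well-defined on padded windows."""
    src = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    scores = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            scores[i, j] = int(src[a, b])
    return SubstitutionMatrix(alphabet=ALPHABET, scores=scores)


# PSI-BLAST ASCII PSSM column order (the first 20 score columns).
_PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"
_PSIBLAST_TO_AA20 = [_PSIBLAST_ORDER.index(a) for a in AA20]


def parse_pssm(path: str | Path, sequence_id: str = "?") -> ResidueProfile:
    """Parse a PSI-BLAST ASCII PSSM, keeping the log-odds score block
    (the first 20 numeric columns of each residue row)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            # Residue rows look like: <pos> <aa> <20 or 40 ints> [stats]
            if len(parts) >= 2 and parts[0].isdigit() and parts[1].isalpha() and len(parts[1]) == 1:
                nums = []
                for tok in parts[2:]:
                    try:
                        nums.append(float(tok))
                    except ValueError:
                        break
                if len(nums) < 20:
                    raise InputError(
                        f"{path}: line {lineno}: expected >=20 score columns, "
                        f"found {len(nums)}"
                    )
                rows.append([nums[k] for k in range(20)])
    if not rows:
        raise InputError(f"{path}: no PSSM residue rows found")
    arr = np.asarray(rows, dtype=float)[:, :20]
    return ResidueProfile(sequence_id=sequence_id, scores=arr[:, _PSIBLAST_TO_AA20])


# ---------------------------------------------------------------------------
# aaindex1 flat file
# ---------------------------------------------------------------------------

# aaindex1 'I' records list values for: first line A R N D C Q E G H I,
# second line L K M F P S T W Y V.
_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AAINDEX_TO_AA20 = [_AAINDEX_ORDER.index(a) for a in AA20]


def parse_aaindex(path: str | Path) -> dict[str, np.ndarray]:
    """Parse an aaindex1 flat file into ``{accession: 20 values}``.

    Values are reordered to :data:`AA20`. Indices containing missing
    ('NA') entries are excluded (the count is logged).
    """
    indices: dict[str, np.ndarray] = {}
    dropped = 0
    accession = None
    collecting = False
    values: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:1]
            if tag == "H":
                accession = line[1:].strip()
                collecting = False
                values = []
            elif tag == "I":
                collecting = True
                values = []
            elif collecting and tag == " ":
                values.extend(line.split())
            elif line.startswith("//"):
                if accession is not None and values:
                    if len(values) != 20:
                        raise InputError(
                            f"{path}: line {lineno}: index {accession} has "
                            f"{len(values)} values, expected 20"
                        )
                    if any(v.upper() == "NA" for v in values):
                        dropped += 1
                    else:
                        arr = np.asarray([float(v) for v in values])
                        indices[accession] = arr[_AAINDEX_TO_AA20]
                accession = None
                collecting = False
                values = []
            elif collecting and tag not in " I":
                collecting = False
    if dropped:
        log.info("parse_aaindex: excluded %d indices with missing values", dropped)
    if not indices:
        raise InputError(f"{path}: no complete aaindex1 records found")
    return indices


# ---------------------------------------------------------------------------
# Structural tracks
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ("pos", "ss", "sa_state", "sa_value", "diso")


def parse_tracks(path: str | Path) -> StructuralTracks:
    """Parse a per-residue structural annotation TSV.

    Columns: pos (1-based), ss (H/E/C), sa_state (B/E), sa_value in [0,1]
    (or NA), diso in [0,1]. Rows must cover positions 1..L contiguously.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"tracks file missing columns: {sorted(missing)}")
    df = df.sort_values("pos")
    pos = df["pos"].to_numpy()
    if not np.array_equal(pos, np.arange(1, len(df) + 1)):
        raise InputError(f"{path}: positions must cover 1..L contiguously")
    sa_value = None
    if not df["sa_value"].isna().all():
        sa_value = df["sa_value"].astype(float).to_numpy()
    return StructuralTracks(
        ss="".join(df["ss"].astype(str)),
        sa_state="".join(df["sa_state"].astype(str)),
        diso=df["diso"].astype(float).to_numpy(),
        sa_value=sa_value,
    )


def write_tracks(tracks: StructuralTracks, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRACK_COLUMNS) + "\n")
        for i in range(len(tracks)):
            sa_val = "NA" if tracks.sa_value is None else f"{tracks.sa_value[i]:.4f}"
            fh.write(
                f"{i + 1}\t{tracks.ss[i]}\t{tracks.sa_state[i]}\t{sa_val}\t"
                f"{tracks.diso[i]:.4f}\n"
            )
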