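"""Synthetic substrate datasets with planted cleavage motifs.

Emulates a MEROPS-style substrate collection without any download:
background sequences are i.i.d. over the 20 standard residues and each
annotated cleavage site carries a 16-column position-weight-matrix motif
redrawn over the P8-P8' window. A ``strength`` dial interpolates each PWM
column with the uniform background, so strength 0 plants nothing and
strength 1 draws straight from the motif. Optional structural tracks come
from simple two-state Markov chains. Everything is reproducible from a
seed, and the emitted FASTA/annotation/track files are exactly what the
real pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import FLANK
from .io import (
    AA20,
    SequenceRecord,
    StructuralTracks,
    SubstrateRecord,
    write_annotations,
    write_fasta,
    write_tracks,
)

#: Reserved identifier for synthetic motifs: the initial letter is not a
#: real catalytic-family code, so family mapping warns instead of
#: mislabelling.
SYNTHETIC_PROTEASE_ID = "X01.001"

_D = AA20.index("D")
_G = AA20.index("G")

# Window column layout: P8..P1 are columns 0..7, P1'..P8' are 8..15.
P_COLUMN = {f"P{FLANK - i}": i for i in range(FLANK)}
P_COLUMN.update({f"P{i + 1}'": FLANK + i for i in range(FLANK)})


@dataclass
class MotifModel:
    """A 16-column x 20-residue position weight matrix with an
    interpolation weight toward uniform background."""

    name: str
    pwm: np.ndarray  # (16, 20), rows sum to 1
    strength: float

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (2 * FLANK, 20):
            raise ValueError("PWM must be 16 positions x 20 residues")
        if not np.allclose(self.pwm.sum(axis=1), 1.0):
            raise ValueError("each PWM column must sum to 1")
        if not (0 <= self.strength <= 1):
            raise ValueError("strength must lie in [0, 1]")

    def effective_pwm(self) -> np.ndarray:
        """strength * PWM + (1 - strength) * uniform background."""
        return self.strength * self.pwm + (1 - self.strength) / 20.0


def _uniform_pwm() -> np.ndarray:
    return np.full((2 * FLANK, 20), 1 / 20)


def caspase_like_motif(strength: float = 0.9) -> MotifModel:
    """Caspase-style specificity: a near-absolute Asp requirement at P1
    and a strong, less selective Asp preference at P4 (the canonical DxxD
    pattern); other columns are uniform background."""
    pwm = _uniform_pwm()
    for pos, weight in (("P1", 0.99), ("P4", 0.85)):
        col = np.full(20, (1 - weight) / 19)
        col[_D] = weight
        pwm[P_COLUMN[pos]] = col
    return MotifModel(name="caspase-like", pwm=pwm, strength=strength)


def gly_rich_motif(strength: float = 0.9) -> MotifModel:
    """MMP-style specificity: Gly overrepresented at P7, P4, P2, P1, P3'
    and P6'; other columns uniform."""
    pwm = _uniform_pwm()
    for pos in ("P7", "P4", "P2", "P1", "P3'", "P6'"):
        col = np.full(20, 0.4 / 19)
        col[_G] = 0.6
        pwm[P_COLUMN[pos]] = col
    return MotifModel(name="gly-rich", pwm=pwm, strength=strength)


def _markov_states(rng, n: int, states: str, persistence: float = 0.8) -> str:
    out = [rng.integers(len(states))]
    for _ in range(n - 1):
        if rng.random() < persistence:
            out.append(out[-1])
        else:
            out.append(rng.integers(len(states)))
    return "".join(states[i] for i in out)


def _synthetic_tracks(rng, n: int) -> StructuralTracks:
    ss = _markov_states(rng, n, "HEC")
    sa_state = _markov_states(rng, n, "BE")
    sa_value = np.where(
        np.frombuffer(sa_state.encode(), dtype="S1") == b"B",
        rng.uniform(0.0, 0.25, size=n),
        rng.uniform(0.25, 1.0, size=n),
    )
    diso_state = _markov_states(rng, n, "OD")  # ordered/disordered
    diso = np.where(
        np.frombuffer(diso_state.encode(), dtype="S1") == b"D",
        rng.uniform(0.5, 1.0, size=n),
        rng.uniform(0.0, 0.3, size=n),
    )
    return StructuralTracks(ss=ss, sa_state=sa_state, diso=diso, sa_value=sa_value)


def generate_substrates(
    n: int,
    motif: MotifModel,
    length_range: tuple[int, int] = (80, 160),
    sites_per_substrate: int = 2,
    protease_id: str = SYNTHETIC_PROTEASE_ID,
    seed: int = 0,
    with_tracks: bool = False,
) -> tuple[list[SubstrateRecord], dict[str, StructuralTracks] | None]:
    """Generate ``n`` substrates with planted, annotated cleavage sites.

    Background residues are i.i.d. uniform over the 20 letters. For each
    planted site the 16 residues around an internal P1 (drawn uniformly,
    windows non-overlapping and away from either terminus) are redrawn
    from the strength-interpolated PWM. Raises if the requested sites
    cannot be placed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 40:
        raise ValueError("substrate lengths must be >= 40")
    rng = np.random.default_rng(seed)
    eff = motif.effective_pwm()
    substrates: list[SubstrateRecord] = []
    tracks: dict[str, StructuralTracks] = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = rng.integers(0, 20, size=length)
        placed: list[int] = []
        for _ in range(sites_per_substrate):
            for _attempt in range(1000):
                p1 = int(rng.integers(FLANK, length - FLANK + 1))
                if all(abs(p1 - q) >= 2 * FLANK for q in placed):
                    placed.append(p1)
                    break
            else:
                raise ValueError(
                    f"cannot place {sites_per_substrate} non-overlapping "
                    f"sites in a length-{length} sequence"
                )
            # Redraw the P8-P8' window (0-based slice p1-8 .. p1+7).
            for col in range(2 * FLANK):
                residues[p1 - FLANK + col] = rng.choice(20, p=eff[col])
        seq = "".join(AA20[r] for r in residues)
        sid = f"syn{i + 1:04d}"
        substrates.append(
            SubstrateRecord(
                record=SequenceRecord(id=sid, sequence=seq),
                events=[(protease_id, p1) for p1 in sorted(placed)],
            )
        )
        if with_tracks:
            tracks[sid] = _synthetic_tracks(rng, length)
    return substrates, (tracks if with_tracks else None)


def write_dataset(
    substrates: list[SubstrateRecord],
    prefix: str | Path,
    tracks: dict[str, StructuralTracks] | None = None,
) -> dict[str, Path]:
    """Write FASTA + annotations TSV (+ per-substrate tracks TSVs) under a
    common path prefix; returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.with_suffix(".fasta")
    annot = prefix.with_suffix(".annotations.tsv")
    write_fasta([s.record for s in substrates], fasta)
    write_annotations(substrates, annot)
    paths = {"fasta": fasta, "annotations": annot}
    if tracks:
        track_dir = prefix.parent / f"{prefix.name}_tracks"
        track_dir.mkdir(exist_ok=True)
        for sid, tr in tracks.items():
            write_tracks(tr, track_dir / f"{sid}.tsv")
        paths["tracks_dir"] = track_dir
    return paths
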