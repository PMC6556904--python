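"""Feature encoding schemes for 16-residue cleavage-site windows.

Eleven schemes map a P8-P8' window (plus optional evolutionary profiles
and predicted structural tracks) onto a fixed-order numeric vector:

===========  ====  =========================================================
scheme        dim  content
===========  ====  =========================================================
BINARY        336  21-bit one-hot per position (20 residues + 'X')
CKSAAP       2400  k-spaced amino-acid pair composition, k = 0..5
KNN             5  fraction of positives among the top-K most similar
                   reference windows, K at 1/3/5/7/9% of the reference size
AAC            20  residue composition of the window
PSSM          320  logistic-squashed PSI-BLAST profile rows
BLOSUM        336  BLOSUM62 row of each window residue
AAINDEX      1024  64 physicochemical indices per position, min-max scaled
CHR             9  net charge, hydropathy and charge/hydropathy ratio over
                   the N-side, C-side and full window
SS             48  3-state secondary-structure one-hot per position
SA             32  2-state solvent-accessibility one-hot per position
DISO           32  (p_disorder, 1 - p_disorder) per position
===========  ====  =========================================================

All eleven together give a 4562-component vector. Encoders are pure
functions of their inputs; every component carries a manifest name
mapping it back to (scheme, position, residue/pair/index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import FLANK, WINDOW_SIZE, SiteWindow
from .io import (
    AA20,
    AA_INDEX,
    ALPHABET,
    ResidueProfile,
    StructuralTracks,
    SubstitutionMatrix,
    load_blosum62,
)

SCHEME_ORDER = (
    "BINARY",
    "CKSAAP",
    "KNN",
    "AAC",
    "PSSM",
    "BLOSUM",
    "AAINDEX",
    "CHR",
    "SS",
    "SA",
    "DISO",
)

SCHEME_DIMS = {
    "BINARY": 336,
    "CKSAAP": 2400,
    "KNN": 5,
    "AAC": 20,
    "PSSM": 320,
    "BLOSUM": 336,
    "AAINDEX": 1024,
    "CHR": 9,
    "SS": 48,
    "SA": 32,
    "DISO": 32,
}

#: Schemes computable from the window string alone (no profiles, tracks or
#: reference set needed).
SEQUENCE_SCHEMES = ("BINARY", "CKSAAP", "AAC", "BLOSUM", "AAINDEX", "CHR")

FULL_DIM = sum(SCHEME_DIMS.values())  # 4562

#: Position labels P8..P1 then P1'..P8'.
POSITION_LABELS = [f"P{FLANK - i}" for i in range(FLANK)] + [
    f"P{i + 1}'" for i in range(FLANK)
]

# Kyte-Doolittle hydropathy scale, keyed to AA20 order.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}
KYTE_DOOLITTLE = np.array([_KD[a] for a in AA20])
_CHARGE = {"K": 1.0, "R": 1.0, "H": 1.0, "D": -1.0, "E": -1.0}
CHARGE = np.array([_CHARGE.get(a, 0.0) for a in AA20])


@dataclass(frozen=True)
class FeatureBlock:
    """One scheme's ordered components plus their manifest names."""

    name: str
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        expected = SCHEME_DIMS[self.name]
        # KNN width follows the configured k-fractions (5 by default).
        if self.name != "KNN" and self.values.shape != (expected,):
            raise ValueError(
                f"{self.name} block must have {expected} components, "
                f"got {self.values.shape}"
            )
        if len(self.names) != len(self.values):
            raise ValueError(f"{self.name} manifest length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.name} block contains non-finite values")

    @property
    def dim(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered concatenation of FeatureBlocks."""

    blocks: tuple[FeatureBlock, ...]

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([b.values for b in self.blocks])

    @property
    def names(self) -> list[str]:
        return [n for b in self.blocks for n in b.names]

    @property
    def total_dim(self) -> int:
        return sum(b.dim for b in self.blocks)


def window_indices(window: str) -> np.ndarray:
    """Alphabet index of each window residue (X = 20)."""
    try:
        return np.array([AA_INDEX[c] for c in window], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in window") from exc


# ---------------------------------------------------------------------------
# Sequence-derived schemes
# ---------------------------------------------------------------------------


def encode_binary(window: str) -> FeatureBlock:
    """21-bit one-hot per window position (alphabet ACDEFGHIKLMNPQRSTVWY+X)."""
    idx = window_indices(window)
    out = np.zeros((WINDOW_SIZE, 21))
    out[np.arange(WINDOW_SIZE), idx] = 1.0
    names = [
        f"BINARY:{POSITION_LABELS[p]}:{a}"
        for p in range(WINDOW_SIZE)
        for a in ALPHABET
    ]
    return FeatureBlock("BINARY", out.ravel(), names)


def encode_cksaap(window: str, k_values: tuple[int, ...] = (0, 1, 2, 3, 4, 5)) -> FeatureBlock:
    """Composition of k-spaced amino-acid pairs over the 400 pair types.

    For spacing k, a pair is (residue i, residue i+k+1); each of the 400
    counts is divided by N_total = L - (k + 1). Pairs touching an 'X'
    contribute to N_total but to no pair type.
    """
    L = len(window)
    idx = window_indices(window)
    blocks = []
    names = []
    for k in k_values:
        counts = np.zeros((20, 20))
        n_total = L - (k + 1)
        for i in range(n_total):
            a, b = idx[i], idx[i + k + 1]
            if a < 20 and b < 20:
                counts[a, b] += 1
        blocks.append(counts.ravel() / n_total)
        names.extend(
            f"CKSAAP:k{k}:{a}{b}" for a in AA20 for b in AA20
        )
    return FeatureBlock("CKSAAP", np.concatenate(blocks), names)


def encode_aac(window: str) -> FeatureBlock:
    """Occurrence frequency of each standard residue; 'X' counts toward the
    window length but no residue slot."""
    idx = window_indices(window)
    counts = np.bincount(idx, minlength=21)[:20].astype(float)
    return FeatureBlock(
        "AAC", counts / len(window), [f"AAC:{a}" for a in AA20]
    )


def encode_chr(window: str) -> FeatureBlock:
    """Charge/hydropathy summary over three segments: the N-side (P8-P1),
    the C-side (P1'-P8') and the full window. Per segment: net charge
    (K/R/H = +1, D/E = -1), summed Kyte-Doolittle hydropathy, and the
    ratio charge / (|hydropathy| + 1). 'X' contributes zero to both."""
    idx = window_indices(window)
    charge21 = np.append(CHARGE, 0.0)
    kd21 = np.append(KYTE_DOOLITTLE, 0.0)
    segments = {"N": idx[:FLANK], "C": idx[FLANK:], "full": idx}
    values, names = [], []
    for tag, seg in segments.items():
        q = float(charge21[seg].sum())
        h = float(kd21[seg].sum())
        values.extend([q, h, q / (abs(h) + 1.0)])
        names.extend([f"CHR:{tag}:charge", f"CHR:{tag}:hydropathy", f"CHR:{tag}:ratio"])
    return FeatureBlock("CHR", np.asarray(values), names)


# ---------------------------------------------------------------------------
# KNN scheme
# ---------------------------------------------------------------------------


@dataclass
class KnnReference:
    """Labelled reference windows ranked against each query by clipped
    BLOSUM62 similarity."""

    windows: list[str]
    labels: np.ndarray
    k_fractions: tuple[float, ...] = (0.01, 0.03, 0.05, 0.07, 0.09)
    _index_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.windows) != len(self.labels):
            raise ValueError("windows/labels length mismatch")
        if not (self.labels == 1).any() or not (self.labels == 0).any():
            raise ValueError("KNN reference needs both classes")
        fr = self.k_fractions
        if not all(0 < a < 1 for a in fr) or any(
            fr[i] >= fr[i + 1] for i in range(len(fr) - 1)
        ):
            raise ValueError("k_fractions must be strictly increasing in (0, 1)")
        self._index_matrix = np.stack([window_indices(w) for w in self.windows])

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def index_matrix(self) -> np.ndarray:
        return self._index_matrix


def clipped_blosum(matrix: SubstitutionMatrix) -> np.ndarray:
    """max(score, 0) table used by the similarity kernel."""
    return np.maximum(matrix.scores.astype(float), 0.0)


def knn_similarity(window_a: str, window_b: str, matrix: SubstitutionMatrix) -> float:
    """Sum over positions of max(BLOSUM62(a, b), 0)."""
    if len(window_a) != len(window_b):
        raise ValueError("windows must have equal length")
    clip = clipped_blosum(matrix)
    ia, ib = window_indices(window_a), window_indices(window_b)
    return float(clip[ia, ib].sum())


def _similarity_to_reference(
    query_idx: np.ndarray, ref: KnnReference, clip: np.ndarray
) -> np.ndarray:
    """Similarity of each query row (n_q, 16) to each reference window."""
    n_q = query_idx.shape[0]
    sims = np.zeros((n_q, len(ref)))
    ref_idx = ref.index_matrix
    for p in range(WINDOW_SIZE):
        sims += clip[query_idx[:, p][:, None], ref_idx[:, p][None, :]]
    return sims


def _knn_components(sims: np.ndarray, ref: KnnReference) -> np.ndarray:
    """Positive fraction among the top-K references for each k-fraction.

    Ties in similarity are broken by stable reference order. K is taken
    from the full reference size even when one entry is self-excluded
    (marked by -inf similarity)."""
    n_total = len(ref)
    order = np.argsort(-sims, axis=1, kind="stable")
    ranked_labels = ref.labels[order]
    out = np.zeros((sims.shape[0], len(ref.k_fractions)))
    for j, f in enumerate(ref.k_fractions):
        k = max(1, int(round(f * n_total)))
        out[:, j] = ranked_labels[:, :k].mean(axis=1)
    return out


def knn_feature_matrix(
    windows: list[str],
    ref: KnnReference,
    matrix: SubstitutionMatrix | None = None,
    exclude_self: bool = False,
) -> np.ndarray:
    """Vectorised KNN block for many windows at once -> (n_windows, 5).

    ``exclude_self=True`` declares that ``windows`` are exactly the
    reference windows in order, and removes each row's own entry from its
    ranking (leave-one-out).
    """
    clip = clipped_blosum(matrix if matrix is not None else load_blosum62())
    qidx = np.stack([window_indices(w) for w in windows])
    sims = _similarity_to_reference(qidx, ref, clip)
    if exclude_self:
        if sims.shape[0] != len(ref):
            raise ValueError("exclude_self requires windows == reference set")
        np.fill_diagonal(sims, -np.inf)
    return _knn_components(sims, ref)


def encode_knn(
    window: str,
    ref: KnnReference,
    matrix: SubstitutionMatrix | None = None,
    exclude_index: int | None = None,
) -> FeatureBlock:
    """For each K at 1/3/5/7/9% of the reference size, the fraction of
    positives among the K reference windows most similar to the query.
    ``exclude_index`` removes the query's own reference entry from the
    ranking (used when the query belongs to the reference set)."""
    matrix = matrix if matrix is not None else load_blosum62()
    clip = clipped_blosum(matrix)
    sims = _similarity_to_reference(window_indices(window)[None, :], ref, clip)
    if exclude_index is not None:
        sims[0, exclude_index] = -np.inf
    values = _knn_components(sims, ref)[0]
    names = [f"KNN:top{int(f * 100)}pct" for f in ref.k_fractions]
    return FeatureBlock("KNN", values, names)


# ---------------------------------------------------------------------------
# Profile schemes
# ---------------------------------------------------------------------------


def _window_sequence_positions(p1: int) -> list[int]:
    """1-based substrate positions covered by the window (<=0 or beyond the
    sequence end means terminal padding)."""
    return list(range(p1 - FLANK + 1, p1 + 1)) + list(range(p1 + 1, p1 + FLANK + 1))


def encode_pssm(profile: ResidueProfile, p1: int) -> FeatureBlock:
    """Per window position the 20 profile scores squashed by the logistic
    1/(1+e^-s); padded (out-of-sequence) positions contribute zero rows."""
    L = len(profile)
    if not (1 <= p1 < L):
        raise ValueError(f"p1={p1} out of range for profile of length {L}")
    rows = np.zeros((WINDOW_SIZE, 20))
    for w, pos in enumerate(_window_sequence_positions(p1)):
        if 1 <= pos <= L:
            rows[w] = 1.0 / (1.0 + np.exp(-profile.scores[pos - 1]))
    names = [
        f"PSSM:{POSITION_LABELS[p]}:{a}" for p in range(WINDOW_SIZE) for a in AA20
    ]
    return FeatureBlock("PSSM", rows.ravel(), names)


def encode_blosum(window: str, matrix: SubstitutionMatrix | None = None) -> FeatureBlock:
    """Per window position the 21-component BLOSUM62 row of that residue
    ('X' row is all zeros)."""
    matrix = matrix if matrix is not None else load_blosum62()
    idx = window_indices(window)
    rows = matrix.scores.astype(float)[idx]
    names = [
        f"BLOSUM:{POSITION_LABELS[p]}:{a}"
        for p in range(WINDOW_SIZE)
        for a in ALPHABET
    ]
    return FeatureBlock("BLOSUM", rows.ravel(), names)


# ---------------------------------------------------------------------------
# AAindex scheme
# ---------------------------------------------------------------------------

N_AAINDEX = 64


@dataclass
class AAIndexSet:
    """An ordered, versioned set of 64 physicochemical indices.

    Raw 20-residue value vectors are min-max scaled to [0, 1] per index;
    'X' positions take the per-index mean of the scaled values.
    """

    ids: list[str]
    raw: np.ndarray  # (n, 20) in AA20 order
    version: str

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.ids), 20):
            raise ValueError("AAindex value table shape mismatch")
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("AAindex set contains missing values")
        lo = self.raw.min(axis=1, keepdims=True)
        span = self.raw.max(axis=1, keepdims=True) - lo
        span[span == 0] = 1.0
        self.scaled = (self.raw - lo) / span  # (n, 20)
        self.means = self.scaled.mean(axis=1)  # 'X' fallback

    def __len__(self) -> int:
        return len(self.ids)


def select_diverse_indices(
    table: dict[str, np.ndarray], n: int = N_AAINDEX, version: str | None = None
) -> AAIndexSet:
    """Deterministically choose ``n`` indices from a parsed aaindex table:
    greedy max-min Euclidean distance between (z-scored) index value
    vectors, ties broken by accession order."""
    ids = sorted(table)
    if len(ids) < n:
        raise ValueError(f"need at least {n} complete indices, have {len(ids)}")
    raw = np.stack([table[i] for i in ids])
    std = raw.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    z = (raw - raw.mean(axis=1, keepdims=True)) / std
    dist = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=2)
    # Seed with the pair at maximal distance (lowest accessions on ties).
    flat = np.argmax(dist)
    i0, j0 = sorted(divmod(flat, len(ids)))
    chosen = [i0, j0]
    remaining = [i for i in range(len(ids)) if i not in chosen]
    while len(chosen) < n:
        min_d = dist[np.ix_(remaining, chosen)].min(axis=1)
        best = remaining[int(np.argmax(min_d))]
        chosen.append(best)
        remaining.remove(best)
    chosen.sort()
    return AAIndexSet(
        ids=[ids[i] for i in chosen],
        raw=raw[chosen],
        version=version or f"user-aaindex-{n}",
    )


def synthetic_aaindex(seed: int = 20180419) -> AAIndexSet:
    """Synthetic stand-in AAindex set used when no aaindex1 file is given.

    Deterministic pseudo-random 20-residue value vectors (not real
    published indices); versioned so model bundles record which table
    produced their features.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(N_AAINDEX, 20))
    ids = [f"SYN{i:04d}" for i in range(1, N_AAINDEX + 1)]
    return AAIndexSet(ids=ids, raw=raw, version="synthetic-aaindex-v1")


def encode_aaindex(window: str, indices: AAIndexSet) -> FeatureBlock:
    """Per window position the 64 scaled index values of that residue,
    position-major; 'X' takes each index's mean scaled value."""
    if len(indices) != N_AAINDEX:
        raise ValueError(f"exactly {N_AAINDEX} indices required, got {len(indices)}")
    idx = window_indices(window)
    table = np.column_stack([indices.scaled, indices.means])  # (64, 21)
    out = table[:, idx].T  # (16, 64), position-major
    names = [
        f"AAINDEX:{POSITION_LABELS[p]}:{acc}"
        for p in range(WINDOW_SIZE)
        for acc in indices.ids
    ]
    return FeatureBlock("AAINDEX", out.ravel(), names)


# ---------------------------------------------------------------------------
# Structural schemes
# ---------------------------------------------------------------------------

SS_STATES = "HEC"
SA_STATES = "BE"


def slice_tracks(tracks: StructuralTracks, p1: int) -> list[tuple | None]:
    """Per-window-position (ss, sa_state, diso) tuples; None marks terminal
    padding."""
    L = len(tracks)
    out: list[tuple | None] = []
    for pos in _window_sequence_positions(p1):
        if 1 <= pos <= L:
            out.append((tracks.ss[pos - 1], tracks.sa_state[pos - 1], tracks.diso[pos - 1]))
        else:
            out.append(None)
    return out


def encode_structural(tracks_slice: list[tuple | None], kind: str) -> FeatureBlock:
    """SS: 3-state one-hot per position; SA: 2-state one-hot; DISO:
    (p_disorder, 1 - p_disorder). Padded positions use uniform priors."""
    if len(tracks_slice) != WINDOW_SIZE:
        raise ValueError("tracks slice must cover 16 window positions")
    rows = []
    names = []
    for p, entry in enumerate(tracks_slice):
        lab = POSITION_LABELS[p]
        if kind == "SS":
            if entry is None:
                rows.append([1 / 3] * 3)
            else:
                rows.append([1.0 if entry[0] == s else 0.0 for s in SS_STATES])
            names.extend(f"SS:{lab}:{s}" for s in SS_STATES)
        elif kind == "SA":
            if entry is None:
                rows.append([0.5, 0.5])
            else:
                rows.append([1.0 if entry[1] == s else 0.0 for s in SA_STATES])
            names.extend(f"SA:{lab}:{s}" for s in SA_STATES)
        elif kind == "DISO":
            if entry is None:
                rows.append([0.5, 0.5])
            else:
                rows.append([float(entry[2]), 1.0 - float(entry[2])])
            names.extend([f"DISO:{lab}:p", f"DISO:{lab}:1-p"])
        else:
            raise ValueError(f"unknown structural scheme {kind!r}")
    return FeatureBlock(kind, np.asarray(rows).ravel(), names)


# ---------------------------------------------------------------------------
# Context and full-vector assembly
# ---------------------------------------------------------------------------


class MissingProviderError(ValueError):
    """An enabled scheme lacks its required input provider."""


@dataclass
class EncodingContext:
    """Everything the enabled schemes need: the substitution matrix, an
    AAindex table, the KNN reference set, and per-substrate profile/track
    providers keyed by substrate id."""

    schemes: tuple[str, ...] = SEQUENCE_SCHEMES
    blosum: SubstitutionMatrix | None = None
    aaindex: AAIndexSet | None = None
    knn_ref: KnnReference | None = None
    profiles: dict[str, ResidueProfile] | None = None
    tracks: dict[str, StructuralTracks] | None = None
    cksaap_k: tuple[int, ...] = (0, 1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        unknown = set(self.schemes) - set(SCHEME_ORDER)
        if unknown:
            raise ValueError(
                f"unknown schemes {sorted(unknown)}; choose from {SCHEME_ORDER}"
            )
        # Keep Table-2 ordering regardless of how schemes were listed.
        self.schemes = tuple(s for s in SCHEME_ORDER if s in self.schemes)
        if self.blosum is None:
            self.blosum = load_blosum62()
        if self.aaindex is None and "AAINDEX" in self.schemes:
            self.aaindex = synthetic_aaindex()

    @property
    def total_dim(self) -> int:
        return sum(SCHEME_DIMS[s] for s in self.schemes)

    def require(self, scheme: str, provider, what: str):
        if provider is None:
            raise MissingProviderError(
                f"scheme {scheme} enabled but no {what} supplied; disable the "
                f"scheme or provide the missing input"
            )
        return provider


def sequence_context(
    schemes: tuple[str, ...] = SEQUENCE_SCHEMES, **kwargs
) -> EncodingContext:
    """Context for the schemes computable from sequence alone."""
    return EncodingContext(schemes=schemes, **kwargs)


def encode_all(
    site: SiteWindow | str,
    context: EncodingContext,
    knn_exclude_index: int | None = None,
) -> FeatureVector:
    """Concatenate the enabled schemes' blocks in fixed table order.

    A plain window string works for sequence-only schemes; PSSM and the
    structural schemes need a :class:`SiteWindow` so the per-substrate
    profile/tracks can be looked up.
    """
    if isinstance(site, SiteWindow):
        window, sid, p1 = site.window, site.substrate_id, site.p1
    else:
        window, sid, p1 = site, None, None
    blocks = []
    for scheme in context.schemes:
        if scheme == "BINARY":
            blocks.append(encode_binary(window))
        elif scheme == "CKSAAP":
            blocks.append(encode_cksaap(window, context.cksaap_k))
        elif scheme == "KNN":
            ref = context.require("KNN", context.knn_ref, "KnnReference")
            blocks.append(
                encode_knn(window, ref, context.blosum, exclude_index=knn_exclude_index)
            )
        elif scheme == "AAC":
            blocks.append(encode_aac(window))
        elif scheme == "PSSM":
            profiles = context.require("PSSM", context.profiles, "profile provider")
            if sid is None or sid not in profiles:
                raise MissingProviderError(f"no PSSM profile for substrate {sid!r}")
            blocks.append(encode_pssm(profiles[sid], p1))
        elif scheme == "BLOSUM":
            blocks.append(encode_blosum(window, context.blosum))
        elif scheme == "AAINDEX":
            aaindex = context.require("AAINDEX", context.aaindex, "AAindex set")
            blocks.append(encode_aaindex(window, aaindex))
        elif scheme == "CHR":
            blocks.append(encode_chr(window))
        else:  # SS / SA / DISO
            tracks = context.require(scheme, context.tracks, "structural tracks")
            if sid is None or sid not in tracks:
                raise MissingProviderError(f"no structural tracks for {sid!r}")
            blocks.append(encode_structural(slice_tracks(tracks[sid], p1), scheme))
    vec = FeatureVector(blocks=tuple(blocks))
    if vec.total_dim != context.total_dim:
        raise AssertionError("block dimensions inconsistent with context")
    return vec


def encode_matrix(
    sites: list[SiteWindow],
    context: EncodingContext,
    knn_exclude_self: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix (n_sites x total_dim) plus the column-name manifest.

    ``knn_exclude_self=True`` declares that ``sites`` are exactly the KNN
    reference windows, in order; each row's own reference entry is then
    excluded from its neighbour ranking (leave-one-out).
    """
    if knn_exclude_self:
        ref = context.knn_ref
        if ref is None or len(ref) != len(sites):
            raise ValueError(
                "knn_exclude_self requires the sites to be the reference set"
            )
    rows = []
    manifest: list[str] | None = None
    for i, site in enumerate(sites):
        vec = encode_all(
            site, context, knn_exclude_index=i if knn_exclude_self else None
        )
        rows.append(vec.values)
        if manifest is None:
            manifest = vec.names
    return np.vstack(rows), manifest or []


def write_feature_tsv(X: np.ndarray, manifest: list[str], path) -> None:
    """Feature matrix as TSV with the column-name manifest as header."""
    if X.shape[1] != len(manifest):
        raise ValueError("manifest length must match column count")
    with open(path, "w") as fh:
        fh.write("\t".join(manifest) + "\n")
        for row in X:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def build_knn_reference(
    windows: list[SiteWindow],
    k_fractions: tuple[float, ...] = (0.01, 0.03, 0.05, 0.07, 0.09),
) -> KnnReference:
    return KnnReference(
        windows=[w.window for w in windows],
        labels=np.array([w.label for w in windows]),
        k_fractions=k_fractions,
    )
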