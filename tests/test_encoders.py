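"""Encoder dimensions, hand-computed values, oracles and purity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protcleave.dataset import SiteWindow
from protcleave.encoders import (
    EncodingContext,
    FULL_DIM,
    KnnReference,
    MissingProviderError,
    SCHEME_DIMS,
    SCHEME_ORDER,
    encode_aac,
    encode_aaindex,
    encode_all,
    encode_binary,
    encode_blosum,
    encode_chr,
    encode_cksaap,
    encode_knn,
    encode_matrix,
    encode_pssm,
    encode_structural,
    knn_feature_matrix,
    knn_similarity,
    select_diverse_indices,
    sequence_context,
    slice_tracks,
    synthetic_aaindex,
)
from protcleave.io import AA20, ALPHABET, ResidueProfile

windows_st = st.text(alphabet=ALPHABET, min_size=16, max_size=16)


class TestDimensions:
    """Every scheme's component count matches its published table entry."""

    def test_total_dimension(self):
        assert FULL_DIM == 4562

    @pytest.mark.parametrize(
        "scheme,dim",
        [
            ("BINARY", 336), ("CKSAAP", 2400), ("KNN", 5), ("AAC", 20),
            ("PSSM", 320), ("BLOSUM", 336), ("AAINDEX", 1024), ("CHR", 9),
            ("SS", 48), ("SA", 32), ("DISO", 32),
        ],
    )
    def test_block_dims(self, scheme, dim):
        assert SCHEME_DIMS[scheme] == dim

    def test_sequence_only_vector(self):
        ctx = sequence_context()
        vec = encode_all("ACDEFGHIKLMNPQRS", ctx)
        assert vec.total_dim == 336 + 2400 + 20 + 336 + 1024 + 9
        assert len(vec.names) == vec.total_dim


class TestBinary:
    def test_poly_a(self):
        block = encode_binary("A" * 16)
        mat = block.values.reshape(16, 21)
        assert mat.sum() == 16
        assert np.array_equal(mat[:, 0], np.ones(16))  # 'A' slot

    def test_padding_hits_x_slot(self):
        block = encode_binary("XX" + "A" * 14)
        mat = block.values.reshape(16, 21)
        assert mat[0, 20] == 1 and mat[1, 20] == 1

    def test_unknown_character_rejected(self):
        with pytest.raises(ValueError):
            encode_binary("B" + "A" * 15)

    def test_binary_onehot_selects_blosum_row(self, blosum):
        """The one-hot index of each position picks out exactly the BLOSUM
        row used by the profile encoding of the same window."""
        w = "ACDXFGHIKLMNPQRern".upper()[:16]
        onehot = encode_binary(w).values.reshape(16, 21)
        rows = encode_blosum(w, blosum).values.reshape(16, 21)
        for p in range(16):
            sel = int(np.argmax(onehot[p]))
            assert np.array_equal(rows[p], blosum.scores[sel].astype(float))


class TestCksaap:
    def test_poly_a_k0(self):
        block = encode_cksaap("A" * 16)
        k0 = block.values[:400]
        assert k0[0] == pytest.approx(1.0)  # AA pair
        assert k0[1:].sum() == 0

    def test_alternating_ac_counted_by_hand(self):
        block = encode_cksaap("ACACACACACACACAC")
        k0 = block.values[:400]
        ac = AA20.index("A") * 20 + AA20.index("C")
        ca = AA20.index("C") * 20 + AA20.index("A")
        assert k0[ac] == pytest.approx(8 / 15)
        assert k0[ca] == pytest.approx(7 / 15)

    def test_dim(self):
        assert encode_cksaap("A" * 16).dim == 2400

    @settings(max_examples=40, deadline=None)
    @given(windows_st)
    def test_k_blocks_sum_to_at_most_one(self, window):
        vals = encode_cksaap(window).values.reshape(6, 400)
        sums = vals.sum(axis=1)
        assert np.all(sums <= 1 + 1e-12)
        if "X" not in window:
            assert np.allclose(sums, 1.0)


class TestAac:
    def test_poly_a(self):
        vals = encode_aac("A" * 16).values
        assert vals[0] == 1.0 and vals[1:].sum() == 0

    def test_all_distinct(self):
        vals = encode_aac("ACDEFGHIKLMNPQRS").values
        assert np.count_nonzero(vals) == 16
        assert np.allclose(vals[vals > 0], 1 / 16)

    @settings(max_examples=40, deadline=None)
    @given(windows_st)
    def test_sums_to_at_most_one(self, window):
        s = encode_aac(window).values.sum()
        assert s <= 1 + 1e-12
        if "X" not in window:
            assert s == pytest.approx(1.0)


class TestKnn:
    def test_similarity_hand_values(self, blosum):
        assert knn_similarity("AC", "AC", blosum) == 13  # 4 + 9
        assert knn_similarity("AC", "AD", blosum) == 4  # 4 + max(-3, 0)

    def test_identity_dominates_single_substitutions(self, blosum):
        w = "ACDEFGHIKLMNPQRS"
        base = knn_similarity(w, w, blosum)
        for p in range(16):
            for a in AA20:
                if a == w[p]:
                    continue
                mutant = w[:p] + a + w[p + 1 :]
                assert knn_similarity(w, mutant, blosum) <= base

    def test_length_mismatch(self, blosum):
        with pytest.raises(ValueError):
            knn_similarity("AC", "ACD", blosum)

    def test_query_equal_to_single_positive(self, blosum):
        ref = KnnReference(
            windows=["D" * 16, "A" * 16], labels=np.array([1, 0]),
            k_fractions=(0.4,),
        )
        block = encode_knn("D" * 16, ref, blosum)
        assert block.values[0] == 1.0

    def test_all_negative_reference(self, blosum):
        ref = KnnReference(
            windows=["A" * 16, "C" * 16, "D" * 16],
            labels=np.array([0, 0, 1]),
            k_fractions=(0.3, 0.5),
        )
        # force label-1 window far away: query close to the negatives
        block = encode_knn("A" * 16, ref, blosum, exclude_index=0)
        assert block.values[0] == 0.0

    def test_matches_brute_force_oracle(self, blosum, small_samples):
        """Vectorised ranking equals an independent full-sort recount on a
        mixed-label reference."""
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(small_samples.windows))
        windows = [small_samples.windows[i] for i in perm[:120]]
        ref = KnnReference(
            windows=[w.window for w in windows],
            labels=np.array([w.label for w in windows]),
        )
        queries = [small_samples.windows[i].window for i in perm[120:140]]
        fast = knn_feature_matrix(queries, ref, blosum)

        clip = np.maximum(blosum.scores, 0)
        aidx = {a: i for i, a in enumerate(ALPHABET)}
        for qi, q in enumerate(queries):
            sims = []
            for rw in ref.windows:
                sims.append(sum(clip[aidx[a], aidx[b]] for a, b in zip(q, rw)))
            order = sorted(range(len(sims)), key=lambda i: (-sims[i], i))
            for fj, f in enumerate(ref.k_fractions):
                k = max(1, round(f * len(ref)))
                expected = np.mean([ref.labels[i] for i in order[:k]])
                assert fast[qi, fj] == pytest.approx(expected)

    def test_reference_requires_both_classes(self):
        with pytest.raises(ValueError):
            KnnReference(windows=["A" * 16], labels=np.array([1]))


class TestProfileEncodings:
    def test_blosum_poly_a_repeats_row(self, blosum):
        vals = encode_blosum("A" * 16, blosum).values.reshape(16, 21)
        for p in range(16):
            assert np.array_equal(vals[p], blosum.scores[0].astype(float))

    def test_pssm_logistic_and_padding(self):
        rng = np.random.default_rng(0)
        prof = ResidueProfile("s", rng.normal(size=(30, 20)))
        block = encode_pssm(prof, p1=3)  # left-padded window
        mat = block.values.reshape(16, 20)
        assert np.array_equal(mat[:5], np.zeros((5, 20)))  # pads are zero rows
        expected = 1 / (1 + np.exp(-prof.scores[0]))
        assert np.allclose(mat[5], expected)  # residue 1 at window slot 6

    def test_pssm_out_of_range(self):
        prof = ResidueProfile("s", np.zeros((10, 20)))
        with pytest.raises(ValueError):
            encode_pssm(prof, p1=10)


class TestAAindexAndChr:
    def test_aaindex_dim_and_x_mean(self):
        idx = synthetic_aaindex()
        block = encode_aaindex("X" * 16, idx)
        assert block.dim == 1024
        mat = block.values.reshape(16, 64)
        assert np.allclose(mat, idx.means[None, :])

    def test_aaindex_scaled_to_unit_interval(self):
        idx = synthetic_aaindex()
        block = encode_aaindex("ACDEFGHIKLMNPQRS", idx)
        assert block.values.min() >= 0 and block.values.max() <= 1

    def test_select_diverse_indices_deterministic(self):
        rng = np.random.default_rng(5)
        table = {f"ID{i:03d}": rng.normal(size=20) for i in range(80)}
        a = select_diverse_indices(table, n=64)
        b = select_diverse_indices(table, n=64)
        assert a.ids == b.ids
        assert len(a.ids) == 64

    def test_chr_poly_d_charges(self):
        vals = encode_chr("D" * 16).values
        # (charge, hydropathy, ratio) per segment: N, C, full
        assert (vals[0], vals[3], vals[6]) == (-8, -8, -16)

    def test_chr_poly_g_no_charge(self):
        vals = encode_chr("G" * 16).values
        assert vals[0] == vals[3] == vals[6] == 0


class TestStructural:
    def test_all_helix(self, small_substrates):
        slice_ = [("H", "B", 0.1)] * 16
        vals = encode_structural(slice_, "SS").values.reshape(16, 3)
        assert np.array_equal(vals[:, 0], np.ones(16))

    def test_diso_half(self):
        slice_ = [("C", "E", 0.5)] * 16
        vals = encode_structural(slice_, "DISO").values
        assert np.allclose(vals, 0.5)

    def test_padding_uses_uniform_priors(self):
        slice_ = [None] * 16
        ss = encode_structural(slice_, "SS").values
        sa = encode_structural(slice_, "SA").values
        assert np.allclose(ss, 1 / 3)
        assert np.allclose(sa, 0.5)

    def test_slice_tracks_marks_padding(self, small_substrates):
        _, tracks = small_substrates
        tr = next(iter(tracks.values()))
        sl = slice_tracks(tr, p1=3)
        assert sl[:5] == [None] * 5
        assert sl[5] is not None


class TestEncodeAll:
    def test_full_vector_dim(self, small_samples, small_substrates):
        _, tracks = small_substrates
        rng = np.random.default_rng(2)
        ref_windows = [
            small_samples.windows[i]
            for i in rng.permutation(len(small_samples.windows))[:40]
        ]
        ref = KnnReference(
            windows=[w.window for w in ref_windows],
            labels=np.array([w.label for w in ref_windows]),
        )
        rng = np.random.default_rng(1)
        profiles = {
            w.substrate_id: ResidueProfile(
                w.substrate_id,
                rng.normal(size=(len(tracks[w.substrate_id]), 20)),
            )
            for w in small_samples.windows
        }
        ctx = EncodingContext(
            schemes=SCHEME_ORDER, knn_ref=ref, profiles=profiles, tracks=tracks
        )
        vec = encode_all(small_samples.windows[0], ctx)
        assert vec.total_dim == 4562
        assert len(vec.names) == 4562
        assert [b.name for b in vec.blocks] == list(SCHEME_ORDER)

    def test_missing_provider_error(self):
        ctx = EncodingContext(schemes=("KNN",))
        with pytest.raises(MissingProviderError):
            encode_all("A" * 16, ctx)

    def test_encoders_are_pure(self, knn_context, small_samples):
        w = small_samples.windows[5]
        a = encode_all(w, knn_context).values
        b = encode_all(w, knn_context).values
        assert np.array_equal(a, b)

    def test_matrix_matches_per_window(self, knn_context, small_samples):
        sites = small_samples.windows[:10]
        X, manifest = encode_matrix(sites, knn_context)
        for i, s in enumerate(sites):
            assert np.array_equal(X[i], encode_all(s, knn_context).values)
        assert len(manifest) == X.shape[1]

    def test_feature_tsv_header_is_manifest(self, knn_context, small_samples, tmp_path):
        from protcleave.encoders import write_feature_tsv

        X, manifest = encode_matrix(small_samples.windows[:4], knn_context)
        f = tmp_path / "features.tsv"
        write_feature_tsv(X, manifest, f)
        lines = f.read_text().splitlines()
        assert lines[0].split("\t") == manifest
        assert len(lines) == 5
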