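"""Window extraction, homology reduction, splitting and sample assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protcleave.dataset import (
    SampleSet,
    SiteWindow,
    build_samples,
    extract_window,
    kmer_identity,
    reduce_redundancy,
    split_train_test,
)
from protcleave.io import AA20, SequenceRecord, StructuralTracks, SubstrateRecord

SEQ26 = "ACDEFGHIKLMNPQRSTVWYACDEFG"


class TestExtractWindow:
    def test_interior_no_padding(self):
        # p1=13 -> residues 6..21 (1-based)
        assert extract_window(SEQ26, 13) == SEQ26[5:21]

    def test_left_padding(self):
        # p1=3 -> 5 X, residues 1..3, then 4..11
        assert extract_window(SEQ26, 3) == "XXXXX" + SEQ26[:3] + SEQ26[3:11]

    def test_first_bond_of_short_sequence(self):
        seq = SEQ26[:9]
        assert extract_window(seq, 1) == "X" * 7 + seq[0] + seq[1:9]

    @pytest.mark.parametrize("p1", [0, 26, 99])
    def test_out_of_range(self, p1):
        with pytest.raises(ValueError):
            extract_window(SEQ26, p1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=10, max_value=40), st.data())
    def test_position_equivariance(self, length, data):
        """Dropping the first residue and decrementing p1 gives the same
        window, away from the left terminus."""
        rng = np.random.default_rng(length)
        seq = "".join(rng.choice(list(AA20), size=length))
        p1 = data.draw(st.integers(min_value=9, max_value=length - 1))
        assert extract_window(seq, p1) == extract_window(seq[1:], p1 - 1)


class TestHomologyReduction:
    def test_identical_sequences_collapse(self):
        recs = [SequenceRecord("a", SEQ26), SequenceRecord("b", SEQ26)]
        assert len(reduce_redundancy(recs)) == 1

    def test_disjoint_sequences_both_kept(self):
        recs = [
            SequenceRecord("a", "ACDEFGHIKL" * 3),
            SequenceRecord("b", "VWYVWYVWYV" * 3),
        ]
        assert len(reduce_redundancy(recs)) == 2

    def test_precomputed_cluster_file_substitutes(self, tmp_path):
        recs = [SequenceRecord(f"r{i}", SEQ26) for i in range(4)]
        f = tmp_path / "clusters.tsv"
        f.write_text(
            "sequence_id\tcluster_id\nr0\tc1\nr1\tc1\nr2\tc2\nr3\tc2\n"
        )
        from protcleave.dataset import apply_cluster_file

        kept = apply_cluster_file(recs, f)
        assert [r.id for r in kept] == ["r0", "r2"]

    def test_retained_set_pairwise_below_threshold(self):
        """All-pairs oracle: survivors are mutually below the estimator
        threshold."""
        rng = np.random.default_rng(0)
        pool = []
        base = "".join(rng.choice(list(AA20), size=80))
        for i in range(15):
            seq = list(base)
            for j in rng.choice(80, size=rng.integers(0, 60), replace=False):
                seq[j] = AA20[rng.integers(20)]
            pool.append(SequenceRecord(f"r{i}", "".join(seq)))
        kept = reduce_redundancy(pool, identity_threshold=0.7)
        assert kept
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert kmer_identity(a.sequence, b.sequence) < 0.7


class TestSplit:
    def _subs(self, n):
        rng = np.random.default_rng(1)
        out = []
        for i in range(n):
            seq = "".join(rng.choice(list(AA20), size=50))
            out.append(
                SubstrateRecord(SequenceRecord(f"s{i}", seq), [("P1.001", 10)])
            )
        return out

    def test_six_substrates_split_five_one(self):
        train, test = split_train_test(self._subs(6), seed=0)
        assert (len(train), len(test)) == (5, 1)

    def test_deterministic_and_partitioning(self):
        subs = self._subs(12)
        t1, e1 = split_train_test(subs, seed=5)
        t2, e2 = split_train_test(subs, seed=5)
        assert [s.id for s in t1] == [s.id for s in t2]
        ids = {s.id for s in t1} | {s.id for s in e1}
        assert ids == {s.id for s in subs}
        assert not ({s.id for s in t1} & {s.id for s in e1})

    def test_too_few_substrates(self):
        with pytest.raises(ValueError):
            split_train_test(self._subs(1))


class TestBuildSamples:
    def test_ratio_exact(self, small_substrates):
        subs, _ = small_substrates
        ss = build_samples(subs, "X01.001", ratio_neg_per_pos=3, seed=0)
        n_pos = len(ss.positives())
        assert len(ss.negatives()) == 3 * n_pos
        assert n_pos == sum(len(s.events) for s in subs)

    def test_candidate_exhaustion_keeps_all(self):
        # One short substrate: 2 positives, few negatives available.
        seq = "ACDEFGHIKLMNPQRSTVWY"
        sub = SubstrateRecord(
            SequenceRecord("s", seq), [("P1.001", p) for p in range(1, 15)]
        )
        ss = build_samples([sub], "P1.001", ratio_neg_per_pos=3, seed=0)
        # 14 positives but only 5 remaining bond positions.
        assert len(ss.negatives()) == 5

    def test_no_label_collision(self, small_substrates):
        subs, _ = small_substrates
        ss = build_samples(subs, "X01.001", seed=3)
        pos_keys = {(w.substrate_id, w.p1) for w in ss.positives()}
        neg_keys = {(w.substrate_id, w.p1) for w in ss.negatives()}
        assert not pos_keys & neg_keys

    def test_seed_reproducible(self, small_substrates):
        subs, _ = small_substrates
        a = build_samples(subs, "X01.001", seed=11)
        b = build_samples(subs, "X01.001", seed=11)
        assert [(w.substrate_id, w.p1, w.label) for w in a.windows] == [
            (w.substrate_id, w.p1, w.label) for w in b.windows
        ]

    def test_sa_filter_restricts_then_falls_back(self, small_substrates):
        subs, tracks = small_substrates
        filtered = build_samples(subs, "X01.001", sa_filter=tracks, seed=0)
        for w in filtered.negatives():
            assert tracks[w.substrate_id].sa_state[w.p1 - 1] == "B"
        # Degenerate filter: everything exposed -> fallback path.
        all_exposed = {
            sid: StructuralTracks(
                ss=t.ss, sa_state="E" * len(t), diso=t.diso, sa_value=t.sa_value
            )
            for sid, t in tracks.items()
        }
        fallback = build_samples(subs, "X01.001", sa_filter=all_exposed, seed=0)
        assert fallback.provenance["sa_fallback"]
        assert fallback.negatives()

    def test_zero_positives_rejected(self, small_substrates):
        subs, _ = small_substrates
        with pytest.raises(ValueError):
            build_samples(subs, "NOPE.000", seed=0)

    def test_tsv_roundtrip(self, small_samples, tmp_path):
        f = tmp_path / "samples.tsv"
        small_samples.to_tsv(f)
        back = SampleSet.from_tsv(f)
        assert back.protease_id == small_samples.protease_id
        assert [w.window for w in back.windows] == [
            w.window for w in small_samples.windows
        ]


class TestSiteWindow:
    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            SiteWindow("s", 1, "ACD", 1, "P1.001")

    def test_rejects_bad_label(self):
        with pytest.raises(ValueError):
            SiteWindow("s", 1, "A" * 16, 2, "P1.001")
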