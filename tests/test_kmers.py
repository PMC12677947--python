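"""k-mer encoding, extraction, inverted index, and binary persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kmertax as kt
from kmertax.kmers import NUM_CODES, revcomp_codes

from conftest import brute_force_intersections


class TestEncoding:
    @pytest.mark.parametrize(
        "kmer,code",
        [("AAAAAAAA", 0), ("AAAAAAAT", 3), ("ACGTACGT", 6939), ("TTTTTTTT", 65535)],
    )
    def test_known_codes(self, kmer, code):
        assert kt.encode_kmer(kmer) == code
        assert kt.decode_kmer(code) == kmer

    def test_bijection_exhaustive(self):
        seen = set()
        for code in range(NUM_CODES):
            s = kt.decode_kmer(code)
            assert kt.encode_kmer(s) == code
            seen.add(s)
        assert len(seen) == NUM_CODES

    def test_lexicographic_order(self):
        # the chosen bit mapping sorts codes with the sequences
        assert kt.encode_kmer("AACGTACG") < kt.encode_kmer("ACGTAACG")

    def test_u_reads_as_t(self):
        assert kt.encode_kmer("ACGUACGU") == kt.encode_kmer("ACGTACGT")

    @pytest.mark.parametrize("bad", ["ACGT", "ACGTACGTA", "ACGNACGT", "acgtacgX"])
    def test_invalid_kmer(self, bad):
        with pytest.raises(kt.InvalidKmerError):
            kt.encode_kmer(bad)

    def test_revcomp_codes(self):
        c = np.array([kt.encode_kmer("AACCGGTT")], dtype=np.uint32)
        assert kt.decode_kmer(int(revcomp_codes(c)[0])) == "AACCGGTT"
        c2 = np.array([kt.encode_kmer("AAAAAAAA")], dtype=np.uint32)
        assert kt.decode_kmer(int(revcomp_codes(c2)[0])) == "TTTTTTTT"


class TestExtraction:
    def test_short_sequence_empty(self):
        assert len(kt.extract_kmer_set("ACGTACG")) == 0

    def test_two_windows(self):
        ks = kt.extract_kmer_set("ACGTACGTA")
        assert ks.codes.tolist() == sorted(
            [kt.encode_kmer("ACGTACGT"), kt.encode_kmer("CGTACGTA")]
        )

    def test_ambiguity_invalidates_windows(self):
        # both flanks of the N are the same 8-mer, so the set has one element
        assert len(kt.extract_kmer_set("ACGTACGTNACGTACGT")) == 1
        # distinct flanks survive as two elements
        ks = kt.extract_kmer_set("ACGTACGTNTGCATGCA")
        assert set(ks.codes.tolist()) == {
            kt.encode_kmer("ACGTACGT"),
            kt.encode_kmer("TGCATGCA"),
        }

    def test_gap_and_dot_invalidate(self):
        assert len(kt.extract_kmer_set("ACGT-ACGTACG.ACG")) == 0

    def test_sorted_and_unique(self):
        ks = kt.extract_kmer_set("ACGTACGTACGTACGTACGT")
        codes = ks.codes
        assert (np.diff(codes) > 0).all()

    @given(st.text(alphabet="ACGTNacgtn-", min_size=0, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_case_invariance(self, seq):
        lo = kt.extract_kmer_set(seq.lower()).codes
        hi = kt.extract_kmer_set(seq.upper()).codes
        assert np.array_equal(lo, hi)

    def test_revcomp_extraction_superset(self):
        seq = "ACGTTGCACCGT"
        fwd = set(kt.extract_kmer_set(seq).codes.tolist())
        both = set(kt.extract_kmer_set(seq, include_revcomp=True).codes.tolist())
        assert fwd <= both
        assert kt.encode_kmer("ACGGTGCA") in both  # revcomp of TGCACCGT


class TestIndex:
    def test_single_record_postings(self):
        idx = kt.build_reference_index(
            [("r1", [("s", "Sp1")], "ACGTACGTA")]
        )
        nonempty = [c for c in range(NUM_CODES) if idx.postings[c] is not None]
        assert len(nonempty) == 2
        for c in nonempty:
            assert idx.postings[c].tolist() == [0]
        assert idx.records[0].kmer_count == 2

    def test_identical_sequences_share_postings(self):
        idx = kt.build_reference_index(
            [
                ("r1", [("s", "Sp1")], "ACGTACGTACGT"),
                ("r2", [("s", "Sp2")], "ACGTACGTACGT"),
            ]
        )
        for c in range(NUM_CODES):
            if idx.postings[c] is not None:
                assert idx.postings[c].tolist() == [0, 1]

    def test_disjoint_reference_never_shares_postings(self):
        # r3 is poly-AC, r1/r2 are poly-GT: no common 8-mer
        idx = kt.build_reference_index(
            [
                ("r1", [("s", "Sp1")], "GTGTGTGTGTGT"),
                ("r2", [("s", "Sp2")], "TGTGTGTGTGTG"),
                ("r3", [("s", "Sp3")], "ACACACACACAC"),
            ]
        )
        leaf3 = idx.tree.leaf_ids.index("r3")
        for c in range(NUM_CODES):
            p = idx.postings[c]
            if p is not None and leaf3 in p.tolist():
                assert p.tolist() == [leaf3]

    def test_duplicate_ref_id_rejected(self):
        with pytest.raises(kt.IndexBuildError, match="duplicate"):
            kt.build_reference_index(
                [("r", [("s", "A")], "ACGTACGT"), ("r", [("s", "B")], "ACGTACGT")]
            )

    def test_empty_input_rejected(self):
        with pytest.raises(kt.IndexBuildError):
            kt.build_reference_index([])

    def test_kmer_count_matches_postings(self, toy_index):
        for i, rec in enumerate(toy_index.records):
            n = sum(
                1
                for c in range(NUM_CODES)
                if toy_index.postings[c] is not None
                and i in toy_index.postings[c].tolist()
            )
            assert n == rec.kmer_count

    def test_build_deterministic(self, toy_records):
        a = kt.build_reference_index(toy_records)
        b = kt.build_reference_index(list(reversed(toy_records)))
        assert [r.ref_id for r in a.records] == [r.ref_id for r in b.records]
        for c in range(NUM_CODES):
            pa, pb = a.postings[c], b.postings[c]
            assert (pa is None) == (pb is None)
            if pa is not None:
                assert np.array_equal(pa, pb)


class TestIntersections:
    def test_self_match(self, toy_records, toy_index):
        rid, _, seq = toy_records[0]
        leaf = toy_index.tree.leaf_ids.index(rid)
        counts = kt.intersection_counts(toy_index, kt.extract_kmer_set(seq))
        d = counts.as_dict()
        assert d[leaf] == toy_index.records[leaf].kmer_count

    def test_no_overlap_empty(self, toy_index):
        q = kt.KmerSet(np.empty(0, dtype=np.uint32), 0)
        counts = kt.intersection_counts(toy_index, q)
        assert counts.indices.size == 0

    def test_matches_brute_force_random(self, toy_records, toy_index):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        for _ in range(25):
            qseq = "".join(bases[i] for i in rng.integers(0, 4, size=60))
            counts = kt.intersection_counts(toy_index, kt.extract_kmer_set(qseq))
            got = {
                toy_index.records[i].ref_id: int(c)
                for i, c in zip(counts.indices, counts.counts)
            }
            assert got == brute_force_intersections(toy_records, qseq)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, derandomize=True)
    def test_matches_brute_force_property(self, seed):
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        n_refs = int(rng.integers(1, 20))
        records = [
            (
                f"r{i}",
                [("s", f"S{i}")],
                "".join(bases[j] for j in rng.integers(0, 4, size=int(rng.integers(8, 100)))),
            )
            for i in range(n_refs)
        ]
        idx = kt.build_reference_index(records)
        qseq = "".join(bases[j] for j in rng.integers(0, 4, size=int(rng.integers(0, 150))))
        counts = kt.intersection_counts(idx, kt.extract_kmer_set(qseq))
        got = {
            idx.records[i].ref_id: int(c)
            for i, c in zip(counts.indices, counts.counts)
        }
        assert got == brute_force_intersections(records, qseq)


class TestPersistence:
    def test_round_trip_equality(self, toy_index, tmp_path):
        p = tmp_path / "toy.kmtx"
        kt.save_index(toy_index, p)
        loaded = kt.load_index(p)
        assert loaded.format_version == toy_index.format_version
        assert loaded.records == toy_index.records
        assert loaded.tree.leaf_ids == toy_index.tree.leaf_ids
        for c in range(NUM_CODES):
            pa, pb = toy_index.postings[c], loaded.postings[c]
            assert (pa is None) == (pb is None)
            if pa is not None:
                assert np.array_equal(pa, pb)

    def test_wrong_magic(self, tmp_path):
        p = tmp_path / "bad.kmtx"
        p.write_bytes(b"NOPE" + b"\x00" * 32)
        with pytest.raises(kt.IndexLoadError, match="magic"):
            kt.load_index(p)

    def test_version_mismatch(self, toy_index, tmp_path):
        p = tmp_path / "v.kmtx"
        kt.save_index(toy_index, p)
        raw = bytearray(p.read_bytes())
        raw[4] = 99
        p.write_bytes(bytes(raw))
        with pytest.raises(kt.IndexLoadError, match="version"):
            kt.load_index(p)

    def test_truncated_file(self, toy_index, tmp_path):
        p = tmp_path / "t.kmtx"
        kt.save_index(toy_index, p)
        p.write_bytes(p.read_bytes()[:50])
        with pytest.raises(kt.IndexLoadError, match="truncated"):
            kt.load_index(p)
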