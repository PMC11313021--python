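"""Minimizer, sketch and end-mapping behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contigwire.hashing import encode_kmer, hash_kmer, revcomp
from contigwire.io_formats import SequenceRecord, write_mapping
from contigwire.sketch_mapper import (
    MapperParams,
    extract_minimizers,
    extract_read_ends,
    jem_sketch,
    map_reads_to_subjects,
    sketch_similarity,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMinimizers:
    def test_lexicographic_forward_example(self):
        # windows: (ACG,CGT)->ACG, (CGT,GTA)->CGT, (GTA,TAC)->GTA, (TAC,ACG)->ACG
        out = extract_minimizers("ACGTACG", k=3, w=2, ordering="lexicographic", canonical=False)
        assert out == {"ACG", "CGT", "GTA"}

    def test_too_short_sequence_yields_empty_set(self):
        assert extract_minimizers("ACGTA", k=4, w=3) == set()  # len == k+w-2

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_canonical_minimizers_strand_invariant(self, seed):
        rng = np.random.default_rng(seed)
        seq = _random_seq(rng, int(rng.integers(60, 400)))
        fwd = extract_minimizers(seq, k=11, w=5)
        rev = extract_minimizers(revcomp(seq), k=11, w=5)
        assert fwd == rev

    def test_kmers_containing_n_are_skipped(self):
        out = extract_minimizers("ACGTNACGT", k=4, w=2)
        assert all("N" not in m for m in out)


class TestSketches:
    def test_identical_sets_identical_sketch(self):
        mins = {"ACGTACGTACGTACG", "TTTTACGTACGTACG"}
        a = jem_sketch(mins, T=30, salt=7)
        b = jem_sketch(set(mins), T=30, salt=7)
        assert np.array_equal(a, b)

    def test_singleton_set_sketch_is_the_hash(self):
        m = "ACGTACGTACGTACG"
        sk = jem_sketch({m}, T=10, salt=3)
        expected = [int(hash_kmer(encode_kmer(m), 3 ^ t)) for t in range(10)]
        assert sk.tolist() == expected

    def test_empty_set_is_unsketchable(self):
        assert jem_sketch(set(), T=30, salt=0) is None

    def test_similarity_of_identical_sketches_is_one(self):
        sk = jem_sketch({"ACGTACGTACGTACG"}, T=30, salt=1)
        assert sketch_similarity(sk, sk) == 1.0

    def test_similarity_counts_agreeing_slots(self):
        a = np.arange(30, dtype=np.uint64)
        b = a.copy()
        b[15:] += 1000
        assert sketch_similarity(a, b) == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sketch_similarity(np.zeros(10, dtype=np.uint64), np.zeros(20, dtype=np.uint64))

    def test_disjoint_sets_similarity_zero(self):
        rng = np.random.default_rng(5)
        a = {_random_seq(rng, 15) for _ in range(200)}
        b = {_random_seq(rng, 15) for _ in range(200)} - a
        sim = sketch_similarity(jem_sketch(a, 30, 42), jem_sketch(b, 30, 42))
        assert sim == 0.0  # collisions have probability ~2^-64

    def test_slot_agreement_estimates_jaccard(self):
        # |A∩B| = 50 of |A∪B| = 100 -> J = 0.5; mean over salts ~ J
        rng = np.random.default_rng(6)
        pool = list({_random_seq(rng, 15) for _ in range(120)})[:100]
        shared, a_only, b_only = pool[:50], pool[50:75], pool[75:]
        A, B = set(shared + a_only), set(shared + b_only)
        sims = [
            sketch_similarity(jem_sketch(A, 30, s), jem_sketch(B, 30, s)) for s in range(100)
        ]
        assert abs(np.mean(sims) - 0.5) < 3 * np.sqrt(0.25 / 30)


class TestReadEnds:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (10_000, [("5p", 0, 2000), ("3p", 8000, 10_000)]),
            (3000, [("5p", 0, 2000), ("3p", 1000, 3000)]),
            (1500, [("whole", 0, 1500)]),
        ],
    )
    def test_end_extraction_windows(self, length, expected):
        rng = np.random.default_rng(7)
        read = SequenceRecord("r", _random_seq(rng, length))
        ends = extract_read_ends(read, 2000)
        assert [(lab, read.sequence[s:e]) for lab, s, e in expected] == ends


class TestMapping:
    def test_read_equal_to_contig_maps_with_similarity_one(self):
        rng = np.random.default_rng(8)
        contig = SequenceRecord("c", _random_seq(rng, 1500))
        read = SequenceRecord("r", contig.sequence)  # shorter than end_len: whole-read sketch
        tuples = map_reads_to_subjects([contig], [read], MapperParams(tau=0.5))
        assert len(tuples) == 1
        t = tuples[0]
        assert (t.contig_id, t.end, t.similarity, t.rank) == ("c", "whole", 1.0, 1)

    def test_junction_read_maps_each_end_to_its_contig(self):
        rng = np.random.default_rng(9)
        a = SequenceRecord("a", _random_seq(rng, 5000))
        b = SequenceRecord("b", _random_seq(rng, 5000))
        read = SequenceRecord("r", a.sequence[-3000:] + b.sequence[:3000])
        tuples = map_reads_to_subjects([a, b], [read], MapperParams(tau=0.2))
        best = {t.end: t.contig_id for t in tuples if t.rank == 1}
        assert best == {"5p": "a", "3p": "b"}

    def test_unrelated_read_produces_no_tuples(self):
        rng = np.random.default_rng(10)
        subjects = [SequenceRecord("c", _random_seq(rng, 5000))]
        read = SequenceRecord("r", _random_seq(rng, 6000))
        assert map_reads_to_subjects(subjects, [read], MapperParams(tau=0.2)) == []

    def test_strand_invariance_up_to_end_label_swap(self):
        rng = np.random.default_rng(11)
        subjects = [SequenceRecord(f"c{i}", _random_seq(rng, 4000)) for i in range(3)]
        genome = subjects[0].sequence + subjects[1].sequence
        read = SequenceRecord("r", genome[2000:8000])
        params = MapperParams()
        fwd = map_reads_to_subjects(subjects, [read], params)
        rev = map_reads_to_subjects(subjects, [read.reverse_complement()], params)
        swap = {"5p": "3p", "3p": "5p", "whole": "whole"}
        assert {(swap[t.end], t.contig_id, round(t.similarity, 9), t.rank) for t in fwd} == {
            (t.end, t.contig_id, round(t.similarity, 9), t.rank) for t in rev
        }

    def test_mapping_is_deterministic_bytewise(self, tmp_path, small_fixture):
        params = MapperParams()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        subjects, reads = small_fixture.contigs[:10], small_fixture.reads[:30]
        write_mapping(map_reads_to_subjects(subjects, reads, params), p1)
        write_mapping(map_reads_to_subjects(subjects, reads, params), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_top_n_caps_tuples_per_end(self, small_fixture):
        params = MapperParams(tau=0.0, top_n=1)
        tuples = map_reads_to_subjects(small_fixture.contigs[:8], small_fixture.reads[:20], params)
        per_end = {}
        for t in tuples:
            per_end[(t.read_id, t.end)] = per_end.get((t.read_id, t.end), 0) + 1
        # with top_n=1 a read maps to at most two subjects, one per end
        assert all(v == 1 for v in per_end.values())
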