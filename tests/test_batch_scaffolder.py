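"""Batching, anchor chaining, stitching and within-batch merging."""

import numpy as np
import pytest

from contigwire.batch_scaffolder import (
    StitchParams,
    assemble_batches,
    chain_anchors,
    collect_batch_reads,
    merge_batch_scaffolds,
    partition_into_batches,
    split_at_fallback_gaps,
    stitch_path,
)
from contigwire.hashing import revcomp
from contigwire.io_formats import MappingTuple, SequenceRecord
from contigwire.wiring import Path


def _seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _path(ids):
    return Path([(c, "?") for c in ids])


class TestBatching:
    def test_small_paths_share_one_batch(self):
        paths = [_path([f"c{i}a", f"c{i}b", f"c{i}c"]) for i in range(10)]
        assert len(partition_into_batches(paths, 8192)) == 1

    def test_first_fit_descending_capacity_six(self):
        paths = [_path([f"p{i}_{j}" for j in range(n)]) for i, n in enumerate([5, 4, 3])]
        batches = partition_into_batches(paths, 6)
        assert [b.n_contigs() for b in batches] == [5, 4, 3]

    def test_oversize_path_gets_own_batch(self):
        big = _path([f"c{i}" for i in range(10)])
        batches = partition_into_batches([big], 4)
        assert len(batches) == 1 and batches[0].n_contigs() == 10

    def test_batching_conserves_paths(self):
        rng = np.random.default_rng(0)
        paths = [
            _path([f"p{i}_{j}" for j in range(int(rng.integers(1, 9)))]) for i in range(30)
        ]
        batches = partition_into_batches(paths, 10)
        flat = sorted(tuple(p.step_ids()) for b in batches for p in b.paths)
        assert flat == sorted(tuple(p.step_ids()) for p in paths)

    def test_collect_batch_reads_unions_mapped_reads(self):
        batch = partition_into_batches([_path(["A"])], 10)[0]
        mapping = [
            MappingTuple("r1", "5p", "A", 0.5, 1),
            MappingTuple("r2", "3p", "A", 0.5, 1),
            MappingTuple("r3", "5p", "B", 0.5, 1),
        ]
        assert collect_batch_reads(batch, mapping) == {"r1", "r2"}

    def test_bridging_read_appears_in_both_batches(self):
        batches = partition_into_batches([_path(["A"]), _path(["B"])], 1)
        mapping = [MappingTuple("r1", "5p", "A", 0.5, 1), MappingTuple("r1", "3p", "B", 0.5, 1)]
        assert all(collect_batch_reads(b, mapping) == {"r1"} for b in batches)


class TestAnchorChains:
    def test_embedded_contig_found_on_plus_strand(self):
        rng = np.random.default_rng(1)
        contig = SequenceRecord("c", _seq(rng, 800))
        read = SequenceRecord("r", _seq(rng, 500) + contig.sequence + _seq(rng, 300))
        chain = chain_anchors(read, contig, anchor_k=21, min_anchors=5)
        assert chain is not None and chain.strand == "+"
        assert chain.diagonal == 500
        assert chain.n_anchors >= 5

    def test_reverse_complement_embedding_found_on_minus_strand(self):
        rng = np.random.default_rng(2)
        contig = SequenceRecord("c", _seq(rng, 800))
        read = SequenceRecord("r", _seq(rng, 200) + revcomp(contig.sequence) + _seq(rng, 100))
        chain = chain_anchors(read, contig)
        assert chain is not None and chain.strand == "-" and chain.diagonal == 200

    def test_unrelated_pair_yields_no_chain(self):
        rng = np.random.default_rng(3)
        assert chain_anchors(SequenceRecord("r", _seq(rng, 2000)),
                             SequenceRecord("c", _seq(rng, 1000))) is None


class TestStitching:
    def _two_contig_setup(self, rng, gap=10, flip_b=False, read_margin=300):
        genome = _seq(rng, 4000)
        a = SequenceRecord("a", genome[500:1800])
        bseq = genome[1800 + gap:3300]
        b = SequenceRecord("b", revcomp(bseq) if flip_b else bseq)
        read = SequenceRecord("r", genome[1800 - read_margin - 700:3300 - 1200])
        linking = {frozenset(("a", "b")): [read]}
        return genome, {"a": a, "b": b}, linking

    def test_single_contig_path_passthrough(self):
        rng = np.random.default_rng(4)
        contig = SequenceRecord("a", _seq(rng, 900))
        scaf = stitch_path(_path(["a"]), {"a": contig}, {})
        assert scaf.sequence == contig.sequence
        assert len(scaf.components) == 1 and scaf.components[0].orientation == "+"

    @pytest.mark.parametrize("flip_b", [False, True])
    def test_spanning_read_reconstructs_genome_substring(self, flip_b):
        rng = np.random.default_rng(5)
        genome, contigs, linking = self._two_contig_setup(rng, gap=10, flip_b=flip_b)
        scaf = stitch_path(_path(["a", "b"]), contigs, linking, StitchParams())
        assert scaf.sequence == genome[500:3300]
        scaf.validate()

    def test_no_linking_read_falls_back_to_n_gap(self):
        rng = np.random.default_rng(6)
        a = SequenceRecord("a", _seq(rng, 700))
        b = SequenceRecord("b", _seq(rng, 600))
        scaf = stitch_path(_path(["a", "b"]), {"a": a, "b": b}, {}, StitchParams(gap_default=100))
        assert scaf.sequence == a.sequence + "N" * 100 + b.sequence

    def test_antisense_path_flips_first_contig(self):
        # both contigs stored antisense to the genome: the junction read must
        # flip the first one so the scaffold is a genome substring (rc'd whole)
        rng = np.random.default_rng(7)
        genome = _seq(rng, 4000)
        a = SequenceRecord("a", revcomp(genome[500:1800]))
        b = SequenceRecord("b", revcomp(genome[1810:3300]))
        read = SequenceRecord("r", genome[1000:3100])
        linking = {frozenset(("a", "b")): [read]}
        scaf = stitch_path(_path(["a", "b"]), {"a": a, "b": b}, linking)
        assert scaf.sequence in (genome[500:3300], revcomp(genome[500:3300]))

    def test_components_rebuild_scaffold(self):
        rng = np.random.default_rng(8)
        genome, contigs, linking = self._two_contig_setup(rng, gap=40)
        read = linking[frozenset(("a", "b"))][0]
        scaf = stitch_path(_path(["a", "b"]), contigs, linking)
        sources = {c.id: c.sequence for c in contigs.values()} | {read.id: read.sequence}
        assert scaf.rebuild_sequence(sources) == scaf.sequence


class TestSplitAndMerge:
    def test_split_at_fallback_gap_pieces_rebuild(self):
        rng = np.random.default_rng(9)
        a = SequenceRecord("a", _seq(rng, 700))
        b = SequenceRecord("b", _seq(rng, 600))
        scaf = stitch_path(_path(["a", "b"]), {"a": a, "b": b}, {})
        pieces = split_at_fallback_gaps(scaf)
        assert [p.sequence for p in pieces] == [a.sequence, b.sequence]

    def test_merge_rejoins_read_bridged_scaffolds(self):
        rng = np.random.default_rng(10)
        genome = _seq(rng, 5000)
        a = SequenceRecord("a", genome[0:2000])
        b = SequenceRecord("b", genome[2300:4500])
        read = SequenceRecord("r", genome[1200:3500])
        s1 = stitch_path(_path(["a"]), {"a": a}, {}, scaffold_id="s1")
        s2 = stitch_path(_path(["b"]), {"b": b}, {}, scaffold_id="s2")
        linking = {frozenset(("a", "b")): [read]}
        merged = merge_batch_scaffolds([s1, s2], linking, StitchParams())
        assert len(merged) == 1
        assert merged[0].sequence in (genome[0:4500], revcomp(genome[0:4500]))

    def test_merge_rejects_containment_bridge(self):
        rng = np.random.default_rng(11)
        genome = _seq(rng, 5000)
        a = SequenceRecord("a", genome[0:3000])
        b = SequenceRecord("b", genome[1000:2000])  # contained in a's span
        read = SequenceRecord("r", genome[500:2500])
        s1 = stitch_path(_path(["a"]), {"a": a}, {}, scaffold_id="s1")
        s2 = stitch_path(_path(["b"]), {"b": b}, {}, scaffold_id="s2")
        merged = merge_batch_scaffolds([s1, s2], {frozenset(("a", "b")): [read]}, StitchParams())
        assert len(merged) == 2  # not a linear join


class TestAssembleBatches:
    def test_empty_batch_list(self):
        assert assemble_batches([], {}, {}, {}) == []

    def test_worker_count_does_not_change_output(self):
        rng = np.random.default_rng(12)
        genome = _seq(rng, 6000)
        contigs = {
            "a": SequenceRecord("a", genome[0:1500]),
            "b": SequenceRecord("b", genome[1600:3100]),
            "c": SequenceRecord("c", genome[3200:4700]),
            "d": SequenceRecord("d", genome[4800:6000]),
        }
        reads = {
            "r1": SequenceRecord("r1", genome[800:2400]),
            "r2": SequenceRecord("r2", genome[4000:5600]),
        }
        linking = {
            frozenset(("a", "b")): [reads["r1"]],
            frozenset(("c", "d")): [reads["r2"]],
        }
        batches = partition_into_batches([_path(["a", "b"]), _path(["c", "d"])], 2)
        one = assemble_batches(batches, contigs, reads, linking, n_workers=1)
        four = assemble_batches(batches, contigs, reads, linking, n_workers=4)
        assert [(s.id, s.sequence) for s in one] == [(s.id, s.sequence) for s in four]
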