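"""Turn enumerated paths into scaffold sequences, in fixed-size batches.

Paths are partitioned into batches of at most ``batch_size`` contigs so each
batch (its contigs plus the long reads mapped to them) is an independent
assembly task. The built-in stitcher places each consecutive contig pair on
the best linking read via unique-k-mer anchor chains, which resolves relative
orientation and either fills the inter-contig gap with read bases or merges a
small overlap (contig bases win). An external assembler backend can be
substituted per batch; the built-in stitcher is the tested code path.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path as FsPath
from typing import Iterable, Mapping, Sequence

from .hashing import revcomp
from .io_formats import Component, MappingTuple, ScaffoldRecord, SequenceRecord, read_sequences, write_sequences
from .wiring import Path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StitchParams:
    """Stitching knobs: anchor k-mer size, chain evidence floor, N-gap size."""

    anchor_k: int = 21
    min_anchors: int = 5
    gap_default: int = 100
    batch_size: int = 8192
    merge_within_batch: bool = True
    #: Largest placement overlap accepted at a junction. Shredded contigs and
    #: phase scaffolds never genuinely overlap by more than the anchor jitter,
    #: so a large implied overlap is the signature of a repeat-confused chain;
    #: read-vs-read (island) assembly raises this, as read overlaps are real.
    max_junction_overlap: int = 500

    def __post_init__(self):
        if not 0 < self.anchor_k <= 31:
            raise ValueError("anchor_k must be in (0, 31]")
        if self.min_anchors < 1 or self.gap_default < 0 or self.batch_size < 1:
            raise ValueError("invalid stitch parameters")


@dataclass
class Batch:
    batch_id: int
    paths: list[Path]
    read_ids: set[str] = field(default_factory=set)

    def n_contigs(self) -> int:
        return sum(len(p) for p in self.paths)


@dataclass(frozen=True)
class AnchorChain:
    """A co-linear run of unique shared k-mers placing a contig on a read.

    ``strand`` is the orientation of the contig on the read; offsets refer to
    the *oriented* contig (the reverse complement when strand is '-').
    ``read_offset - contig_offset`` is the chain diagonal: the read coordinate
    of the oriented contig's first base (may fall outside the read when the
    contig overhangs it).
    """

    read_id: str
    contig_id: str
    read_offset: int
    contig_offset: int
    strand: str
    n_anchors: int

    @property
    def diagonal(self) -> int:
        return self.read_offset - self.contig_offset


# ---------------------------------------------------------------------------
# Batching


def partition_into_batches(paths: Sequence[Path], s: int) -> list[Batch]:
    """Greedy first-fit in descending path length; a path is never split.

    A single path longer than ``s`` gets its own (oversize) batch.
    """
    if s < 1:
        raise ValueError("batch size must be >= 1")
    order = sorted(paths, key=lambda p: (-len(p), p.step_ids()[0]))
    batches: list[Batch] = []
    loads: list[int] = []
    for p in order:
        for i, load in enumerate(loads):
            if load + len(p) <= s:
                batches[i].paths.append(p)
                loads[i] += len(p)
                break
        else:
            batches.append(Batch(len(batches), [p]))
            loads.append(len(p))
    return batches


def collect_batch_reads(batch: Batch, mapping: Iterable[MappingTuple]) -> set[str]:
    """Union of read ids mapped to any contig of the batch."""
    contigs = {cid for p in batch.paths for cid in p.step_ids()}
    return {t.read_id for t in mapping if t.contig_id in contigs}


# ---------------------------------------------------------------------------
# Anchor chaining


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int | None] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        pos[kmer] = None if kmer in pos else i
    return {kmer: p for kmer, p in pos.items() if p is not None}


def chain_anchors(
    read: SequenceRecord,
    contig: SequenceRecord,
    anchor_k: int = 21,
    min_anchors: int = 5,
) -> AnchorChain | None:
    """Best strand-consistent co-linear anchor chain of contig onto read.

    Anchors are k-mers unique within both sequences; the densest common
    diagonal (read position minus oriented-contig position) wins. Returns
    None when fewer than ``min_anchors`` anchors support the best diagonal.
    """
    read_pos = _unique_kmer_positions(read.sequence, anchor_k)
    best: AnchorChain | None = None
    for strand in "+-":
        oriented = contig.sequence if strand == "+" else revcomp(contig.sequence)
        contig_pos = _unique_kmer_positions(oriented, anchor_k)
        diagonals: dict[int, int] = {}
        for kmer, cpos in contig_pos.items():
            rpos = read_pos.get(kmer)
            if rpos is not None:
                diagonals[rpos - cpos] = diagonals.get(rpos - cpos, 0) + 1
        if not diagonals:
            continue
        diag, count = max(diagonals.items(), key=lambda kv: (kv[1], -abs(kv[0])))
        if count < min_anchors:
            continue
        candidate = AnchorChain(
            read_id=read.id,
            contig_id=contig.id,
            read_offset=max(diag, 0),
            contig_offset=max(-diag, 0),
            strand=strand,
            n_anchors=count,
        )
        if best is None or candidate.n_anchors > best.n_anchors:
            best = candidate
    return best


# ---------------------------------------------------------------------------
# Stitching


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _oriented_placement(chain: AnchorChain, read_len: int, contig_len: int, rho: str) -> tuple[str, int]:
    """(orientation, start) of the contig on the rho-oriented read."""
    if rho == "+":
        return chain.strand, chain.diagonal
    return _flip(chain.strand), read_len - chain.diagonal - contig_len


def stitch_path(
    path: Path,
    contigs: Mapping[str, SequenceRecord],
    linking_reads: Mapping[frozenset, list[SequenceRecord]],
    params: StitchParams | None = None,
    scaffold_id: str = "scaffold",
) -> ScaffoldRecord:
    """Walk consecutive contig pairs and join them on their best linking read.

    The first contig is fixed to '+'; each junction read (oriented to agree
    with the already-placed left contig) determines the next contig's
    orientation and either contributes its intervening bases as a read
    component or, on overlap, trims the incoming contig (contig bases are
    preferred). Junctions with no consistent dual-anchored read are joined by
    a run of ``gap_default`` N.
    """
    params = params or StitchParams()
    steps = path.owned_steps()
    for cid, _ in steps:
        if cid not in contigs:
            raise KeyError(f"contig {cid!r} missing from sequence map")

    first_id = steps[0][0]
    parts: list[str] = [contigs[first_id].sequence]
    components: list[Component] = [
        Component(first_id, "+", 0, len(contigs[first_id].sequence), 0, kind="contig")
    ]
    cur_orient = "+"
    pos = len(parts[0])

    for junction, ((u, _), (v, _)) in enumerate(zip(steps, steps[1:])):
        seq_u, seq_v = contigs[u], contigs[v]
        candidates = sorted(linking_reads.get(frozenset((u, v)), []), key=lambda r: r.id)
        # The first contig's orientation is nominally '+', but the first
        # junction read is allowed to flip it: a path walked antisense to the
        # genome places the successor to the *left* of a '+'-oriented start.
        allowed_u = ("+", "-") if junction == 0 else (cur_orient,)
        best = None  # (score, o_u, rho, d_u, d_v, o_v, read)
        for read in candidates:
            cu = chain_anchors(read, seq_u, params.anchor_k, params.min_anchors)
            cv = chain_anchors(read, seq_v, params.anchor_k, params.min_anchors)
            if cu is None or cv is None:
                continue
            L = len(read.sequence)
            for o_u in allowed_u:
                rho = "+" if cu.strand == o_u else "-"
                _, d_u = _oriented_placement(cu, L, len(seq_u.sequence), rho)
                o_v, d_v = _oriented_placement(cv, L, len(seq_v.sequence), rho)
                end_u = d_u + len(seq_u.sequence)
                if d_v <= d_u:  # v must extend to the right of u
                    continue
                if d_v > end_u and (end_u < 0 or d_v > L):  # gap bases not on the read
                    continue
                overlap = end_u - d_v
                if overlap >= len(seq_v.sequence):  # containment: not a linear join
                    continue
                if overlap > params.max_junction_overlap:
                    continue
                score = cu.n_anchors + cv.n_anchors
                if best is None or score > best[0]:
                    best = (score, o_u, rho, d_u, d_v, o_v, read)
        if best is not None and best[1] != cur_orient:  # flip the lone first contig
            from .hashing import revcomp as _rc

            parts[0] = _rc(parts[0])
            components[0] = Component(first_id, "-", 0, len(parts[0]), 0, kind="contig")
            cur_orient = "-"

        if best is None:
            gap = params.gap_default
            parts.append("N" * gap + seq_v.sequence)
            components.append(
                Component(v, "+", pos + gap, pos + gap + len(seq_v.sequence), gap, kind="contig")
            )
            cur_orient = "+"
            pos += gap + len(seq_v.sequence)
            continue

        _, _, rho, d_u, d_v, o_v, read = best
        L = len(read.sequence)
        end_u = d_u + len(seq_u.sequence)
        oriented_read = read.sequence if rho == "+" else revcomp(read.sequence)
        if d_v >= end_u:
            fill = oriented_read[end_u:d_v]
            if fill:
                if rho == "+":
                    src = (end_u, d_v)
                else:
                    src = (L - d_v, L - end_u)
                components.append(
                    Component(read.id, rho, pos, pos + len(fill), 0,
                              source_start=src[0], source_end=src[1], kind="read")
                )
                parts.append(fill)
                pos += len(fill)
            trim = 0
        else:
            trim = end_u - d_v
            if trim >= len(seq_v.sequence):  # v contained in u on this read: degenerate
                gap = params.gap_default
                parts.append("N" * gap + seq_v.sequence)
                components.append(
                    Component(v, "+", pos + gap, pos + gap + len(seq_v.sequence), gap, kind="contig")
                )
                cur_orient = "+"
                pos += gap + len(seq_v.sequence)
                continue
        v_seq = seq_v.sequence if o_v == "+" else revcomp(seq_v.sequence)
        v_seq = v_seq[trim:]
        if o_v == "+":
            src = (trim, len(seq_v.sequence))
        else:
            src = (0, len(seq_v.sequence) - trim)
        components.append(
            Component(v, o_v, pos, pos + len(v_seq), 0,
                      source_start=src[0], source_end=src[1], kind="contig")
        )
        parts.append(v_seq)
        pos += len(v_seq)
        cur_orient = o_v

    scaffold = ScaffoldRecord(scaffold_id, "".join(parts), components)
    scaffold.validate()
    return scaffold


# ---------------------------------------------------------------------------
# Within-batch scaffold merging
#
# A standalone batch assembler does not stop at path boundaries: it joins any
# two sequences of the batch that a read bridges. The built-in stand-in does
# the same after per-path stitching: contig-graph edges whose endpoints fell
# into different path scaffolds nominate junctions, each is validated by dual
# anchor chains of one linking read against both scaffold sequences, and
# scaffolds are chained greedily (each scaffold end joins at most once, no
# cycles). This step, not path enumeration, is what grows scaffolds past the
# reach of any single wiring decision.


@dataclass(frozen=True)
class _Junction:
    """A validated read bridge between two scaffolds, in read coordinates.

    ``first`` is the scaffold starting earlier on the (as-stored) read.
    """

    first: str
    second: str
    sigma_first: str
    sigma_second: str
    d_first: int
    d_second: int
    len_first: int
    len_second: int
    read: SequenceRecord
    score: int

    @property
    def trim(self) -> int:
        return max(0, self.d_first + self.len_first - self.d_second)

    def port_first(self) -> tuple[str, str]:
        return (self.first, "R" if self.sigma_first == "+" else "L")

    def port_second(self) -> tuple[str, str]:
        return (self.second, "L" if self.sigma_second == "+" else "R")


def _best_junction(A: ScaffoldRecord, B: ScaffoldRecord, reads, params: StitchParams) -> _Junction | None:
    recA = SequenceRecord(A.id, A.sequence)
    recB = SequenceRecord(B.id, B.sequence)
    best = None
    for read in sorted(reads, key=lambda r: r.id):
        ca = chain_anchors(read, recA, params.anchor_k, params.min_anchors)
        cb = chain_anchors(read, recB, params.anchor_k, params.min_anchors)
        if ca is None or cb is None:
            continue
        if ca.diagonal <= cb.diagonal:
            (F, cf), (S, cs) = (A, ca), (B, cb)
        else:
            (F, cf), (S, cs) = (B, cb), (A, ca)
        eF = cf.diagonal + len(F.sequence)
        trim = eF - cs.diagonal
        if trim >= len(S.sequence):  # containment: not a linear join
            continue
        if trim > params.max_junction_overlap:
            continue
        L = len(read.sequence)
        if trim < 0 and (eF < 0 or cs.diagonal > L):  # gap bases must lie on the read
            continue
        score = ca.n_anchors + cb.n_anchors
        if best is None or score > best.score:
            best = _Junction(F.id, S.id, cf.strand, cs.strand, cf.diagonal, cs.diagonal,
                             len(F.sequence), len(S.sequence), read, score)
    return best


def split_at_fallback_gaps(scaf: ScaffoldRecord) -> list[ScaffoldRecord]:
    """Split a stitched scaffold at its N-gap (fallback) junctions.

    A junction that no linking read could place consistently is either a
    genuinely unspanned gap or a chimeric path step (e.g. a repeat-induced
    edge); the within-batch merge pass re-joins the split pieces wherever a
    read bridge passes geometric validation, so only unsupported joins stay
    dissolved.
    """
    groups: list[list[Component]] = []
    for comp in scaf.components:
        if not groups or comp.gap_before > 0:
            groups.append([])
        groups[-1].append(comp)
    if len(groups) <= 1:
        return [scaf]
    out = []
    for i, group in enumerate(groups):
        offset = group[0].start
        seq = scaf.sequence[offset:group[-1].end]
        comps = [
            replace(c, start=c.start - offset, end=c.end - offset,
                    gap_before=0 if k == 0 else c.gap_before)
            for k, c in enumerate(group)
        ]
        piece = ScaffoldRecord(f"{scaf.id}s{i}", seq, comps)
        piece.validate()
        out.append(piece)
    return out


def merge_batch_scaffolds(
    scaffolds: list[ScaffoldRecord],
    linking_reads: Mapping[frozenset, list[SequenceRecord]],
    params: StitchParams,
) -> list[ScaffoldRecord]:
    """Chain path scaffolds of one batch along unconsumed read bridges."""
    by_id = {s.id: s for s in scaffolds}
    owner: dict[str, str] = {}
    for s in scaffolds:
        for c in s.components:
            if c.kind == "contig":
                owner[c.source_id] = s.id

    pair_reads: dict[tuple[str, str], dict[str, SequenceRecord]] = {}
    for edge, reads in linking_reads.items():
        u, v = tuple(edge)
        a, b = owner.get(u), owner.get(v)
        if a is None or b is None or a == b:
            continue
        bucket = pair_reads.setdefault(tuple(sorted((a, b))), {})
        for r in reads:
            bucket[r.id] = r

    candidates = []
    for (a, b), bucket in sorted(pair_reads.items()):
        j = _best_junction(by_id[a], by_id[b], bucket.values(), params)
        if j is not None:
            candidates.append((len(bucket), j.score, a, b, j))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))

    parent = {sid: sid for sid in by_id}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ports_used: set[tuple[str, str]] = set()
    joins_at: dict[tuple[str, str], _Junction] = {}
    for _support, _score, a, b, j in candidates:
        pf, ps = j.port_first(), j.port_second()
        if pf in ports_used or ps in ports_used or find(a) == find(b):
            continue
        ports_used.update((pf, ps))
        joins_at[pf] = j
        joins_at[ps] = j
        parent[find(a)] = find(b)

    degree = {}
    for sid, _port in joins_at:
        degree[sid] = degree.get(sid, 0) + 1

    merged: list[ScaffoldRecord] = []
    visited: set[str] = set()
    for sid in sorted(by_id):
        if sid in visited:
            continue
        if degree.get(sid, 0) == 0:
            visited.add(sid)
            merged.append(by_id[sid])
            continue
        if degree.get(sid, 0) == 2:
            continue  # chain interior; reached from an endpoint
        merged.append(_stitch_chain(sid, by_id, joins_at, visited, params))
    return merged


def _stitch_chain(start: str, by_id, joins_at, visited, params: StitchParams) -> ScaffoldRecord:
    # Endpoint orientation: the single used port faces into the chain.
    o0 = "+" if (start, "R") in joins_at else "-"
    X, oX = start, o0
    visited.add(X)
    seqX = by_id[X].sequence if oX == "+" else revcomp(by_id[X].sequence)
    parts = [seqX]
    items = [("comp", Component(X, oX, 0, len(seqX), 0, kind="contig"))]
    prev_junction = None
    while True:
        exit_port = (X, "R" if oX == "+" else "L")
        j = joins_at.get(exit_port)
        if j is None or j is prev_junction:
            break
        forward = X == j.first
        Y = j.second if forward else j.first
        oY = ("+" if j.sigma_second == "+" else "-") if forward else ("+" if j.sigma_first == "-" else "-")
        eF = j.d_first + j.len_first
        gap = j.d_second - eF
        trim = max(0, -gap)
        if gap > 0:
            orient = "+" if forward else "-"
            fill = j.read.sequence[eF:j.d_second]
            parts.append(fill if orient == "+" else revcomp(fill))
            items.append(("comp", Component(j.read.id, orient, 0, gap, 0,
                                            source_start=eF, source_end=j.d_second, kind="read")))
        seq_y = by_id[Y].sequence
        if oY == "+":
            src = (trim, len(seq_y))
            seg = seq_y[trim:]
        else:
            src = (0, len(seq_y) - trim)
            seg = revcomp(seq_y[:len(seq_y) - trim])
        parts.append(seg)
        items.append(("comp", Component(Y, oY, 0, len(seg), 0,
                                        source_start=src[0], source_end=src[1], kind="contig")))
        visited.add(Y)
        prev_junction = j
        X, oX = Y, oY

    from .io_formats import _materialize_items, flatten_scaffold

    nested = _materialize_items(f"chain_{start}", "".join(parts), items)
    return flatten_scaffold(nested, {sid: by_id[sid] for sid in by_id})


# ---------------------------------------------------------------------------
# Batch assembly


def build_linking_reads(graph, reads: Mapping[str, SequenceRecord]) -> dict[frozenset, list[SequenceRecord]]:
    """Per-edge linking read records from the contig graph's link sets."""
    out: dict[frozenset, list[SequenceRecord]] = {}
    for u, v, data in graph.edges(data=True):
        recs = [reads[r] for r in sorted(data["read_ids"]) if r in reads]
        out[frozenset((u, v))] = recs
    return out


def _stitch_batch(args):
    batch, contigs, linking_reads, params = args
    out = []
    for i, p in enumerate(batch.paths):
        out.append(stitch_path(p, contigs, linking_reads, params, scaffold_id=f"path{i:05d}"))
    if params.merge_within_batch:
        out = [piece for s in out for piece in split_at_fallback_gaps(s)]
        if len(out) > 1:
            out = merge_batch_scaffolds(out, linking_reads, params)
    return [
        ScaffoldRecord(f"scaffold_b{batch.batch_id}_p{i}", s.sequence, s.components)
        for i, s in enumerate(out)
    ]


def assemble_batches(
    batches: Sequence[Batch],
    contigs: Mapping[str, SequenceRecord],
    reads: Mapping[str, SequenceRecord],
    linking_reads: Mapping[frozenset, list[SequenceRecord]],
    params: StitchParams | None = None,
    backend: str = "builtin",
    backend_cmd: str | None = None,
    workdir=None,
    n_workers: int = 1,
) -> list[ScaffoldRecord]:
    """Assemble every batch; output order is deterministic (batch, path).

    ``backend='external-command'`` writes each batch's contigs and reads to a
    FASTA under ``workdir`` and invokes ``backend_cmd`` (a template with
    ``{in}`` and ``{out}``); a failing batch falls back to the built-in
    stitcher with a warning.
    """
    params = params or StitchParams()
    if backend == "external-command":
        return _assemble_external(batches, contigs, reads, linking_reads, params, backend_cmd, workdir)
    if backend != "builtin":
        raise ValueError(f"unknown backend {backend!r}")
    tasks = [(b, dict(contigs), linking_reads, params) for b in batches]
    if n_workers > 1 and len(batches) > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as ex:
            results = list(ex.map(_stitch_batch, tasks))
    else:
        results = [_stitch_batch(t) for t in tasks]
    return [scaf for group in results for scaf in group]


def _assemble_external(batches, contigs, reads, linking_reads, params, backend_cmd, workdir):
    if not backend_cmd or workdir is None:
        raise ValueError("external backend requires backend_cmd and workdir")
    workdir = FsPath(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out: list[ScaffoldRecord] = []
    for batch in batches:
        in_fa = workdir / f"batch{batch.batch_id}.fa"
        out_fa = workdir / f"batch{batch.batch_id}.out.fa"
        batch_contigs = [contigs[cid] for p in batch.paths for cid in p.step_ids() if cid in contigs]
        batch_reads = [reads[r] for r in sorted(batch.read_ids) if r in reads]
        write_sequences(batch_contigs + batch_reads, in_fa)
        cmd = backend_cmd.format(**{"in": str(in_fa), "out": str(out_fa)})
        try:
            subprocess.run(shlex.split(cmd), check=True, capture_output=True)
            for i, rec in enumerate(read_sequences(out_fa)):
                out.append(ScaffoldRecord(f"scaffold_b{batch.batch_id}_p{i}", rec.sequence, []))
        except (subprocess.CalledProcessError, FileNotFoundError) as exc:
            logger.warning("external backend failed on batch %d (%s); using builtin stitcher",
                           batch.batch_id, exc)
            out.extend(_stitch_batch((batch, dict(contigs), linking_reads, params)))
    return out
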