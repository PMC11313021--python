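"""Three-phase scaffolding pipeline: contig expansion, long-read island
construction, bridge linking.

Phase 1 maps long-read ends to contigs, wires the resulting contig graph and
stitches the enumerated paths into first-generation partial scaffolds. Phase
2 takes the reads left unused, discards those that map to a first-generation
scaffold (they are set aside as bridge candidates) and assembles the rest —
reads falling in regions no contig covers — into island scaffolds by running
the very same graph machinery with reads in the contig role. Phase 3 reruns
the expansion machinery once more with the union of both scaffold generations
as subjects and the set-aside reads as queries, bridging partial scaffolds
into the final set. Read bookkeeping keeps the per-phase used-read sets
disjoint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path as FsPath

import yaml

from . import contig_graph as cg
from .batch_scaffolder import (
    StitchParams,
    assemble_batches,
    build_linking_reads,
    collect_batch_reads,
    partition_into_batches,
)
from .evaluation import nx_metric
from .io_formats import (
    Component,
    ScaffoldRecord,
    SequenceRecord,
    flatten_scaffold,
    write_agp,
    write_gfa,
    write_mapping,
    write_paths,
    write_sequences,
    read_sequences,
)
from .sketch_mapper import MapperParams, map_reads_to_subjects
from .wiring import enumerate_paths, wire_graph

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mapper: MapperParams = field(default_factory=MapperParams)
    stitch: StitchParams = field(default_factory=StitchParams)
    min_support: int = 1
    islands: bool = True
    bridges: bool = True
    n_workers: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mapper = MapperParams(**raw.get("mapper", {}))
        stitch = StitchParams(**raw.get("scaffold", {}))
        graph = raw.get("graph", {})
        phases = raw.get("phases", {})
        return cls(
            mapper=mapper,
            stitch=stitch,
            min_support=graph.get("min_support", 1),
            islands=phases.get("islands", True),
            bridges=phases.get("bridges", True),
            n_workers=raw.get("n_workers", 1),
            seed=raw.get("seed", 0),
        )


@dataclass
class PhaseReport:
    phase: str
    n_subjects: int
    n_reads_in: int
    n_reads_used: int
    n_scaffolds_out: int
    nx_before: int
    nx_after: int

    def __post_init__(self):
        if self.n_reads_used > self.n_reads_in:
            raise ValueError("used reads cannot exceed input reads")


def _n50(lengths) -> int:
    lengths = list(lengths)
    total = sum(lengths)
    return nx_metric(lengths, total, 50) if total else 0


def _singleton_scaffold(sid: str, seq: SequenceRecord) -> ScaffoldRecord:
    return ScaffoldRecord(sid, seq.sequence, [Component(seq.id, "+", 0, len(seq.sequence))])


def _expand(subjects, reads, config, id_prefix):
    """The shared map->graph->wire->walk->stitch machinery of phases 1 and 3."""
    mapping = map_reads_to_subjects(subjects, reads, config.mapper)
    lengths = {s.id: len(s.sequence) for s in subjects}
    graph = cg.build_contig_graph(mapping, lengths)
    if config.min_support > 1:
        graph = cg.filter_edges(graph, config.min_support)
    wiring = wire_graph(graph)
    paths = enumerate_paths(graph, wiring)
    batches = partition_into_batches(paths, config.stitch.batch_size)
    read_index = {r.id: r for r in reads}
    for b in batches:
        b.read_ids = collect_batch_reads(b, mapping)
    linking = build_linking_reads(graph, read_index)
    subject_index = {s.id: s for s in subjects}
    scaffolds = assemble_batches(
        batches, subject_index, read_index, linking,
        config.stitch, n_workers=config.n_workers,
    )
    scaffolds = [
        ScaffoldRecord(f"{id_prefix}{i}", s.sequence, s.components)
        for i, s in enumerate(scaffolds)
    ]
    return mapping, graph, paths, scaffolds


def _consumed_read_ids(graph, paths, scaffolds) -> set[str]:
    """Reads spent by a phase: link sets of edges internal to an output
    scaffold (both endpoints placed in the same scaffold), plus reads whose
    bases were stitched in as gap fill.

    Reads that only link contigs across a remaining *break* are deliberately
    left unused — they are the bridge evidence later phases run on.
    """
    owner: dict[str, int] = {}
    used: set[str] = set()
    for i, scaf in enumerate(scaffolds):
        for c in scaf.components:
            if c.kind == "read":
                used.add(c.source_id)
            else:
                owner[c.source_id] = i
    for u, v, data in graph.edges(data=True):
        if u in owner and owner.get(u) == owner.get(v):
            used.update(data["read_ids"])
    return used


def phase_contig_expansion(contigs, reads, config: PipelineConfig):
    """Phase 1: link contigs through long-read evidence into partial scaffolds.

    Returns (first-generation scaffolds, used read ids, report) plus the
    intermediate artifacts (mapping, graph, paths) for inspection.
    """
    if not contigs:
        raise ValueError("zero contigs: nothing to expand")
    contig_n50 = _n50(len(c.sequence) for c in contigs)
    mapping, graph, paths, scaffolds = _expand(contigs, reads, config, "exp")
    if not mapping:
        logger.warning("no read mapped to any contig; passing contigs through unchanged")
        scaffolds = [_singleton_scaffold(f"exp{i}", c) for i, c in enumerate(contigs)]
    used = _consumed_read_ids(graph, paths, scaffolds)
    report = PhaseReport(
        phase="expansion",
        n_subjects=len(contigs),
        n_reads_in=len(reads),
        n_reads_used=len(used),
        n_scaffolds_out=len(scaffolds),
        nx_before=contig_n50,
        nx_after=_n50(len(s.sequence) for s in scaffolds),
    )
    return scaffolds, used, report, (mapping, graph, paths)


def phase_longread_islands(unused_reads, scaffolds_gen1, config: PipelineConfig):
    """Phase 2: assemble reads unmapped to any gen-1 scaffold into islands.

    Reads that do map to a gen-1 scaffold are set aside (they remain unused
    here and become the natural phase-3 bridge candidates). The remainder are
    assembled with the expansion machinery itself, reads taking the contig
    role; island paths of a single read are discarded as chaff.
    """
    nx_before = _n50(len(s.sequence) for s in scaffolds_gen1)
    empty = PhaseReport("islands", len(scaffolds_gen1), len(unused_reads), 0, 0, nx_before, nx_before)
    if not unused_reads:
        return [], set(), empty
    subjects = [SequenceRecord(s.id, s.sequence) for s in scaffolds_gen1]
    remap = map_reads_to_subjects(subjects, unused_reads, config.mapper) if subjects else []
    mapped_ids = {t.read_id for t in remap}
    unmapped = [r for r in unused_reads if r.id not in mapped_ids]
    if not unmapped:
        return [], set(), empty

    mapping = map_reads_to_subjects(unmapped, unmapped, config.mapper)
    mapping = [t for t in mapping if t.contig_id != t.read_id]  # self-hits carry no link signal
    lengths = {r.id: len(r.sequence) for r in unmapped}
    graph = cg.build_contig_graph(mapping, lengths)
    wiring = wire_graph(graph)
    paths = enumerate_paths(graph, wiring)
    multi = [p for p in paths if len(p.owned_steps()) >= 2]
    read_index = {r.id: r for r in unmapped}
    linking = build_linking_reads(graph, read_index)
    # Reads genuinely overlap each other, unlike contigs: lift the junction
    # overlap cap for the reads-as-subjects assembly route.
    island_params = replace(config.stitch, max_junction_overlap=10**9)
    from .batch_scaffolder import merge_batch_scaffolds, split_at_fallback_gaps, stitch_path

    stitched = [
        stitch_path(p, read_index, linking, island_params, scaffold_id=f"islpath{i}")
        for i, p in enumerate(multi)
    ]
    if island_params.merge_within_batch:
        stitched = [piece for s in stitched for piece in split_at_fallback_gaps(s)]
        if len(stitched) > 1:
            stitched = merge_batch_scaffolds(stitched, linking, island_params)
    scaffolds = []
    used: set[str] = set()
    for i, s in enumerate(stitched):
        scaf = ScaffoldRecord(f"isl{i}", s.sequence, s.components)
        scaffolds.append(scaf)
        used.update(c.source_id for c in scaf.components)
    report = PhaseReport(
        phase="islands",
        n_subjects=len(scaffolds_gen1),
        n_reads_in=len(unused_reads),
        n_reads_used=len(used),
        n_scaffolds_out=len(scaffolds),
        nx_before=nx_before,
        nx_after=_n50([len(s.sequence) for s in scaffolds_gen1] + [len(s.sequence) for s in scaffolds]),
    )
    return scaffolds, used, report


def phase_link_bridges(partials, remaining_reads, config: PipelineConfig):
    """Phase 3: bridge gen-1 and gen-2 partial scaffolds with leftover reads.

    Partials take the contig role; joined partials merge into final scaffolds
    and unjoined ones pass through. Components are flattened back to the
    original contigs and reads afterwards.
    """
    if not partials:
        raise ValueError("no partial scaffolds to link")
    nx_before = _n50(len(s.sequence) for s in partials)
    sub_index = {s.id: s for s in partials}
    if not remaining_reads:
        final = [
            ScaffoldRecord(f"final{i}", s.sequence,
                           [Component(s.id, "+", 0, len(s.sequence))])
            for i, s in enumerate(partials)
        ]
        final = [flatten_scaffold(s, sub_index) for s in final]
        report = PhaseReport("bridges", len(partials), 0, 0, len(final), nx_before, nx_before)
        return final, set(), report
    subjects = [SequenceRecord(s.id, s.sequence) for s in partials]
    mapping, graph, paths, scaffolds = _expand(subjects, remaining_reads, config, "final")
    final = [flatten_scaffold(s, sub_index) for s in scaffolds]
    used = {t.read_id for t in mapping}
    report = PhaseReport(
        phase="bridges",
        n_subjects=len(partials),
        n_reads_in=len(remaining_reads),
        n_reads_used=len(used),
        n_scaffolds_out=len(final),
        nx_before=nx_before,
        nx_after=_n50(len(s.sequence) for s in final),
    )
    return final, used, report


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(contigs_path, reads_path, workdir, config: PipelineConfig | None = None):
    """Run all enabled phases, writing artifacts under ``workdir``.

    Produces scaffolds.fa, scaffolds.agp, report.json and the phase-1
    intermediates (mapping.tsv, graph.gfa, paths.txt). Fully deterministic
    for a given config.
    """
    config = config or PipelineConfig()
    workdir = FsPath(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    contigs = read_sequences(contigs_path)
    reads = read_sequences(reads_path)
    return run_pipeline_in_memory(contigs, reads, config, workdir)


def run_pipeline_in_memory(contigs, reads, config: PipelineConfig | None = None, workdir=None):
    config = config or PipelineConfig()
    reports: list[PhaseReport] = []

    gen1, used1, rep1, (mapping, graph, paths) = phase_contig_expansion(contigs, reads, config)
    reports.append(rep1)
    if workdir is not None:
        write_mapping(mapping, workdir / "mapping.tsv")
        write_gfa(graph, workdir / "graph.gfa")
        write_paths(paths, workdir / "paths.txt")

    unused = [r for r in reads if r.id not in used1]
    if config.islands:
        gen2, used2, rep2 = phase_longread_islands(unused, gen1, config)
        reports.append(rep2)
    else:
        gen2, used2 = [], set()
        logger.info("island phase disabled by config")

    remaining = [r for r in unused if r.id not in used2]
    partials = gen1 + gen2
    if config.bridges:
        final, used3, rep3 = phase_link_bridges(partials, remaining, config)
        reports.append(rep3)
    else:
        sub = {s.id: s for s in partials}
        final = [
            flatten_scaffold(
                ScaffoldRecord(f"final{i}", s.sequence, [Component(s.id, "+", 0, len(s.sequence))]),
                sub,
            )
            for i, s in enumerate(partials)
        ]
        logger.info("bridge phase disabled by config")

    if workdir is not None:
        write_sequences(
            [SequenceRecord(s.id, s.sequence) for s in final], workdir / "scaffolds.fa"
        )
        write_agp(final, workdir / "scaffolds.agp")
        with open(workdir / "report.json", "w") as fh:
            json.dump(
                {"phases_enabled": {"islands": config.islands, "bridges": config.bridges},
                 "reports": [asdict(r) for r in reports]},
                fh, indent=2,
            )
    return final, reports
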