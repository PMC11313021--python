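"""On-disk artifacts: FASTA/FASTQ, mapping TSV, path files, AGP v2.1, GFA1.

Internal coordinates are 0-based half-open everywhere; the AGP writer converts
to the 1-based inclusive coordinates the AGP standard requires at the boundary.
Gzip input is detected by magic bytes, not by file extension.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .hashing import revcomp

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
_ENDS = ("5p", "3p", "whole")


class SequenceFormatError(ValueError):
    """Raised for malformed or inconsistent on-disk records."""


@dataclass(frozen=True)
class SequenceRecord:
    """One contig, long read, or scaffold: an id plus uppercase ACGTN bases."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence of {self.id!r} must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, sequence=revcomp(self.sequence))


@dataclass(frozen=True)
class MappingTuple:
    """One <contig, read> mapping produced from a single read end.

    ``end`` is which part of the read was sketched (5p/3p, or ``whole`` for
    reads shorter than the end length); ``rank`` is 1 for the most similar
    subject of that end.
    """

    read_id: str
    end: str
    contig_id: str
    similarity: float
    rank: int

    def __post_init__(self):
        if self.end not in _ENDS:
            raise SequenceFormatError(f"unknown end token {self.end!r}")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(f"similarity {self.similarity} outside [0,1]")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass(frozen=True)
class Component:
    """One piece of a scaffold: an oriented slice of a contig or read.

    ``start``/``end`` are scaffold coordinates; ``source_start``/``source_end``
    are coordinates on the source sequence whose oriented slice equals
    ``scaffold.sequence[start:end]``. ``gap_before`` is the length of the run
    of N immediately preceding this component.
    """

    source_id: str
    orientation: str  # '+' or '-'
    start: int
    end: int
    gap_before: int = 0
    source_start: int = 0
    source_end: int = -1  # -1: filled in by __post_init__ from start/end
    kind: str = "contig"  # 'contig' or 'read' (read-derived gap fill)

    def __post_init__(self):
        if self.orientation not in "+-":
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")
        if self.source_end == -1:
            object.__setattr__(self, "source_end", self.source_start + (self.end - self.start))
        if self.end - self.start != self.source_end - self.source_start:
            raise ValueError("component scaffold span and source span differ in length")
        if self.start < 0 or self.end <= self.start or self.gap_before < 0:
            raise ValueError("invalid component coordinates")


@dataclass
class ScaffoldRecord:
    """An ordered, oriented sequence of contig (and read) slices with gaps."""

    id: str
    sequence: str
    components: list[Component] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        pos = 0
        for comp in self.components:
            if comp.start != pos + comp.gap_before:
                raise ValueError(
                    f"scaffold {self.id}: component {comp.source_id} at {comp.start}, "
                    f"expected {pos + comp.gap_before}"
                )
            pos = comp.end
        if self.components and pos != len(self.sequence):
            raise ValueError(f"scaffold {self.id}: components end at {pos}, length {len(self.sequence)}")

    def rebuild_sequence(self, sources: dict[str, str]) -> str:
        """Concatenate oriented component slices and gap runs (round-trip oracle)."""
        parts: list[str] = []
        for comp in self.components:
            parts.append("N" * comp.gap_before)
            seg = sources[comp.source_id][comp.source_start:comp.source_end]
            parts.append(revcomp(seg) if comp.orientation == "-" else seg)
        return "".join(parts)


# ---------------------------------------------------------------------------
# Component algebra: slicing / reversing / flattening nested scaffolds.
# Intermediate representation: ("gap", length) | ("comp", Component).


def _items_of(scaf: "ScaffoldRecord") -> list:
    items = []
    for c in scaf.components:
        if c.gap_before:
            items.append(("gap", c.gap_before))
        items.append(("comp", c))
    return items


def _slice_items(items: list, a: int, b: int) -> list:
    """Slice an item list (positions implied by cumulative lengths) to [a, b)."""
    out = []
    pos = 0
    for item in items:
        length = item[1] if item[0] == "gap" else item[1].end - item[1].start
        lo, hi = max(pos, a), min(pos + length, b)
        if hi > lo:
            if item[0] == "gap":
                out.append(("gap", hi - lo))
            else:
                c = item[1]
                cut_l, cut_r = lo - pos, (pos + length) - hi
                if c.orientation == "+":
                    src = (c.source_start + cut_l, c.source_end - cut_r)
                else:
                    src = (c.source_start + cut_r, c.source_end - cut_l)
                out.append(("comp", replace(c, start=0, end=hi - lo, gap_before=0,
                                            source_start=src[0], source_end=src[1])))
        pos += length
    return out


def _reverse_items(items: list) -> list:
    out = []
    for item in reversed(items):
        if item[0] == "gap":
            out.append(item)
        else:
            c = item[1]
            out.append(("comp", replace(c, orientation="-" if c.orientation == "+" else "+")))
    return out


def _materialize_items(scaffold_id: str, sequence: str, items: list) -> "ScaffoldRecord":
    components = []
    pos = 0
    gap = 0
    for item in items:
        if item[0] == "gap":
            gap += item[1]
            pos += item[1]
        else:
            c = item[1]
            length = c.source_end - c.source_start
            components.append(replace(c, start=pos, end=pos + length, gap_before=gap))
            gap = 0
            pos += length
    out = ScaffoldRecord(scaffold_id, sequence, components)
    out.validate()
    return out


def flatten_scaffold(scaf: "ScaffoldRecord", sub: dict[str, "ScaffoldRecord"]) -> "ScaffoldRecord":
    """Rewrite components referencing nested scaffolds to their base
    contigs/reads, composing orientations, trims and gap runs."""
    items: list = []
    for comp in scaf.components:
        if comp.gap_before:
            items.append(("gap", comp.gap_before))
        if comp.source_id in sub:
            inner = _items_of(sub[comp.source_id])
            inner = _slice_items(inner, comp.source_start, comp.source_end)
            if comp.orientation == "-":
                inner = _reverse_items(inner)
            items.extend(inner)
        else:
            items.append(("comp", comp))
    return _materialize_items(scaf.id, scaf.sequence, items)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _open_text(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path) -> str:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise SequenceFormatError(f"{path}: line {lineno}: not a FASTA/FASTQ header: {line.strip()!r}")
    return "fasta"  # empty file: treat as empty FASTA


def read_sequences(path, format: str = "auto") -> list[SequenceRecord]:
    """Read FASTA or FASTQ (gzip transparent) into uppercase SequenceRecords.

    FASTQ qualities are discarded. IUPAC ambiguity codes other than N are
    replaced by N with a logged warning. Duplicate ids are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    warned = False
    with _open_text(path) as fh:
        try:
            parsed = list(SeqIO.parse(fh, fmt))
        except ValueError as exc:
            raise SequenceFormatError(f"{path}: malformed {fmt}: {exc}") from exc
    for rec in parsed:
        seq = str(rec.seq).upper()
        if set(seq) - VALID_BASES:
            if not warned:
                logger.warning("%s: replacing non-ACGTN ambiguity codes with N", path)
                warned = True
            seq = "".join(b if b in VALID_BASES else "N" for b in seq)
        if rec.id in seen:
            raise SequenceFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq, rec.description[len(rec.id):].strip()))
    return records


def write_sequences(records: Iterable[SequenceRecord], path, line_width: int = 80) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Mapping TSV

_MAPPING_COLUMNS = ["read_id", "end", "contig_id", "similarity", "rank"]


def write_mapping(tuples: Iterable[MappingTuple], path) -> None:
    with open(path, "wt", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MAPPING_COLUMNS)
        for t in tuples:
            writer.writerow([t.read_id, t.end, t.contig_id, f"{t.similarity:.6f}", t.rank])


def read_mapping(path) -> list[MappingTuple]:
    out: list[MappingTuple] = []
    with _open_text(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and header != _MAPPING_COLUMNS:
            raise SequenceFormatError(f"{path}: unexpected mapping header {header}")
        for row in reader:
            if not row:
                continue
            read_id, end, contig_id, sim, rank = row
            if end not in _ENDS:
                raise SequenceFormatError(f"{path}: unknown end token {end!r}")
            out.append(MappingTuple(read_id, end, contig_id, float(sim), int(rank)))
    return out


def mapping_roundtrip(tuples: Sequence[MappingTuple], path) -> list[MappingTuple]:
    """Serialize then re-read a mapping set (lossless at 6-decimal similarity)."""
    write_mapping(tuples, path)
    return read_mapping(path)


# ---------------------------------------------------------------------------
# Path files: one path per line, tab-separated contig_id:orientation tokens.


def write_paths(paths, out_path) -> None:
    with open(out_path, "wt") as fh:
        for p in paths:
            fh.write("\t".join(f"{cid}:{orient}" for cid, orient in p.steps) + "\n")


def read_path_steps(path) -> list[list[tuple[str, str]]]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            steps = []
            for token in line.split("\t"):
                cid, _, orient = token.rpartition(":")
                if orient not in "+-?" or not cid:
                    raise SequenceFormatError(f"bad path token {token!r}")
                steps.append((cid, orient))
            out.append(steps)
    return out


# ---------------------------------------------------------------------------
# AGP v2.1


def write_agp(scaffolds: Iterable[ScaffoldRecord], path, known_sources: set[str] | None = None) -> None:
    """AGP v2.1: W lines for components, N lines for gaps (scaffold/yes/map)."""
    with open(path, "wt") as fh:
        fh.write("##agp-version\t2.1\n")
        for scaf in scaffolds:
            scaf.validate()
            part = 0
            for comp in scaf.components:
                if known_sources is not None and comp.source_id not in known_sources:
                    raise SequenceFormatError(
                        f"scaffold {scaf.id}: component references unknown sequence {comp.source_id!r}"
                    )
                if comp.gap_before:
                    part += 1
                    fh.write(
                        f"{scaf.id}\t{comp.start - comp.gap_before + 1}\t{comp.start}\t{part}\t"
                        f"N\t{comp.gap_before}\tscaffold\tyes\tmap\n"
                    )
                part += 1
                fh.write(
                    f"{scaf.id}\t{comp.start + 1}\t{comp.end}\t{part}\tW\t"
                    f"{comp.source_id}\t{comp.source_start + 1}\t{comp.source_end}\t{comp.orientation}\n"
                )


def read_agp(path) -> list[ScaffoldRecord]:
    """Read AGP back into ScaffoldRecords with empty sequences (components only)."""
    scaffolds: dict[str, ScaffoldRecord] = {}
    pending_gap: dict[str, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            obj, beg, end, _part, ctype = cols[:5]
            scaf = scaffolds.setdefault(obj, ScaffoldRecord(obj, ""))
            if ctype == "N" or ctype == "U":
                pending_gap[obj] = int(cols[5])
            elif ctype == "W":
                comp_id, cbeg, cend, orient = cols[5:9]
                scaf.components.append(
                    Component(
                        source_id=comp_id,
                        orientation=orient,
                        start=int(beg) - 1,
                        end=int(end),
                        gap_before=pending_gap.pop(obj, 0),
                        source_start=int(cbeg) - 1,
                        source_end=int(cend),
                    )
                )
            else:
                raise SequenceFormatError(f"{path}: unsupported AGP component type {ctype!r}")
    return list(scaffolds.values())


# ---------------------------------------------------------------------------
# GFA1 export of a contig graph (write-only; S lines = contigs, L lines 0M)


def write_gfa(graph, path, with_sequences: dict[str, str] | None = None) -> None:
    with open(path, "wt") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for node in sorted(graph.nodes):
            seq = (with_sequences or {}).get(node, "*")
            length = graph.nodes[node].get("length", len(seq) if seq != "*" else 0)
            fh.write(f"S\t{node}\t{seq}\tLN:i:{length}\n")
        for u, v in sorted(graph.edges, key=lambda e: tuple(sorted(e))):
            a, b = sorted((u, v))
            support = len(graph.edges[u, v]["read_ids"])
            fh.write(f"L\t{a}\t+\t{b}\t+\t0M\tSV:i:{support}\n")
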