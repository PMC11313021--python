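"""The contig graph: vertices are contigs, edges are long-read links.

A read that maps to two distinct contigs contributes its id to the link set
L_{i,j} of that contig pair; |L_{i,j}| is the edge's *support value*. Contigs
with no links remain as isolated vertices so they can be emitted as singleton
scaffolds downstream.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx

from .io_formats import MappingTuple


def build_contig_graph(
    mapping: Iterable[MappingTuple],
    contig_lengths: Mapping[str, int],
) -> nx.Graph:
    """Group mapping tuples by read and link every distinct contig pair.

    A read contributes its id at most once per edge, regardless of how many
    (end, rank) tuples pair the same two contigs; both ends landing on one
    contig creates no edge. Construction is order-independent.
    """
    by_read: dict[str, set[str]] = {}
    for t in mapping:
        if t.contig_id not in contig_lengths:
            raise KeyError(f"mapping references unknown contig {t.contig_id!r}")
        by_read.setdefault(t.read_id, set()).add(t.contig_id)

    graph = nx.Graph()
    for cid, length in contig_lengths.items():
        graph.add_node(cid, length=length)
    for read_id, contigs in by_read.items():
        if len(contigs) < 2:
            continue
        for a, b in combinations(sorted(contigs), 2):
            if graph.has_edge(a, b):
                graph.edges[a, b]["read_ids"].add(read_id)
            else:
                graph.add_edge(a, b, read_ids={read_id})
    return graph


def filter_edges(graph: nx.Graph, min_support: int = 1) -> nx.Graph:
    """Drop edges with support below min_support; vertices are retained."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    out = graph.copy()
    weak = [(u, v) for u, v, d in out.edges(data=True) if len(d["read_ids"]) < min_support]
    out.remove_edges_from(weak)
    return out


def total_support(graph: nx.Graph) -> int:
    return sum(len(d["read_ids"]) for _, _, d in graph.edges(data=True))
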