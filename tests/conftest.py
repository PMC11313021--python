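"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

import contigwire as cw


def random_link_graph(rng: np.random.Generator, max_vertices: int = 200) -> nx.Graph:
    """A random contig-graph-shaped test instance.

    A mixture of planted chains (with link sets wired so consecutive edges
    share reads), branch edges and extra cycle-closing edges, plus purely
    random link sets — the shapes the path walker must survive.
    """
    n = int(rng.integers(5, max_vertices + 1))
    names = [f"v{i:03d}" for i in range(n)]
    g = nx.Graph()
    for v in names:
        g.add_node(v, length=int(rng.integers(1000, 10_000)))

    read_counter = 0

    def fresh_read():
        nonlocal read_counter
        read_counter += 1
        return f"r{read_counter:05d}"

    # partition vertices into chains; wire consecutive edges with shared reads
    order = list(rng.permutation(names))
    i = 0
    while i < len(order):
        clen = int(rng.integers(1, 9))
        chain = order[i:i + clen]
        i += clen
        for a, b in zip(chain, chain[1:]):
            g.add_edge(a, b, read_ids={fresh_read()})
        for a, b, c in zip(chain, chain[1:], chain[2:]):
            shared = fresh_read()
            g.edges[a, b]["read_ids"].add(shared)
            g.edges[b, c]["read_ids"].add(shared)

    # extra random edges: branches and cycle closers
    n_extra = int(rng.integers(0, max(2, n // 3)))
    for _ in range(n_extra):
        a, b = rng.choice(names, size=2, replace=False)
        if g.has_edge(a, b):
            continue
        reads = {fresh_read() for _ in range(int(rng.integers(1, 4)))}
        g.add_edge(a, b, read_ids=reads)
        if rng.random() < 0.5:  # sometimes share a read with a neighboring edge
            nbrs = [x for x in g[a] if x != b]
            if nbrs:
                x = nbrs[int(rng.integers(len(nbrs)))]
                shared = fresh_read()
                g.edges[a, b]["read_ids"].add(shared)
                g.edges[a, x]["read_ids"].add(shared)
    return g


@pytest.fixture(scope="session")
def small_fixture():
    """A 60 kb repeat-free study: fast enough for per-module tests."""
    return cw.make_fixture(seed=11, genome_length=60_000, repeats=())


@pytest.fixture(scope="session")
def small_pipeline_result(small_fixture):
    final, reports = cw.run_pipeline_in_memory(
        small_fixture.contigs, small_fixture.reads, cw.PipelineConfig()
    )
    return final, reports
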