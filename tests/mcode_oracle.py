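"""Independent straight-line reimplementation of the module-detection rules.

Used as the second implementation in equivalence tests: k-cores by literal
repeated pruning, recursive complex growth, and naive post-processing.
Deliberately unoptimized and structurally different from the package code.
"""

from __future__ import annotations

import networkx as nx
import pytest

from enzynet.mcode import grow_complexes, postprocess, vertex_weights
from enzynet.network import EnzymeNetwork


def oracle_core_number_by_pruning(graph: nx.Graph) -> dict:
    """k-core numbers by literal repeated pruning."""
    core: dict = {}
    k = 0
    remaining = graph.copy()
    while remaining.number_of_nodes():
        while True:
            low = [v for v in remaining if remaining.degree(v) < k + 1]
            if not low:
                break
            for v in low:
                core[v] = k
                remaining.remove_node(v)
        k += 1
    return core


def oracle_weights(graph: nx.Graph, degree_cutoff: int = 2) -> dict:
    weights = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = graph.subgraph(set(graph[v]) | {v})
        cores = oracle_core_number_by_pruning(closed)
        k_max = max(cores.values())
        members = [u for u, c in cores.items() if c >= k_max]
        sub = closed.subgraph(members)
        n = sub.number_of_nodes()
        dens = 0.0 if n < 2 else 2 * sub.number_of_edges() / (n * (n - 1))
        weights[v] = k_max * dens
    return weights


def oracle_grow(graph: nx.Graph, weights: dict, vwp: float) -> list[set]:
    visited: set = set()
    complexes = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], v)):
        if seed in visited:
            continue
        members = {seed}

        def recurse(v):
            for w in sorted(graph[v]):
                if w in members or w in visited:
                    continue
                if weights[w] > (1 - vwp) * weights[seed]:
                    members.add(w)
                    recurse(w)

        recurse(seed)
        visited |= members
        complexes.append(members)
    return complexes


def assert_equivalent(graph: nx.Graph, vwp: float = 0.2, k_core_min: int = 2, haircut: bool = True):
    """Package implementation vs oracle on one graph, stage by stage."""
    net = EnzymeNetwork(graph=graph, label="oracle-test")
    w = vertex_weights(net)
    ow = oracle_weights(graph)
    assert w == pytest.approx(ow)
    got = grow_complexes(net, w, vwp=vwp)
    expected = oracle_grow(graph, ow, vwp)
    assert sorted(map(sorted, got)) == sorted(map(sorted, expected))
    mods = postprocess(got, net, k_core_min=k_core_min, haircut=haircut)
    expected_members = []
    for c in expected:
        sub = graph.subgraph(c)
        core = oracle_core_number_by_pruning(sub)
        if max(core.values(), default=0) < k_core_min:
            continue
        kept = sub.subgraph([v for v, k in core.items() if k >= 2]) if haircut else sub
        for comp in nx.connected_components(kept):
            comp_core = oracle_core_number_by_pruning(graph.subgraph(comp))
            if max(comp_core.values(), default=0) >= k_core_min:
                expected_members.append(sorted(comp))
    assert sorted(sorted(mod.members) for mod in mods) == sorted(expected_members)
    seen: set = set()
    for mod in mods:
        assert nx.k_core(graph.subgraph(mod.members), 2).number_of_nodes() > 0
        assert not set(mod.members) & seen
        seen |= set(mod.members)
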