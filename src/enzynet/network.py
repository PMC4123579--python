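"""Directed enzyme-network construction from metabolic reactions.

Enzymes (EC numbers) are nodes; an edge E_i -> E_j exists when a reaction
catalyzed by E_i produces a compound that a reaction catalyzed by E_j
consumes — the substrate/product chaining rule. Each edge carries the set
of mediating compounds. Currency metabolites (ubiquitous cofactors such as
ATP, H2O, NAD+) can be excluded from the chaining, since their inclusion
connects nearly every enzyme to every other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .io import Reaction

__all__ = [
    "DEFAULT_CURRENCY_COMPOUNDS",
    "EnzymeNetwork",
    "build_enzyme_network",
    "undirected_view",
    "write_edgelist",
    "read_edgelist",
]

#: Default currency-metabolite exclusion list. Overridable, including with
#: the empty set to chain through every compound.
DEFAULT_CURRENCY_COMPOUNDS = frozenset(
    {"ATP", "ADP", "H2O", "NAD+", "NADH", "CO2", "Pi", "H+"}
)


@dataclass
class EnzymeNetwork:
    """An enzyme graph plus its provenance label.

    ``graph`` is a :class:`networkx.DiGraph` (or :class:`networkx.Graph`
    for undirected views) whose edges carry a ``compounds`` frozenset of
    mediating compound ids (empty for undirected views that merged edges
    only, never for built directed edges).
    """

    graph: nx.DiGraph | nx.Graph
    label: str = "overall"
    compartment: str | None = None

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def enzymes(self) -> set[str]:
        return set(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_enzyme_network(
    reactions: Iterable[Reaction],
    currency_compounds: frozenset[str] | set[str] = DEFAULT_CURRENCY_COMPOUNDS,
    allow_self_loops: bool = False,
    keep_isolated: bool = True,
    label: str = "overall",
) -> EnzymeNetwork:
    """Chain reactions into a directed enzyme network.

    For every ordered pair of *distinct* reactions (R_a, R_b) such that a
    non-currency product of R_a is a substrate of R_b, an edge E_i -> E_j
    is added for every E_i catalyzing R_a and E_j catalyzing R_b,
    annotated with the shared compounds. Reversible reactions contribute
    both orientations of their substrate/product sets. Two ECs catalyzing
    the *same* reaction are never connected by that reaction. Parallel
    edges merge, unioning their mediating compounds.
    """
    reactions = list(reactions)
    currency = frozenset(currency_compounds)
    graph = nx.DiGraph()

    # (reaction index, substrates, products) with reversible reactions
    # expanded into both orientations
    oriented: list[tuple[int, frozenset[str], frozenset[str]]] = []
    for i, r in enumerate(reactions):
        subs = r.substrates - currency
        prods = r.products - currency
        oriented.append((i, subs, prods))
        if r.reversible:
            oriented.append((i, prods, subs))

    if keep_isolated:
        for r in reactions:
            graph.add_nodes_from(r.enzymes)

    # index: compound -> orientations consuming it
    consumers: dict[str, list[int]] = {}
    for idx, (i, subs, _) in enumerate(oriented):
        for c in subs:
            consumers.setdefault(c, []).append(idx)

    for i_a, _, prods_a in oriented:
        enzymes_a = reactions[i_a].enzymes
        if not enzymes_a:
            continue
        # collect target reactions and the compounds mediating each
        targets: dict[int, set[str]] = {}
        for c in prods_a:
            for idx_b in consumers.get(c, ()):
                i_b = oriented[idx_b][0]
                if i_b == i_a:  # within-reaction pairs are never chained
                    continue
                targets.setdefault(i_b, set()).add(c)
        for i_b, shared in targets.items():
            for e_i in enzymes_a:
                for e_j in reactions[i_b].enzymes:
                    if e_i == e_j and not allow_self_loops:
                        continue
                    if graph.has_edge(e_i, e_j):
                        graph[e_i][e_j]["compounds"] = frozenset(
                            graph[e_i][e_j]["compounds"] | shared
                        )
                    else:
                        graph.add_edge(e_i, e_j, compounds=frozenset(shared))
    return EnzymeNetwork(graph=graph, label=label)


def undirected_view(net: EnzymeNetwork) -> EnzymeNetwork:
    """Collapse directions and parallel edges into a simple undirected graph.

    Self-loops are dropped; mediating-compound sets of merged edges are
    unioned. Idempotent: the undirected view of an undirected view is
    itself.
    """
    graph = nx.Graph()
    graph.add_nodes_from(net.graph.nodes)
    for u, v, data in net.graph.edges(data=True):
        if u == v:
            continue
        compounds = frozenset(data.get("compounds", frozenset()))
        if graph.has_edge(u, v):
            compounds = frozenset(graph[u][v]["compounds"] | compounds)
        graph.add_edge(u, v, compounds=compounds)
    return EnzymeNetwork(graph=graph, label=net.label, compartment=net.compartment)


def write_edgelist(net: EnzymeNetwork, path: str | Path) -> None:
    """Edge-list TSV export: source EC, target EC, ';'-joined compounds."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("source\ttarget\tcompounds\n")
        for u, v, data in sorted(net.graph.edges(data=True)):
            handle.write(f"{u}\t{v}\t{';'.join(sorted(data.get('compounds', ())))}\n")
        isolated = sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0)
        for n in isolated:
            handle.write(f"{n}\t\t\n")


def read_edgelist(path: str | Path, directed: bool = True, label: str = "overall") -> EnzymeNetwork:
    graph: nx.DiGraph | nx.Graph = nx.DiGraph() if directed else nx.Graph()
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("source\ttarget"):
            raise ValueError(f"{path}: not an enzyme-network edge list")
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            source, target = parts[0], parts[1]
            if not target:
                graph.add_node(source)
                continue
            compounds = frozenset(c for c in parts[2].split(";") if c) if len(parts) > 2 else frozenset()
            graph.add_edge(source, target, compounds=compounds)
    return EnzymeNetwork(graph=graph, label=label)


def write_graphml(net: EnzymeNetwork, path: str | Path) -> None:
    """GraphML export (compound sets serialized as ';'-joined strings)."""
    g = net.graph.copy()
    for _, _, data in g.edges(data=True):
        data["compounds"] = ";".join(sorted(data.get("compounds", ())))
    nx.write_graphml(g, path)
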