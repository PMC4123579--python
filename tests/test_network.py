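"""Enzyme-network construction: chaining rule, currency exclusion, views."""

from __future__ import annotations

import numpy as np
import pytest

from enzynet.io import Reaction
from enzynet.network import (
    EnzymeNetwork,
    build_enzyme_network,
    read_edgelist,
    undirected_view,
    write_edgelist,
)
from enzynet.synthetic import SyntheticConfig, generate_reactions


def R(rid, subs, prods, ecs, rev=False):
    return Reaction(rid, frozenset(subs), frozenset(prods), frozenset(ecs), rev)


def brute_force_edges(reactions, currency=frozenset(), allow_self_loops=False):
    """Independent double loop over ordered reaction pairs and enzyme pairs."""
    edges: dict[tuple[str, str], set[str]] = {}
    def sides(r):
        out = [(r.substrates - currency, r.products - currency)]
        if r.reversible:
            out.append((r.products - currency, r.substrates - currency))
        return out
    for ra in reactions:
        for rb in reactions:
            if ra.reaction_id == rb.reaction_id:
                continue
            for _, prods_a in sides(ra):
                for subs_b, _ in sides(rb):
                    shared = prods_a & subs_b
                    if not shared:
                        continue
                    for ei in ra.enzymes:
                        for ej in rb.enzymes:
                            if ei == ej and not allow_self_loops:
                                continue
                            edges.setdefault((ei, ej), set()).update(shared)
    return {k: frozenset(v) for k, v in edges.items()}


class TestChainingRule:
    def test_product_feeds_substrate(self):
        net = build_enzyme_network(
            [R("R1", "A", "B", ["E1"]), R("R2", "B", "C", ["E2"])],
            currency_compounds=frozenset(),
        )
        assert set(net.graph.edges) == {("E1", "E2")}
        assert net.graph["E1"]["E2"]["compounds"] == {"B"}

    def test_currency_exclusion_keeps_isolated_nodes(self):
        net = build_enzyme_network(
            [R("R1", "A", "B", ["E1"]), R("R2", "B", "C", ["E2"])],
            currency_compounds={"B"},
            keep_isolated=True,
        )
        assert net.graph.number_of_edges() == 0
        assert net.enzymes == {"E1", "E2"}

    def test_self_loop_flag(self):
        reactions = [R("R1", "A", "B", ["E1"]), R("R2", "B", "A", ["E1"])]
        off = build_enzyme_network(reactions, currency_compounds=frozenset())
        assert off.graph.number_of_edges() == 0
        on = build_enzyme_network(
            reactions, currency_compounds=frozenset(), allow_self_loops=True
        )
        assert set(on.graph.edges) == {("E1", "E1")}

    def test_reversible_chains_both_orientations(self):
        net = build_enzyme_network(
            [R("R1", "A", "B", ["E1"], rev=True), R("R2", "A", "C", ["E2"])],
            currency_compounds=frozenset(),
        )
        # reverse orientation of R1 produces A, consumed by R2
        assert ("E1", "E2") in net.graph.edges

    def test_within_reaction_enzyme_pairs_not_connected(self):
        net = build_enzyme_network(
            [R("R1", "A", "B", ["E1", "E2"], rev=True)], currency_compounds=frozenset()
        )
        assert net.graph.number_of_edges() == 0

    def test_spontaneous_reactions_contribute_no_edges(self):
        net = build_enzyme_network(
            [R("R1", "A", "B", []), R("R2", "B", "C", ["E2"])],
            currency_compounds=frozenset(),
        )
        assert net.graph.number_of_edges() == 0

    def test_empty_reaction_list_gives_empty_network(self):
        net = build_enzyme_network([], currency_compounds=frozenset())
        assert len(net) == 0


class TestOracleAndProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SyntheticConfig(
            seed=seed, n_reactions=40, n_compounds=30, n_enzymes=15,
            n_planted_reporter_enzymes=4,
        )
        reactions, currency = generate_reactions(cfg, rng)
        reactions = reactions[:50]
        for cur in (frozenset(), currency):
            net = build_enzyme_network(reactions, currency_compounds=cur)
            got = {
                (u, v): data["compounds"] for u, v, data in net.graph.edges(data=True)
            }
            assert got == brute_force_edges(reactions, cur)

    def test_enlarging_currency_never_adds_edges(self, rng):
        cfg = SyntheticConfig(
            seed=5, n_reactions=60, n_compounds=40, n_enzymes=20,
            n_planted_reporter_enzymes=4,
        )
        reactions, _ = generate_reactions(cfg, rng)
        compounds = sorted({c for r in reactions for c in r.substrates | r.products})
        small = frozenset(compounds[:5])
        large = small | frozenset(compounds[5:15])
        edges_small = set(build_enzyme_network(reactions, small).graph.edges)
        edges_large = set(build_enzyme_network(reactions, large).graph.edges)
        assert edges_large <= edges_small

    def test_reaction_order_does_not_matter(self, rng):
        cfg = SyntheticConfig(
            seed=6, n_reactions=50, n_compounds=30, n_enzymes=15,
            n_planted_reporter_enzymes=4,
        )
        reactions, currency = generate_reactions(cfg, rng)
        shuffled = list(reactions)
        rng.shuffle(shuffled)
        a = build_enzyme_network(reactions, currency)
        b = build_enzyme_network(shuffled, currency)
        assert set(a.graph.edges(data="compounds")) == set(b.graph.edges(data="compounds"))


class TestUndirectedView:
    def test_antiparallel_edges_merge(self):
        net = build_enzyme_network(
            [R("R1", "A", "B", ["E1"]), R("R2", "B", "A", ["E2"])],
            currency_compounds=frozenset(),
        )
        assert set(net.graph.edges) == {("E1", "E2"), ("E2", "E1")}
        und = undirected_view(net)
        assert und.graph.number_of_edges() == 1
        assert und.graph["E1"]["E2"]["compounds"] == {"A", "B"}

    def test_self_loops_removed_and_idempotent(self):
        net = build_enzyme_network(
            [R("R1", "A", "B", ["E1"]), R("R2", "B", "A", ["E1"])],
            currency_compounds=frozenset(),
            allow_self_loops=True,
        )
        und = undirected_view(net)
        assert und.graph.number_of_edges() == 0
        again = undirected_view(und)
        assert set(again.graph.edges) == set(und.graph.edges)
        assert set(again.graph.nodes) == set(und.graph.nodes)

    def test_empty_network(self):
        import networkx as nx

        assert len(undirected_view(EnzymeNetwork(graph=nx.DiGraph()))) == 0


def test_edgelist_round_trip(tmp_path, overall_net):
    path = tmp_path / "net.tsv"
    write_edgelist(overall_net, path)
    again = read_edgelist(path)
    assert set(again.graph.nodes) == set(overall_net.graph.nodes)
    assert set(again.graph.edges(data="compounds")) == set(
        overall_net.graph.edges(data="compounds")
    )
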