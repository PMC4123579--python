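"""Hypergeometric enrichment, BH-FDR, and function-class labelling."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzynet.enrichment import (
    EnrichmentResult,
    FunctionClassScheme,
    bh_fdr,
    class_counts,
    classify_terms,
    hypergeom_enrich,
    load_function_classes,
)


def enumeration_p(universe: set, term: set, module_size: int, observed: int) -> float:
    """P(hits >= observed) by exhaustive enumeration of all module draws."""
    total = hits_ge = 0
    for draw in itertools.combinations(sorted(universe), module_size):
        total += 1
        if len(set(draw) & term) >= observed:
            hits_ge += 1
    return hits_ge / total


class TestHypergeomEnrich:
    def test_worked_case_five_over_210(self):
        # universe of 10, term of 5, module of 4 with all 4 hits:
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        module = {f"g{i}" for i in range(4)}
        (res,) = hypergeom_enrich(module, {"T": term}, universe)
        assert res.p == pytest.approx(5 / 210, abs=1e-12)
        assert res.p == pytest.approx(enumeration_p(universe, term, 4, 4), abs=1e-12)

    def test_term_covering_universe_has_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        (res,) = hypergeom_enrich({"g0", "g1"}, {"T": set(universe)}, universe)
        assert res.p == pytest.approx(1.0)

    def test_zero_hit_terms_absent(self):
        universe = {f"g{i}" for i in range(8)}
        results = hypergeom_enrich({"g0"}, {"T": {"g5", "g6"}}, universe)
        assert results == []

    def test_empty_universe_is_domain_error(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(set(), {}, set())

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich({"x"}, {}, {"g0"})

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_on_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(6, 13))
        universe = {f"g{i}" for i in range(m)}
        term = set(rng.choice(sorted(universe), size=int(rng.integers(1, m)), replace=False))
        module_size = int(rng.integers(1, m // 2 + 1))
        module = set(rng.choice(sorted(universe), size=module_size, replace=False))
        results = hypergeom_enrich(module, {"T": term}, universe)
        observed = len(module & term)
        if observed == 0:
            assert results == []
        else:
            assert results[0].p == pytest.approx(
                enumeration_p(universe, term, module_size, observed), abs=1e-10
            )

    def test_hit_count_invariant(self):
        universe = {f"g{i}" for i in range(10)}
        results = hypergeom_enrich(
            {"g0", "g1", "g2"}, {"A": {"g0", "g1"}, "B": {"g2", "g9"}}, universe
        )
        for r in results:
            assert r.hits <= min(r.module_size, r.term_size)
            assert 0 < r.p <= 1
            assert r.fdr >= r.p - 1e-15


class TestBhFdr:
    def test_hand_computed_step_up(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3, then cumulative min from the right
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.1, 0.1, 0.1, 0.1]) == pytest.approx([0.1] * 4)

    def test_order_preserving(self):
        ps = [0.04, 0.001, 0.9, 0.02]
        adj = bh_fdr(ps)
        sorted_adj = bh_fdr(sorted(ps))
        order = np.argsort(ps)
        assert [adj[i] for i in order] == pytest.approx(sorted_adj)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    def test_adjusted_values_bounded_by_raw_and_one(self, ps):
        adj = bh_fdr(ps)
        assert all(p - 1e-12 <= a <= 1.0 + 1e-12 for p, a in zip(ps, adj))
        # step-up never adjusts the maximum P upward
        assert max(adj) <= max(ps) + 1e-12
        order = np.argsort(ps)
        sorted_adj = [adj[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(sorted_adj, sorted_adj[1:]))

    def test_monotone_on_sorted_input(self, rng):
        ps = np.sort(rng.uniform(0.001, 1, 50))
        adj = bh_fdr(list(ps))
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_null_false_discovery_control(self, rng):
        # modules drawn uniformly from the universe: the rate of FDR<0.05
        # terms stays near or below the nominal level
        universe = {f"g{i}" for i in range(60)}
        terms = {
            f"T{j}": set(rng.choice(sorted(universe), size=12, replace=False))
            for j in range(15)
        }
        sig = total = 0
        for _ in range(200):
            module = set(rng.choice(sorted(universe), size=8, replace=False))
            for r in hypergeom_enrich(module, terms, universe):
                total += 1
                sig += r.fdr < 0.05
        assert sig / total < 0.05


class TestClassifyTerms:
    scheme = FunctionClassScheme.from_mapping(
        {
            "death": {"keywords": ["cell death", "apoptotic"]},
            "lipid": {"term_ids": ["GO:42"], "keywords": ["lipid"]},
            "basic_metabolic": {"keywords": ["metabolic"]},
        }
    )

    def _result(self, term_id, name):
        return EnrichmentResult(term_id, name, 1, 1, 1, 10, 0.01, 0.01)

    def test_keyword_match(self):
        (r,) = classify_terms(
            [self._result("GO:1", "positive regulation of programmed cell death")],
            self.scheme,
        )
        assert r.function_class == "death"

    def test_term_id_beats_keyword(self):
        # listed under lipid by id although its name says metabolic
        (r,) = classify_terms(
            [self._result("GO:42", "some metabolic process")], self.scheme
        )
        assert r.function_class == "lipid"

    def test_unmatched_is_unclassified(self):
        (r,) = classify_terms([self._result("GO:7", "ion transport")], self.scheme)
        assert r.function_class == "unclassified"

    def test_bundled_scheme_loads_and_orders_death_first(self):
        scheme = load_function_classes()
        assert scheme.classify("GO:x", "apoptotic process") == "death"
        assert scheme.classify("GO:x", "lipid metabolic process") == "lipid"
        assert scheme.classify("GO:x", "glucose metabolic process") == "basic_metabolic"

    def test_class_counts_respects_fdr(self):
        results = [
            EnrichmentResult("GO:1", "apoptotic process", 1, 1, 1, 10, 0.001, 0.01),
            EnrichmentResult("GO:2", "apoptotic process", 1, 1, 1, 10, 0.5, 0.9),
        ]
        counts = class_counts(classify_terms(results, self.scheme))
        assert counts["death"] == 1
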