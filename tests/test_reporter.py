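"""Reporter statistic: inverse-normal scores, aggregation, sampled null."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enzynet.io import GeneEnzymeMap
from enzynet.network import EnzymeNetwork
from enzynet.reporter import (
    NullModel,
    aggregate_enzyme_z,
    build_null,
    intersect_reporters,
    null_pool_for_network,
    p_to_z,
    score_network,
)

# standard-normal upper 5% quantile, frozen from an independent quantile
# computation (scipy.stats.norm.ppf(0.95))
Z_95 = 1.6448536269514722


class TestPToZ:
    def test_median_maps_to_zero(self):
        assert p_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_upper_tail_quantile(self):
        assert p_to_z(0.05) == pytest.approx(Z_95, abs=1e-9)

    def test_symmetry(self):
        assert p_to_z(0.95) == pytest.approx(-p_to_z(0.05), abs=1e-12)

    def test_monotone_decreasing(self):
        ps = np.linspace(1e-6, 1.0, 200)
        zs = p_to_z(ps)
        assert np.all(np.diff(zs) < 0)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001, 2.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            p_to_z(bad)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(min_value=1e-12, max_value=1.0, exclude_max=True))
    def test_inverse_relation_round_trips(self, p):
        # Phi(Z) must return 1 - p for any valid p
        assert stats.norm.cdf(p_to_z(p)) == pytest.approx(1.0 - p, abs=1e-9)


class TestAggregate:
    @pytest.mark.parametrize(
        "zs, mode, expected",
        [
            ([1.0, 2.0, 3.0], "median", 2.0),
            ([1.0, 3.0], "median", 2.0),  # even-k: mean of middle two
            ([0.0, 0.0, 6.0], "mean", 2.0),
            ([0.0, 0.0, 6.0], "median", 0.0),  # the mode divergence
        ],
    )
    def test_examples(self, zs, mode, expected):
        assert aggregate_enzyme_z(zs, mode) == pytest.approx(expected)

    def test_empty_list_is_domain_error(self):
        with pytest.raises(ValueError):
            aggregate_enzyme_z([])


class TestNullModel:
    def test_degenerate_pool_raises(self):
        null = NullModel(pool=np.zeros(50), rounds=100, seed=1)
        with pytest.raises(ValueError, match="degenerate"):
            null.moments(3)

    def test_mean_mode_matches_closed_form_se(self, rng):
        # mean of k without-replacement draws from a fixed pool: mu equals
        # the pool mean and sigma the finite-population standard error
        # pool_sd/sqrt(k) * sqrt((N-k)/(N-1)); tolerance 3x the MC error
        pool = rng.standard_normal(2000)
        null = build_null(pool, rounds=20000, seed=4, mode="mean")
        for k in (2, 5, 10):
            mu, sigma = null.moments(k)
            expected = np.std(pool) / np.sqrt(k) * np.sqrt((pool.size - k) / (pool.size - 1))
            mc_err = expected / np.sqrt(2 * (null.rounds - 1))
            assert mu == pytest.approx(np.mean(pool), abs=3 * expected / np.sqrt(null.rounds))
            assert sigma == pytest.approx(expected, abs=3 * mc_err + 0.01 * expected)

    def test_k_one_moments_match_pool(self, rng):
        pool = rng.standard_normal(300)
        null = build_null(pool, rounds=50000, seed=5, mode="mean")
        mu, sigma = null.moments(1)
        assert mu == pytest.approx(np.mean(pool), abs=3 * np.std(pool) / np.sqrt(null.rounds))
        assert sigma == pytest.approx(np.std(pool), rel=0.05)

    def test_moments_independent_of_query_order(self, rng):
        pool = rng.standard_normal(200)
        a = build_null(pool, rounds=500, seed=9)
        b = build_null(pool, rounds=500, seed=9)
        ka = [a.moments(k) for k in (1, 3, 5)]
        kb = [b.moments(k) for k in (5, 1, 3)]
        assert ka == [kb[1], kb[2], kb[0]]


def _star_net(enzymes):
    g = nx.DiGraph()
    g.add_nodes_from(enzymes)
    return EnzymeNetwork(graph=g, label="toy")


class TestScoreNetwork:
    def test_correction_identity_and_p(self, rng):
        enzymes = [f"E{i}" for i in range(30)]
        gmap = GeneEnzymeMap(
            [(f"g{i}_{j}", e) for i, e in enumerate(enzymes) for j in range(1 + i % 3)]
        )
        pvals = {g: float(p) for g, p in zip(sorted(gmap.gene_to_enzymes), rng.uniform(0.001, 1.0, 100))}
        net = _star_net(enzymes)
        pool = null_pool_for_network(net, pvals, gmap)
        null = NullModel(pool=pool, rounds=2000, seed=2)
        table = score_network(net, pvals, gmap, null).table
        assert np.allclose(
            table["z_corrected"], (table["z"] - table["mu_k"]) / table["sigma_k"]
        )
        assert np.allclose(table["p"], stats.norm.sf(table["z_corrected"]))
        assert ((table["p"] > 0) & (table["p"] < 1)).all()
        assert (table["sigma_k"] > 0).all()

    def test_corrected_z_at_upper_quantile_gives_alpha(self):
        # Z_corrected = 1.6449 corresponds to P ~ 0.05
        assert stats.norm.sf(Z_95) == pytest.approx(0.05, abs=1e-9)

    def test_mean_mode_k1_reduces_to_gene_pipeline(self, rng):
        enzymes = [f"E{i}" for i in range(40)]
        gmap = GeneEnzymeMap([(f"g{i}", e) for i, e in enumerate(enzymes)])
        pvals = {f"g{i}": float(p) for i, p in enumerate(rng.uniform(0.001, 1, 40))}
        net = _star_net(enzymes)
        pool = null_pool_for_network(net, pvals, gmap, mode="mean")
        null = NullModel(pool=pool, rounds=5000, seed=3, mode="mean")
        table = score_network(net, pvals, gmap, null).table
        for i, e in enumerate(enzymes):
            assert table.loc[e, "z"] == pytest.approx(p_to_z(pvals[f"g{i}"]), abs=1e-12)

    def test_unmeasured_enzymes_are_skipped(self, rng):
        gmap = GeneEnzymeMap([("g0", "E0")])
        net = _star_net(["E0", "E_nogene"])
        pvals = {"g0": 0.3, "other": 0.5}
        pool = np.asarray(rng.standard_normal(50))
        result = score_network(net, pvals, gmap, NullModel(pool=pool, rounds=200, seed=1))
        assert list(result.table.index) == ["E0"]
        assert result.skipped == ["E_nogene"]

    def test_same_seed_gives_identical_tables(self, overall_net, bundle, pvalues):
        pv = pvalues["macrophage"]
        out = []
        for _ in range(2):
            pool = null_pool_for_network(overall_net, pv, bundle.gene_map)
            null = NullModel(pool=pool, rounds=300, seed=17)
            out.append(score_network(overall_net, pv, bundle.gene_map, null).table)
        assert out[0].equals(out[1])  # bitwise-identical frames


class TestIntersectReporters:
    def _table(self, flags: dict[str, float], label="net"):
        import pandas as pd
        from enzynet.reporter import ReporterScoreTable

        frame = pd.DataFrame(
            {
                "k": 1,
                "z": 0.0,
                "mu_k": 0.0,
                "sigma_k": 1.0,
                "z_corrected": 0.0,
                "p": list(flags.values()),
            },
            index=list(flags.keys()),
        )
        return ReporterScoreTable(table=frame, network_label=label, mode="median")

    def test_set_intersection(self):
        a = self._table({"E1": 0.01, "E2": 0.02, "E3": 0.5})
        b = self._table({"E1": 0.9, "E2": 0.03, "E3": 0.01})
        assert intersect_reporters([a, b]) == {"E2"}

    def test_disjoint_sets_yield_empty(self):
        a = self._table({"E1": 0.01, "E2": 0.5})
        b = self._table({"E1": 0.5, "E2": 0.01})
        assert intersect_reporters([a, b]) == set()

    def test_identical_tables_idempotent(self):
        a = self._table({"E1": 0.01, "E2": 0.5})
        assert intersect_reporters([a, a]) == {"E1"}

    def test_tie_at_alpha_excluded(self):
        a = self._table({"E1": 0.05, "E2": 0.049})
        assert intersect_reporters([a, a], alpha=0.05) == {"E2"}

    def test_mismatched_networks_rejected(self):
        a = self._table({"E1": 0.01}, label="overall")
        b = self._table({"E1": 0.01}, label="mitochondria")
        with pytest.raises(ValueError, match="different networks"):
            intersect_reporters([a, b])
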