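"""Reporter-enzyme scoring: inverse-normal gene scores, per-enzyme
aggregation, and a sampled background null.

The pipeline is the reporter-feature statistic adapted to enzymes:

1. each gene's differential-expression P-value is converted to a standard
   Z-score, ``Z_g = Phi^-1(1 - P_g)``;
2. an enzyme mapped to k genes aggregates their Z-scores (median by
   default; the arithmetic mean is an option);
3. the aggregate is corrected against a background null built by sampling
   many (default 10000) size-k sets from the network's gene-score pool,
   ``Z_corr = (Z_E - mu_k) / sigma_k``;
4. ``P_E = 1 - Phi(Z_corr)``, and enzymes with ``P_E`` strictly below the
   significance threshold (default 0.05) are flagged.

Reporter enzymes of a disease are the flagged enzymes common to the
per-cell-type contrasts (here: macrophage and foam-cell, disease vs
control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneEnzymeMap
from .network import EnzymeNetwork

__all__ = [
    "NullModel",
    "ReporterScoreTable",
    "p_to_z",
    "aggregate_enzyme_z",
    "build_null",
    "null_pool_for_network",
    "score_network",
    "intersect_reporters",
]

AggregationMode = Literal["median", "mean"]

#: Rows are sampled in blocks to bound peak memory at large pool sizes.
_SAMPLING_BLOCK = 2000


def p_to_z(p: float | np.ndarray) -> float | np.ndarray:
    """Inverse-normal conversion ``Z = Phi^-1(1 - p)``.

    Monotone decreasing in p: small P-values map to large positive
    Z-scores. Domain is (0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("P-values must lie in (0, 1]")
    z = stats.norm.isf(arr)
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


def aggregate_enzyme_z(gene_zs: Sequence[float], mode: AggregationMode = "median") -> float:
    """Aggregate the Z-scores of an enzyme's k genes.

    ``median`` (default) uses the sample median with the mean-of-middle-two
    convention for even k; ``mean`` is the arithmetic mean.
    """
    arr = np.asarray(gene_zs, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty Z-score list")
    if mode == "median":
        return float(np.median(arr))
    if mode == "mean":
        return float(np.mean(arr))
    raise ValueError(f"unknown aggregation mode {mode!r}")


@dataclass
class NullModel:
    """Sampled background null for aggregated Z-scores.

    For each gene count k, ``rounds`` sets of k scores are drawn without
    replacement from ``pool`` and aggregated; ``mu_k``/``sigma_k`` are the
    mean and SD of those aggregates. Moments for a k depend only on
    (seed, pool, mode, rounds, k) — never on the order in which ks are
    requested — so the cache can be extended on demand reproducibly.
    """

    pool: np.ndarray
    rounds: int = 10000
    seed: int = 0
    mode: AggregationMode = "median"
    _cache: dict[int, tuple[float, float]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.pool = np.asarray(self.pool, dtype=float)
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.pool.size < 1:
            raise ValueError("empty gene-score pool")

    def moments(self, k: int) -> tuple[float, float]:
        """(mu_k, sigma_k), computing and caching on first request."""
        if k not in self._cache:
            self._cache[k] = self._sample_moments(k)
        return self._cache[k]

    def _sample_moments(self, k: int) -> tuple[float, float]:
        if not (1 <= k <= self.pool.size):
            raise ValueError(f"k={k} outside [1, pool size {self.pool.size}]")
        rng = np.random.default_rng([self.seed, k])
        n = self.pool.size
        aggregates = np.empty(self.rounds, dtype=float)
        agg = np.median if self.mode == "median" else np.mean
        done = 0
        while done < self.rounds:
            block = min(_SAMPLING_BLOCK, self.rounds - done)
            if k == n:
                samples = np.broadcast_to(self.pool, (block, n))
            else:
                # without-replacement sampling via random-key argpartition
                keys = rng.random((block, n))
                idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
                samples = self.pool[idx]
            aggregates[done : done + block] = agg(samples, axis=1)
            done += block
        mu = float(np.mean(aggregates))
        sigma = float(np.std(aggregates, ddof=0))
        if sigma <= 0.0:
            raise ValueError(
                f"degenerate null (sigma_{k} = 0); supply a larger or less "
                "uniform gene-score pool, or jitter the scores"
            )
        return mu, sigma

    def precompute(self, ks: set[int]) -> "NullModel":
        for k in sorted(ks):
            self.moments(k)
        return self


def build_null(
    gene_z_pool: Sequence[float],
    ks: set[int] | None = None,
    rounds: int = 10000,
    seed: int = 0,
    mode: AggregationMode = "median",
) -> NullModel:
    """Construct (and optionally precompute) a :class:`NullModel`."""
    null = NullModel(pool=np.asarray(gene_z_pool, dtype=float), rounds=rounds, seed=seed, mode=mode)
    if ks:
        null.precompute(ks)
    return null


def null_pool_for_network(
    net: EnzymeNetwork,
    pvals: dict[str, float],
    gene_map: GeneEnzymeMap,
    strategy: Literal["gene", "enzyme"] = "gene",
    mode: AggregationMode = "median",
) -> np.ndarray:
    """Background score pool for a network.

    ``gene`` (default): Z-scores of every measured gene mapped to any
    enzyme of the network — each network (the overall one or a compartment
    subnetwork) gets its own background. ``enzyme``: one aggregated
    Z-score per network enzyme, for samplers that draw k enzymes instead
    of k genes.
    """
    if strategy == "gene":
        genes = sorted(
            {g for e in net.enzymes for g in gene_map.genes_of(e) if g in pvals}
        )
        return p_to_z(np.array([pvals[g] for g in genes])) if genes else np.empty(0)
    if strategy == "enzyme":
        zs = []
        for e in sorted(net.enzymes):
            gs = sorted(g for g in gene_map.genes_of(e) if g in pvals)
            if gs:
                zs.append(aggregate_enzyme_z(p_to_z(np.array([pvals[g] for g in gs])), mode))
        return np.asarray(zs, dtype=float)
    raise ValueError(f"unknown null pool strategy {strategy!r}")


@dataclass
class ReporterScoreTable:
    """Per-enzyme reporter scores for one network and one contrast.

    ``table`` columns: k, z, mu_k, sigma_k, z_corrected, p (index:
    enzyme). ``skipped`` lists enzymes omitted for lack of any measured
    mapped gene.
    """

    table: pd.DataFrame
    network_label: str
    mode: AggregationMode
    cell_type: str = ""
    skipped: list[str] = field(default_factory=list)

    def flagged(self, alpha: float = 0.05) -> set[str]:
        """Enzymes with P strictly below alpha (ties excluded)."""
        return set(self.table.index[self.table["p"] < alpha])

    def write(self, path: str | Path, alpha: float = 0.05) -> None:
        out = self.table.copy()
        out["flagged"] = (out["p"] < alpha).astype(int)
        out.index.name = "enzyme"
        out.to_csv(path, sep="\t", float_format="%.10g")


def score_network(
    net: EnzymeNetwork,
    pvals: dict[str, float],
    gene_map: GeneEnzymeMap,
    null: NullModel,
    cell_type: str = "",
) -> ReporterScoreTable:
    """Score every enzyme of the network against the background null.

    Enzymes with no measured mapped gene are omitted (and listed in
    ``skipped``); ks missing from the null cache are computed on demand
    from the same seed stream.
    """
    rows = {}
    skipped = []
    for enzyme in sorted(net.enzymes):
        genes = sorted(g for g in gene_map.genes_of(enzyme) if g in pvals)
        if not genes:
            skipped.append(enzyme)
            continue
        zs = p_to_z(np.array([pvals[g] for g in genes]))
        z_enzyme = aggregate_enzyme_z(zs, null.mode)
        mu, sigma = null.moments(len(genes))
        z_corr = (z_enzyme - mu) / sigma
        rows[enzyme] = (len(genes), z_enzyme, mu, sigma, z_corr, float(stats.norm.sf(z_corr)))
    columns = ["k", "z", "mu_k", "sigma_k", "z_corrected", "p"]
    if rows:
        table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
        table["k"] = table["k"].astype(int)
    else:
        table = pd.DataFrame(columns=columns)
    return ReporterScoreTable(
        table=table, network_label=net.label, mode=null.mode, cell_type=cell_type, skipped=skipped
    )


def intersect_reporters(
    tables: Sequence[ReporterScoreTable], alpha: float = 0.05
) -> set[str]:
    """Enzymes significant (P < alpha) in every per-cell-type table.

    All tables must score the same network; mixing networks is a
    validation error.
    """
    if len(tables) < 2:
        raise ValueError("need at least two score tables to intersect")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    labels = {t.network_label for t in tables}
    if len(labels) != 1:
        raise ValueError(f"tables score different networks: {sorted(labels)}")
    flagged = [t.flagged(alpha) for t in tables]
    return set.intersection(*flagged)
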