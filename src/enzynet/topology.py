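"""Topology statistics for enzyme networks.

Summaries (degree distribution, characteristic path length, diameter,
clustering), a log-log least-squares power-law fit to the degree
histogram (the scale-free check), and a nonparametric comparison of
reporter-enzyme topology against the network background.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats

from .network import EnzymeNetwork, undirected_view

__all__ = [
    "TopologySummary",
    "ReporterTopologyComparison",
    "summarize",
    "degree_histogram",
    "fit_power_law",
    "compare_reporter_topology",
]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    degree_sequence: list[int]
    characteristic_path_length: float
    diameter: int
    max_shortest_path: int
    clustering_coefficient: float
    power_law_a: float | None
    power_law_b: float | None
    power_law_residual: float | None

    def to_json(self, path: str | Path) -> None:
        record = asdict(self)
        record["degree_histogram"] = {
            str(d): c for d, c in sorted(degree_histogram_from_sequence(self.degree_sequence).items())
        }
        del record["degree_sequence"]
        Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


@dataclass
class ReporterTopologyComparison:
    """Reporter vs background degree/clustering comparison (rank-sum)."""

    degree_p: float
    clustering_p: float
    reporter_median_degree: float
    background_median_degree: float
    reporter_median_clustering: float
    background_median_clustering: float

    @property
    def degree_direction(self) -> str:
        if self.reporter_median_degree > self.background_median_degree:
            return "reporters_higher"
        if self.reporter_median_degree < self.background_median_degree:
            return "reporters_lower"
        return "tied"


def degree_histogram_from_sequence(degrees: list[int]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return hist


def degree_histogram(net: EnzymeNetwork) -> dict[int, int]:
    und = undirected_view(net) if net.directed else net
    return degree_histogram_from_sequence([d for _, d in und.graph.degree()])


def summarize(net: EnzymeNetwork) -> TopologySummary:
    """Topology summary of the network's undirected view.

    Shortest-path statistics are computed over the largest connected
    component; the clustering coefficient is the mean local clustering
    over all nodes, with nodes of degree < 2 contributing 0.
    """
    und = undirected_view(net) if net.directed else net
    graph = und.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot summarize an empty network")
    degrees = sorted((d for _, d in graph.degree()), reverse=True)
    components = list(nx.connected_components(graph))
    largest = graph.subgraph(max(components, key=lambda c: (len(c), sorted(c)[0])))
    if largest.number_of_nodes() > 1:
        cpl = nx.average_shortest_path_length(largest)
        diameter = nx.diameter(largest)
    else:
        cpl, diameter = 0.0, 0
    clustering = nx.average_clustering(graph) if graph.number_of_nodes() else 0.0
    hist = degree_histogram_from_sequence(degrees)
    try:
        a, b, resid = fit_power_law(hist)
    except ValueError:
        a = b = resid = None
    return TopologySummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        degree_sequence=degrees,
        characteristic_path_length=float(cpl),
        diameter=int(diameter),
        max_shortest_path=int(diameter),
        clustering_coefficient=float(clustering),
        power_law_a=a,
        power_law_b=b,
        power_law_residual=resid,
    )


def fit_power_law(degree_hist: dict[int, int]) -> tuple[float, float, float]:
    """Least-squares fit of ``count = a * degree^b`` on the log-log scale.

    Only strictly positive degrees with nonzero counts enter the fit; at
    least two distinct support points are required. Returns ``(a, b,
    rms residual on the log scale)``.
    """
    points = [(d, c) for d, c in degree_hist.items() if d > 0 and c > 0]
    if len(points) < 2:
        raise ValueError("power-law fit needs >=2 nonzero-degree support points")
    x = np.log(np.array([d for d, _ in points], dtype=float))
    y = np.log(np.array([c for _, c in points], dtype=float))
    b, log_a = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - (log_a + b * x)) ** 2)))
    return float(np.exp(log_a)), float(b), resid


def compare_reporter_topology(
    net: EnzymeNetwork, reporters: set[str]
) -> ReporterTopologyComparison:
    """Two-sided Wilcoxon rank-sum comparison of reporters vs the rest.

    Degree and local clustering are compared separately; group medians
    and the direction of the degree difference are reported alongside the
    P-values. Exact P-values are used automatically at small group sizes
    (scipy's method selection).
    """
    und = undirected_view(net) if net.directed else net
    graph = und.graph
    if not reporters <= set(graph.nodes):
        raise ValueError("reporters must be a subset of the network's nodes")
    background = set(graph.nodes) - reporters
    if not reporters or not background:
        raise ValueError("both reporter and background groups must be non-empty")
    clustering = nx.clustering(graph)
    rep = sorted(reporters)
    bg = sorted(background)
    rep_deg = np.array([graph.degree(v) for v in rep], dtype=float)
    bg_deg = np.array([graph.degree(v) for v in bg], dtype=float)
    rep_clu = np.array([clustering[v] for v in rep], dtype=float)
    bg_clu = np.array([clustering[v] for v in bg], dtype=float)
    def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
        if np.ptp(np.concatenate([a, b])) == 0:  # all tied: no evidence either way
            return 1.0
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        return 1.0 if np.isnan(p) else p

    degree_p = _ranksum_p(rep_deg, bg_deg)
    clustering_p = _ranksum_p(rep_clu, bg_clu)
    return ReporterTopologyComparison(
        degree_p=degree_p,
        clustering_p=clustering_p,
        reporter_median_degree=float(np.median(rep_deg)),
        background_median_degree=float(np.median(bg_deg)),
        reporter_median_clustering=float(np.median(rep_clu)),
        background_median_clustering=float(np.median(bg_clu)),
    )
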