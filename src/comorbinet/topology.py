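"""Node centralities, distribution diagnostics and measure-measure correlations.

All centralities are computed on the unweighted thresholded graph (weights
stay edge attributes).  Betweenness is normalized by (n-1)(n-2)/2; the local
clustering coefficient (cc1) of nodes with degree < 2 is 0; closeness (cc2)
is computed within each connected component; path length is averaged over
connected pairs only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

#: the six measure pairs correlated for the hierarchy diagnostics
CORRELATION_PAIRS = (
    ("degree", "cc1"),
    ("cc2", "cc1"),
    ("degree", "cc2"),
    ("bc", "cc2"),
    ("degree", "bc"),
    ("cc1", "bc"),
)


@dataclass(frozen=True)
class TopologyProfile:
    """Per-node centralities plus global network summaries."""

    nodes: pd.DataFrame  # index: node; columns: degree, bc, cc1, cc2
    n_nodes: int
    n_edges: int
    average_degree: float
    average_path_length: float
    average_cc1: float


def compute_topology(network: nx.Graph, *, weighted_paths: bool = False) -> TopologyProfile:
    """Compute degree, betweenness (bc), clustering (cc1) and closeness (cc2).

    ``weighted_paths=True`` uses edge weights as path costs for bc/cc2
    (off by default; the standard diagnostics are unweighted).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("topology requires a network with at least one node")
    weight = "weight" if weighted_paths else None
    degree = dict(network.degree())
    bc = nx.betweenness_centrality(network, normalized=True, weight=weight)
    cc1 = nx.clustering(network)
    cc2 = nx.closeness_centrality(network, wf_improved=False, distance=weight)
    nodes = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "bc": pd.Series(bc),
            "cc1": pd.Series(cc1),
            "cc2": pd.Series(cc2),
        }
    ).sort_index()
    n, m = network.number_of_nodes(), network.number_of_edges()
    return TopologyProfile(
        nodes=nodes,
        n_nodes=n,
        n_edges=m,
        average_degree=2 * m / n,
        average_path_length=_average_path_length(network),
        average_cc1=float(nodes["cc1"].mean()),
    )


def _average_path_length(network: nx.Graph) -> float:
    """Mean shortest-path length over connected (reachable) node pairs."""
    total, pairs = 0.0, 0
    for component in nx.connected_components(network):
        sub = network.subgraph(component)
        k = len(component)
        if k < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += k * (k - 1)
    return total / pairs if pairs else float("nan")


def degree_and_weight_distributions(
    network: nx.Graph, *, n_bins: int = 12
) -> tuple[pd.Series, pd.Series, dict[str, float | None]]:
    """Degree and edge-weight histograms plus log-log least-squares slopes.

    The slope is fit on logarithmically binned (value, density) points as a
    heavy-tail diagnostic, not a formal power-law fit.  Degenerate
    (all-equal) distributions yield a ``None`` slope.
    """
    if network.number_of_nodes() < 10:
        warnings.warn("fewer than 10 nodes: slope estimates unreliable", stacklevel=2)
    degrees = np.array([d for _, d in network.degree()], dtype=float)
    weights = np.array([d.get("weight", 1) for _, _, d in network.edges(data=True)], dtype=float)
    degree_hist = pd.Series(degrees).value_counts().sort_index()
    weight_hist = pd.Series(weights).value_counts().sort_index()
    slopes = {
        "degree_slope": _loglog_slope(degrees, n_bins),
        "weight_slope": _loglog_slope(weights, n_bins),
    }
    return degree_hist, weight_hist, slopes


def _loglog_slope(values: np.ndarray, n_bins: int) -> float | None:
    values = values[values > 0]
    if values.size == 0 or np.all(values == values[0]):
        return None
    edges = np.logspace(np.log10(values.min()), np.log10(values.max()), n_bins + 1)
    edges[-1] *= 1 + 1e-9
    counts, edges = np.histogram(values, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    widths = np.diff(edges)
    mask = counts > 0
    if mask.sum() < 2:
        return None
    x = np.log10(centers[mask])
    y = np.log10(counts[mask] / widths[mask])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def measure_correlations(profile: TopologyProfile) -> pd.DataFrame:
    """Pearson correlations (with two-sided p-values) for the six measure pairs.

    Zero-variance measures yield NaN for the affected pairs.
    """
    if profile.n_nodes < 3:
        raise ValueError("measure correlations require at least 3 nodes")
    rows = []
    for a, b in CORRELATION_PAIRS:
        x = profile.nodes[a].to_numpy()
        y = profile.nodes[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((a, b, np.nan, np.nan))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((a, b, float(r), float(p)))
    return pd.DataFrame(rows, columns=["measure_x", "measure_y", "pcc", "p_value"])


def top_k_nodes(profile: TopologyProfile, measure: str, k: int) -> pd.DataFrame:
    """Top-k nodes by a measure, descending; ties broken lexicographically by code."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if measure not in profile.nodes.columns:
        raise ValueError(f"unknown measure {measure!r}; choose from {list(profile.nodes.columns)}")
    if k > profile.n_nodes:
        warnings.warn(f"k={k} exceeds node count {profile.n_nodes}; returning all", stacklevel=2)
        k = profile.n_nodes
    ranked = profile.nodes.sort_values(
        [measure], ascending=False, kind="stable"
    )
    # stable sort on the lexicographically pre-sorted index fixes tie order
    return ranked.head(k)[[measure]].reset_index(names="node")
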