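"""Modularity and multi-level greedy (BGLL/Louvain) community detection.

The optimizer is implemented here rather than delegated, with a seeded node
visit order so runs are reproducible.  Weighted modularity (co-occurrence
edge weights) is the default; unweighted mode treats every edge as weight 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CommunityPartition:
    """Node -> community assignment (ids contiguous from 0) with its modularity."""

    assignment: dict[Hashable, int]
    modularity_q: float
    n_communities: int

    def communities(self) -> list[set[Hashable]]:
        out: list[set[Hashable]] = [set() for _ in range(self.n_communities)]
        for node, c in self.assignment.items():
            out[c].add(node)
        return out


def _edge_weight(data: Mapping, weighted: bool) -> float:
    return float(data.get("weight", 1.0)) if weighted else 1.0


def modularity(
    network: nx.Graph, assignment: Mapping[Hashable, int], *, weighted: bool = True,
    resolution: float = 1.0,
) -> float:
    """Newman-Girvan modularity of a partition.

    Q = sum_c [ w_in(c)/W - resolution * (s(c) / 2W)^2 ] where W is the total
    edge weight (each edge counted once), w_in(c) the intra-community edge
    weight and s(c) the summed node strength of community c.
    """
    missing = [v for v in network.nodes if v not in assignment]
    if missing:
        raise ValueError(f"assignment missing {len(missing)} nodes, e.g. {missing[0]!r}")
    w_total = 0.0
    w_in: dict[int, float] = {}
    strength: dict[int, float] = {}
    for u, v, data in network.edges(data=True):
        w = _edge_weight(data, weighted)
        w_total += w
        cu, cv = assignment[u], assignment[v]
        strength[cu] = strength.get(cu, 0.0) + w
        strength[cv] = strength.get(cv, 0.0) + w  # self-loops count twice, as in k_i
        if cu == cv:
            w_in[cu] = w_in.get(cu, 0.0) + w
    if w_total == 0:
        return 0.0
    q = 0.0
    for c in set(assignment.values()):
        q += w_in.get(c, 0.0) / w_total - resolution * (strength.get(c, 0.0) / (2 * w_total)) ** 2
    return q


def _relabel_contiguous(assignment: dict[Hashable, int]) -> tuple[dict[Hashable, int], int]:
    ids: dict[int, int] = {}
    out = {}
    for node in sorted(assignment, key=str):
        c = assignment[node]
        if c not in ids:
            ids[c] = len(ids)
        out[node] = ids[c]
    return out, len(ids)


def _one_level(
    adj: list[dict[int, float]], strength: np.ndarray, two_w: float,
    rng: np.random.Generator, resolution: float,
) -> tuple[np.ndarray, bool]:
    """Phase 1 of BGLL: greedy local moves until no move improves Q."""
    n = len(adj)
    community = np.arange(n)
    comm_strength = strength.copy()
    improved_any = False
    improved = True
    while improved:
        improved = False
        for node in rng.permutation(n):
            c_old = community[node]
            # weight from node to each neighboring community (excluding self-edges)
            links: dict[int, float] = {}
            for nbr, w in adj[node].items():
                if nbr != node:
                    links[community[nbr]] = links.get(community[nbr], 0.0) + w
            comm_strength[c_old] -= strength[node]
            best_c, best_gain = c_old, 0.0
            base = links.get(c_old, 0.0) - resolution * comm_strength[c_old] * strength[node] / two_w
            for c, w_link in links.items():
                if c == c_old:
                    continue
                gain = (w_link - resolution * comm_strength[c] * strength[node] / two_w) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            community[node] = best_c
            comm_strength[best_c] += strength[node]
            if best_c != c_old:
                improved = True
                improved_any = True
    return community, improved_any


def louvain(
    network: nx.Graph, *, seed: int = 0, weighted: bool = True, resolution: float = 1.0,
    restarts: int = 1,
) -> CommunityPartition:
    """BGLL community detection: local moves + community aggregation, repeated.

    Deterministic given ``seed`` (which shuffles the node visit order).  The
    returned ``modularity_q`` equals ``modularity(network, assignment)``.
    ``restarts > 1`` reruns the greedy optimization with derived seeds and
    keeps the best partition — the usual antidote to visit-order traps on
    small graphs.
    """
    if restarts > 1:
        sub_seeds = np.random.default_rng(seed).integers(0, 2**31, size=restarts)
        best = None
        for s in sub_seeds:
            part = louvain(
                network, seed=int(s), weighted=weighted, resolution=resolution, restarts=1
            )
            if best is None or part.modularity_q > best.modularity_q:
                best = part
        return best
    if network.number_of_nodes() == 0:
        raise ValueError("louvain requires at least one node")
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}

    # current aggregated graph as adjacency dicts; meta[i] = original community id
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for u, v, data in network.edges(data=True):
        w = _edge_weight(data, weighted)
        i, j = index[u], index[v]
        if i == j:
            adj[i][i] = adj[i].get(i, 0.0) + w  # stored once; strength doubles it
        else:
            adj[i][j] = adj[i].get(j, 0.0) + w
            adj[j][i] = adj[j].get(i, 0.0) + w

    two_w = 0.0
    strength_list = []
    for i, nbrs in enumerate(adj):
        s = sum(w * (2.0 if j == i else 1.0) for j, w in nbrs.items())
        strength_list.append(s)
        two_w += s
    membership = np.arange(len(nodes))  # original node -> current meta-node

    if two_w == 0:
        assignment, k = _relabel_contiguous({v: 0 for v in nodes})
        return CommunityPartition(assignment, 0.0, k)

    while True:
        strength = np.array(strength_list)
        community, improved = _one_level(adj, strength, two_w, rng, resolution)
        if not improved:
            break
        # aggregate: communities become nodes of the next-level graph
        labels = {c: i for i, c in enumerate(sorted(set(community)))}
        membership = np.array([labels[community[m]] for m in membership])
        n_new = len(labels)
        new_adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
        for i, nbrs in enumerate(adj):
            ci = labels[community[i]]
            for j, w in nbrs.items():
                cj = labels[community[j]]
                if j < i:
                    continue  # each undirected edge once
                if ci == cj:
                    new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                    new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
        adj = new_adj
        strength_list = [
            sum(w * (2.0 if j == i else 1.0) for j, w in nbrs.items())
            for i, nbrs in enumerate(adj)
        ]

    raw = {v: int(membership[index[v]]) for v in nodes}
    assignment, k = _relabel_contiguous(raw)
    q = modularity(network, assignment, weighted=weighted, resolution=resolution)
    return CommunityPartition(assignment=assignment, modularity_q=q, n_communities=k)


def community_composition(
    partition: CommunityPartition,
    chapter_map: Mapping[Hashable, str] | None = None,
) -> pd.DataFrame:
    """Per-community chapter composition (counts, fractions, dominant chapter).

    ``chapter_map`` defaults to the first character of the disease code.
    Unmapped nodes get chapter ``UNKNOWN`` with a warning.
    """
    rows = []
    for node, comm in partition.assignment.items():
        if chapter_map is not None:
            chapter = chapter_map.get(node)
            if chapter is None:
                warnings.warn(f"node {node!r} missing from chapter_map; using UNKNOWN", stacklevel=2)
                chapter = "UNKNOWN"
        else:
            chapter = str(node)[:1] if str(node) else "UNKNOWN"
        rows.append((comm, chapter))
    df = pd.DataFrame(rows, columns=["community", "chapter"])
    counts = df.groupby(["community", "chapter"]).size().rename("count").reset_index()
    totals = counts.groupby("community")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    counts["total"] = totals
    dominant = counts.loc[counts.groupby("community")["count"].idxmax(), ["community", "chapter"]]
    counts = counts.merge(dominant.rename(columns={"chapter": "dominant_chapter"}), on="community")
    return counts.sort_values(["community", "chapter"]).reset_index(drop=True)
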