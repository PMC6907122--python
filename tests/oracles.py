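"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive: Floyd-Warshall paths, explicit
shortest-path counting, double loops over patients, exhaustive set-partition
enumeration.  None of it shares code with the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# pair statistics

def brute_force_pair_counts(patient_sets: list[set[str]]) -> dict:
    """Contingency counts from a double loop over patients."""
    codes = sorted(set().union(*patient_sets)) if patient_sets else []
    n = len(patient_sets)
    prevalence = {c: sum(1 for s in patient_sets if c in s) for c in codes}
    co = {}
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            c_ab = sum(1 for s in patient_sets if a in s and b in s)
            co[(a, b)] = c_ab
    return {"n": n, "prevalence": prevalence, "co": co}


def indicator_pearson(c_ij: int, p_i: int, p_j: int, n: int) -> float:
    """Pearson correlation of the expanded binary indicator vectors."""
    x = np.zeros(n)
    y = np.zeros(n)
    x[:p_i] = 1  # both: first c_ij; only-i: next p_i - c_ij
    y[:c_ij] = 1
    y[p_i : p_i + (p_j - c_ij)] = 1
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# graph centralities

def _adjacency(nodes, edges):
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        if u != v:
            a[index[u], index[v]] = a[index[v], index[u]] = True
    return a


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[a] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def shortest_path_counts(a: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of shortest s-t paths, by dynamic programming."""
    n = a.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(dist[s])
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            preds = [u for u in range(n) if a[u, t] and dist[s, u] == dist[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    return sigma


def brute_force_centralities(nodes, edges):
    """degree, betweenness (normalized), clustering, closeness per node."""
    a = _adjacency(nodes, edges)
    n = len(nodes)
    dist = floyd_warshall(a)
    sigma = shortest_path_counts(a, dist)

    degree = a.sum(axis=1).astype(float)

    clustering = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for x, y in itertools.combinations(nbrs, 2) if a[x, y]
        )
        clustering[v] = 2 * links / (k * (k - 1))

    closeness = np.zeros(n)
    for v in range(n):
        reachable = np.flatnonzero(np.isfinite(dist[v]) & (np.arange(n) != v))
        if reachable.size:
            closeness[v] = reachable.size / dist[v, reachable].sum()

    betweenness = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if dist[s, v] + dist[v, t] == dist[s, t]:
                betweenness[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if n > 2:
        betweenness /= (n - 1) * (n - 2) / 2

    return {
        node: {
            "degree": degree[i],
            "cc1": clustering[i],
            "cc2": closeness[i],
            "bc": betweenness[i],
        }
        for i, node in enumerate(nodes)
    }


# ---------------------------------------------------------------------------
# modularity / partitions

def brute_force_modularity(edges_with_weights, assignment) -> float:
    """Direct double-sum modularity: (1/2W) sum_ij (A_ij - k_i k_j / 2W) delta."""
    nodes = sorted(assignment, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, w in edges_with_weights:
        i, j = index[u], index[v]
        if i == j:
            a[i, i] += 2 * w
        else:
            a[i, j] += w
            a[j, i] += w
    two_w = a.sum()
    if two_w == 0:
        return 0.0
    k = a.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += a[i, j] - k[i] * k[j] / two_w
    return q / two_w


def set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield [[first]] + partial


def best_partition_exhaustive(nodes, edges_with_weights):
    """Maximum-modularity partition by enumerating all set partitions."""
    best_q, best = -math.inf, None
    for parts in set_partitions(list(nodes)):
        assignment = {v: ci for ci, block in enumerate(parts) for v in block}
        q = brute_force_modularity(edges_with_weights, assignment)
        if q > best_q:
            best_q, best = q, assignment
    return best_q, best


# ---------------------------------------------------------------------------
# plain correlation

def plain_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
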