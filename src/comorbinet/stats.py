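"""Pairwise contingency statistics and the thresholded Disease Comorbidity Network.

Counting is patient-level: a patient contributes at most once to each
prevalence count and to each co-occurrence count, regardless of how many
visits mention a disease (the disease set is the union over visits).

The phi correlation uses the binary-indicator Pearson form

    phi = (C_ij * N - P_i * P_j) / sqrt(P_i * P_j * (N - P_i) * (N - P_j))

with P_i, P_j patient counts.  A published variant with numerator
``C_ij - P_i * P_j`` circulates in the comorbidity literature; it is
dimensionally inconsistent with count prevalences (it cannot be positive
whenever RR > 1) and is provided only behind ``printed_formula=True`` for
comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from comorbinet.ingest import PatientProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairStatistics:
    """Contingency counts plus RR and phi for one disease pair (i < j)."""

    disease_i: str
    disease_j: str
    c_ij: int
    p_i: int
    p_j: int
    n: int
    rr: float
    phi: float

    def __post_init__(self) -> None:
        if self.disease_i >= self.disease_j:
            raise ValueError("pair must be ordered disease_i < disease_j")
        if not 0 <= self.c_ij <= min(self.p_i, self.p_j):
            raise ValueError("C_ij must satisfy 0 <= C_ij <= min(P_i, P_j)")
        if max(self.p_i, self.p_j) > self.n:
            raise ValueError("prevalence counts cannot exceed N")


class ComorbidityNetwork(nx.Graph):
    """Undirected weighted DCN; edge attributes ``weight`` (= C_ij), ``rr``, ``phi``."""


def relative_risk(c_ij: int, p_i: int, p_j: int, n: int) -> float:
    """Relative risk of co-occurrence, ``C_ij * N / (P_i * P_j)``.

    Raises
    ------
    ValueError
        If either prevalence count or N is zero.
    """
    if p_i <= 0 or p_j <= 0 or n <= 0:
        raise ValueError("relative risk requires P_i > 0, P_j > 0, N > 0")
    return c_ij * n / (p_i * p_j)


def phi_correlation(
    c_ij: int, p_i: int, p_j: int, n: int, *, printed_formula: bool = False
) -> float:
    """Phi correlation of the two binary patient-indicator vectors.

    Equals the Pearson correlation of the length-N {0,1} indicator vectors
    of the two diseases.  ``printed_formula=True`` switches the numerator to
    ``C_ij - P_i * P_j`` (compatibility only; see module docstring).

    Raises
    ------
    ValueError
        If either disease has zero or full prevalence (degenerate indicator).
    """
    if not (0 < p_i < n and 0 < p_j < n):
        raise ValueError("phi requires 0 < P_i < N and 0 < P_j < N")
    numerator = (c_ij - p_i * p_j) if printed_formula else (c_ij * n - p_i * p_j)
    return numerator / math.sqrt(p_i * p_j * (n - p_i) * (n - p_j))


def count_contingency(
    profiles: Sequence[PatientProfile],
    *,
    n_patients: int | None = None,
    include_zero_pairs: bool = False,
    printed_formula: bool = False,
) -> list[PairStatistics]:
    """Compute patient-level contingency counts, RR and phi for disease pairs.

    Each patient contributes at most 1 to ``C_ij`` and to each ``P_i``.  By
    default only pairs observed together at least once are materialized;
    ``include_zero_pairs=True`` also emits co-occurrence-free pairs (useful
    for unselected correlation analyses).  Pairs where either disease has
    zero or full prevalence are skipped with a logged count.

    ``n_patients`` overrides the population size N when the cohort includes
    patients without any recorded diagnosis (otherwise N is the number of
    profiles, which conditions on >= 1 disease and biases RR/phi downward).
    """
    if not profiles:
        raise ValueError("count_contingency requires a nonempty profile collection")
    n = len(profiles) if n_patients is None else int(n_patients)
    if n < len(profiles):
        raise ValueError("n_patients cannot be smaller than the number of profiles")
    codes = sorted({c for prof in profiles for c in prof.disease_set})
    idx = {c: i for i, c in enumerate(codes)}
    rows, cols = [], []
    for r, prof in enumerate(profiles):
        for c in prof.disease_set:
            rows.append(r)
            cols.append(idx[c])
    incidence = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=(n, len(codes))
    )
    prevalence = np.asarray(incidence.sum(axis=0)).ravel()
    co = (incidence.T @ incidence).toarray()

    stats: list[PairStatistics] = []
    n_degenerate = 0
    for i in range(len(codes)):
        p_i = int(prevalence[i])
        for j in range(i + 1, len(codes)):
            c_ij = int(co[i, j])
            if c_ij == 0 and not include_zero_pairs:
                continue
            p_j = int(prevalence[j])
            if p_i in (0, n) or p_j in (0, n):
                n_degenerate += 1
                continue
            stats.append(
                PairStatistics(
                    disease_i=codes[i],
                    disease_j=codes[j],
                    c_ij=c_ij,
                    p_i=p_i,
                    p_j=p_j,
                    n=n,
                    rr=relative_risk(c_ij, p_i, p_j, n),
                    phi=phi_correlation(c_ij, p_i, p_j, n, printed_formula=printed_formula),
                )
            )
    if n_degenerate:
        logger.info("skipped %d pairs with degenerate prevalence (0 or N)", n_degenerate)
    return stats


def build_network(
    pair_stats: Iterable[PairStatistics],
    *,
    min_cooccurrence: float = 5,
    min_rr: float = 1.0,
    min_phi: float = 0.0,
    strict: bool = True,
) -> ComorbidityNetwork:
    """Build the thresholded DCN from pair statistics.

    Retains pairs with ``C_ij > min_cooccurrence``, ``RR > min_rr`` and
    ``phi > min_phi`` (all strict by default; ``strict=False`` switches to
    >=).  Nodes are diseases incident to at least one retained edge; edge
    weight is the co-occurrence count.
    """
    net = ComorbidityNetwork()
    cmp = (lambda a, b: a > b) if strict else (lambda a, b: a >= b)
    for ps in pair_stats:
        if cmp(ps.c_ij, min_cooccurrence) and cmp(ps.rr, min_rr) and cmp(ps.phi, min_phi):
            net.add_edge(ps.disease_i, ps.disease_j, weight=ps.c_ij, rr=ps.rr, phi=ps.phi)
    if net.number_of_edges() == 0:
        logger.warning("no pair survives the thresholds; returning an empty network")
    return net


def pair_stats_to_frame(pair_stats: Iterable[PairStatistics]) -> pd.DataFrame:
    """Tabulate pair statistics (one row per pair)."""
    return pd.DataFrame(
        [
            (p.disease_i, p.disease_j, p.c_ij, p.p_i, p.p_j, p.n, p.rr, p.phi)
            for p in pair_stats
        ],
        columns=["disease_i", "disease_j", "c_ij", "p_i", "p_j", "n", "rr", "phi"],
    )


def export_network(
    network: ComorbidityNetwork, path: str | Path, *, fmt: str = "tsv"
) -> None:
    """Write the network as a TSV edge list or GraphML.

    The edge list has columns ``disease_i, disease_j, weight, rr, phi`` with
    pairs ordered lexicographically; reading it back reproduces the network.
    """
    if fmt == "tsv":
        rows = []
        for u, v, data in network.edges(data=True):
            a, b = sorted((u, v))
            rows.append((a, b, data["weight"], data["rr"], data["phi"]))
        df = pd.DataFrame(rows, columns=["disease_i", "disease_j", "weight", "rr", "phi"])
        df = df.sort_values(["disease_i", "disease_j"])
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unknown network export format: {fmt!r}")


def load_network(path: str | Path, *, fmt: str = "tsv") -> ComorbidityNetwork:
    """Read a network written by :func:`export_network`."""
    net = ComorbidityNetwork()
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"disease_i": str, "disease_j": str})
        for row in df.itertuples(index=False):
            net.add_edge(
                row.disease_i, row.disease_j,
                weight=int(row.weight), rr=float(row.rr), phi=float(row.phi),
            )
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        net.add_nodes_from(g.nodes)
        for u, v, data in g.edges(data=True):
            net.add_edge(u, v, weight=int(data["weight"]), rr=float(data["rr"]), phi=float(data["phi"]))
    else:
        raise ValueError(f"unknown network format: {fmt!r}")
    return net
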