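"""Validation of comorbidity strength against shared molecular mechanisms.

For each disease pair: shared gene/pathway counts and Jaccard / cosine set
similarities; across pairs: Pearson correlations between comorbidity
strength (RR, phi) and molecular overlap, plus binned mean-strength curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from comorbinet.stats import PairStatistics

logger = logging.getLogger(__name__)

#: default shared-count bin edges: {0}, [1,5], [6,10], [11,20], [21, inf)
DEFAULT_BIN_EDGES = (0, 1, 6, 11, 21)


@dataclass(frozen=True)
class MolecularOverlap:
    """Molecular overlap of one disease pair."""

    disease_i: str
    disease_j: str
    shared_gene_count: int
    shared_pathway_count: int
    jaccard_genes: float
    cosine_genes: float
    jaccard_pathways: float
    cosine_pathways: float


def _set_similarities(a: frozenset, b: frozenset) -> tuple[int, float, float]:
    """(intersection size, jaccard, cosine); both-empty yields (0, 0, 0)."""
    inter = len(a & b)
    union = len(a | b)
    jacc = inter / union if union else 0.0
    cos = inter / math.sqrt(len(a) * len(b)) if a and b else 0.0
    return inter, jacc, cos


def overlap_statistics(
    pairs: Iterable[tuple[str, str]],
    disease_genes: Mapping[str, frozenset[str]],
    disease_pathways: Mapping[str, frozenset[str]],
) -> list[MolecularOverlap]:
    """Shared counts and similarities for every pair covered by the maps.

    Pairs with a disease absent from the gene map are skipped (logged).
    Diseases missing from the pathway map are treated as having no pathways.
    """
    out = []
    n_skipped = 0
    for a, b in pairs:
        if a not in disease_genes or b not in disease_genes:
            n_skipped += 1
            continue
        i, j = sorted((a, b))
        g_shared, g_jacc, g_cos = _set_similarities(disease_genes[i], disease_genes[j])
        pw_i = disease_pathways.get(i, frozenset())
        pw_j = disease_pathways.get(j, frozenset())
        p_shared, p_jacc, p_cos = _set_similarities(pw_i, pw_j)
        out.append(
            MolecularOverlap(i, j, g_shared, p_shared, g_jacc, g_cos, p_jacc, p_cos)
        )
    if n_skipped:
        logger.info("skipped %d pairs without gene annotations", n_skipped)
    return out


def _pcc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def format_p(p: float) -> str:
    """Display rule mirroring common statistical output: floors tiny p-values."""
    if math.isnan(p):
        return "NA"
    return "< 2.2e-16" if p < 2.2e-16 else f"{p:.4g}"


def correlate_comorbidity_with_molecular(
    pair_stats: Sequence[PairStatistics],
    overlaps: Sequence[MolecularOverlap],
) -> pd.DataFrame:
    """Pearson correlation of each comorbidity measure with each overlap measure.

    Rows: (comorbidity measure, molecular measure, pcc, p_value, n_pairs).
    Only pairs present in both inputs contribute.  Zero-variance vectors
    yield NaN with a warning in the log.
    """
    by_pair = {(o.disease_i, o.disease_j): o for o in overlaps}
    rows_x, rows_o = [], []
    for ps in pair_stats:
        o = by_pair.get((ps.disease_i, ps.disease_j))
        if o is not None:
            rows_x.append(ps)
            rows_o.append(o)
    if len(rows_x) < 3:
        raise ValueError("need at least 3 pairs with both statistics")
    comorb = {
        "rr": np.array([p.rr for p in rows_x]),
        "phi": np.array([p.phi for p in rows_x]),
    }
    molecular = {
        "shared_genes": np.array([o.shared_gene_count for o in rows_o], dtype=float),
        "shared_pathways": np.array([o.shared_pathway_count for o in rows_o], dtype=float),
        "jaccard_genes": np.array([o.jaccard_genes for o in rows_o]),
        "cosine_genes": np.array([o.cosine_genes for o in rows_o]),
        "jaccard_pathways": np.array([o.jaccard_pathways for o in rows_o]),
        "cosine_pathways": np.array([o.cosine_pathways for o in rows_o]),
    }
    records = []
    for cname, cvec in comorb.items():
        for mname, mvec in molecular.items():
            r, p = _pcc(cvec, mvec)
            if math.isnan(r):
                logger.warning("zero variance for %s vs %s: PCC undefined", cname, mname)
            records.append((cname, mname, r, p, len(cvec)))
    # similarity-vs-count correlations (Jaccard/Cosine against shared counts)
    for sim in ("jaccard_genes", "cosine_genes"):
        r, p = _pcc(molecular[sim], molecular["shared_genes"])
        records.append((sim, "shared_genes", r, p, len(rows_x)))
    for sim in ("jaccard_pathways", "cosine_pathways"):
        r, p = _pcc(molecular[sim], molecular["shared_pathways"])
        records.append((sim, "shared_pathways", r, p, len(rows_x)))
    return pd.DataFrame(records, columns=["measure_x", "measure_y", "pcc", "p_value", "n_pairs"])


def binned_strength_curve(
    pair_stats: Sequence[PairStatistics],
    overlaps: Sequence[MolecularOverlap],
    *,
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
    overlap_measure: str = "shared_gene_count",
) -> pd.DataFrame:
    """Mean comorbidity strength per shared-count bin.

    ``bin_edges`` are left edges starting at 0; the default (0, 1, 6, 11, 21)
    gives bins {0}, [1,5], [6,10], [11,20], [21, inf).  Empty bins are
    reported with n=0 and NaN means.
    """
    edges = list(bin_edges)
    if edges[0] != 0:
        raise ValueError("bin_edges must start at 0")
    if any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    by_pair = {(o.disease_i, o.disease_j): o for o in overlaps}
    data = []
    for ps in pair_stats:
        o = by_pair.get((ps.disease_i, ps.disease_j))
        if o is None:
            continue
        count = getattr(o, overlap_measure)
        idx = int(np.searchsorted(edges, count, side="right")) - 1
        data.append((idx, ps.rr, ps.phi))
    df = pd.DataFrame(data, columns=["bin", "rr", "phi"])
    labels = []
    for i, lo in enumerate(edges):
        hi = edges[i + 1] - 1 if i + 1 < len(edges) else None
        if hi is None:
            labels.append(f"[{lo},inf)")
        elif hi == lo:
            labels.append(f"{{{lo}}}")
        else:
            labels.append(f"[{lo},{hi}]")
    rows = []
    for i, label in enumerate(labels):
        sub = df[df["bin"] == i]
        rows.append(
            (label, len(sub),
             float(sub["rr"].mean()) if len(sub) else float("nan"),
             float(sub["phi"].mean()) if len(sub) else float("nan"))
        )
    return pd.DataFrame(rows, columns=["bin", "n_pairs", "mean_rr", "mean_phi"])


def shared_gene_report(
    disease_a: str,
    disease_b: str,
    disease_genes: Mapping[str, frozenset[str]],
    disease_pathways: Mapping[str, frozenset[str]] | None = None,
) -> dict[str, list[str]]:
    """Sorted lists of the genes (and pathways) shared by two diseases."""
    for d in (disease_a, disease_b):
        if d not in disease_genes:
            raise KeyError(f"unknown disease {d!r}")
    shared_genes = sorted(disease_genes[disease_a] & disease_genes[disease_b])
    out = {"shared_genes": shared_genes}
    if disease_pathways is not None:
        out["shared_pathways"] = sorted(
            disease_pathways.get(disease_a, frozenset())
            & disease_pathways.get(disease_b, frozenset())
        )
    return out
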