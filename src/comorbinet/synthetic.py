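"""Synthetic patient cohorts, molecular annotations and trajectories.

All generators plant recoverable structure: modular comorbidity (diseases of
the same module co-occur more than chance), hierarchically nested modules
with cross-module hub diseases, gene-sharing coupled to module membership,
and temporal risk rules (a target disease triggered by earlier risk
diseases).  Every generator is deterministic given its seed.

Disease codes are synthetic ICD-10-like strings (letter + 3 digits) whose
leading letter ("chapter") is aligned with the planted module, so
community-composition checks have ground truth.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from comorbinet.ingest import DiagnosisRecord

_PROB_CLAMP = 0.99


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the flat modular cohort generator.

    ``within_module_boost`` multiplies a disease's sampling probability when
    the patient already carries another disease of the same module; 1.0
    yields fully independent diseases.
    """

    n_patients: int
    n_diseases: int
    n_modules: int
    module_assignment: dict[str, int]
    baseline_prevalence: dict[str, float]
    within_module_boost: float = 1.0
    n_visits_range: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_diseases <= 0 or self.n_modules <= 0:
            raise ValueError("n_patients, n_diseases and n_modules must be positive")
        if self.n_diseases < self.n_modules:
            raise ValueError(
                f"n_diseases ({self.n_diseases}) must be >= n_modules ({self.n_modules})"
            )
        if self.within_module_boost < 1.0:
            raise ValueError("within_module_boost must be >= 1")
        lo, hi = self.n_visits_range
        if lo < 2 or hi < lo:
            raise ValueError("n_visits_range must satisfy 2 <= lo <= hi")
        if set(self.module_assignment) != set(self.baseline_prevalence):
            raise ValueError("module_assignment and baseline_prevalence must cover the same diseases")
        if len(self.module_assignment) != self.n_diseases:
            raise ValueError("module_assignment must cover exactly n_diseases diseases")
        for code, p in self.baseline_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"baseline prevalence of {code} outside (0,1): {p}")
            if p * self.within_module_boost >= _PROB_CLAMP:
                raise ValueError(
                    f"boosted probability for {code} reaches the clamp threshold "
                    f"({p} * {self.within_module_boost} >= {_PROB_CLAMP}); "
                    "lower the boost or the baseline prevalence"
                )

    @property
    def codes(self) -> list[str]:
        return sorted(self.module_assignment)


@dataclass(frozen=True)
class MolecularConfig:
    """Parameters of the disease-gene / pathway-gene table generator.

    ``coupling`` is the fraction of a disease's genes drawn from its module's
    shared gene pool; at 0 gene sharing is independent of comorbidity.
    """

    n_genes: int
    n_pathways: int
    genes_per_disease_range: tuple[int, int] = (5, 15)
    coupling: float = 0.0
    pathway_size_range: tuple[int, int] = (10, 50)
    module_pool_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.genes_per_disease_range[1] > self.n_genes:
            raise ValueError("genes_per_disease upper bound exceeds n_genes")
        if self.genes_per_disease_range[0] < 1 or self.pathway_size_range[0] < 1:
            raise ValueError("gene-count ranges must be >= 1")
        if self.genes_per_disease_range[1] > self.module_pool_size:
            raise ValueError("genes_per_disease upper bound exceeds module_pool_size")


@dataclass(frozen=True)
class RiskRuleConfig:
    """Temporal rule planting a target disease triggered by earlier risk diseases."""

    target_disease: str
    risk_diseases: frozenset[str]
    trigger_probability: float
    background_probability: float

    def __post_init__(self) -> None:
        if not self.risk_diseases:
            raise ValueError("risk_diseases must be nonempty")
        if self.target_disease in self.risk_diseases:
            raise ValueError("target_disease must not be a risk disease")
        if not 0.0 < self.trigger_probability <= 1.0:
            raise ValueError("trigger_probability must lie in (0, 1]")
        if not 0.0 <= self.background_probability < 1.0:
            raise ValueError("background_probability must lie in [0, 1)")
        if self.trigger_probability <= self.background_probability:
            raise ValueError("trigger_probability must exceed background_probability")


def make_cohort_config(
    n_patients: int,
    n_diseases: int,
    n_modules: int,
    *,
    mean_prevalence: float = 0.02,
    prevalence_sigma: float = 0.0,
    within_module_boost: float = 1.0,
    n_visits_range: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> CohortConfig:
    """Build a config with chapter-aligned codes and (optionally) heavy-tailed prevalence.

    Diseases are split into contiguous equal-size blocks, one per module;
    module ``m`` uses chapter letter ``chr(ord('A') + m)``.  With
    ``prevalence_sigma > 0`` baseline prevalences are log-normal around
    ``mean_prevalence`` (clipped to stay clear of the clamp), giving the
    heavy-tailed prevalence profile typical of discharge data.
    """
    if n_modules > 25:
        raise ValueError("at most 25 modules supported (one chapter letter each; Z is reserved)")
    rng = np.random.default_rng(seed)
    letters = string.ascii_uppercase
    module_assignment: dict[str, int] = {}
    baseline: dict[str, float] = {}
    per_module = [n_diseases // n_modules] * n_modules
    for i in range(n_diseases % n_modules):
        per_module[i] += 1
    idx = 0
    for m in range(n_modules):
        for _ in range(per_module[m]):
            code = f"{letters[m]}{idx:03d}"
            module_assignment[code] = m
            idx += 1
    upper = min(0.5, (_PROB_CLAMP / within_module_boost) * 0.9)
    for code in sorted(module_assignment):
        if prevalence_sigma > 0:
            p = float(np.exp(rng.normal(math.log(mean_prevalence), prevalence_sigma)))
        else:
            p = mean_prevalence
        baseline[code] = float(np.clip(p, 1e-4, upper))
    return CohortConfig(
        n_patients=n_patients,
        n_diseases=n_diseases,
        n_modules=n_modules,
        module_assignment=module_assignment,
        baseline_prevalence=baseline,
        within_module_boost=within_module_boost,
        n_visits_range=n_visits_range,
        seed=seed,
    )


def _distribute_to_visits(
    rng: np.random.Generator, present: np.ndarray, n_visits: int
) -> list[np.ndarray]:
    """Assign each present disease to a nonempty subset of visits.

    The union over visits equals the patient's disease set, and every visit
    of a patient with at least one disease is nonempty (an encounter always
    records some diagnosis), so no visit silently disappears downstream.
    """
    k = present.size
    if k == 0:
        return [np.empty(0, dtype=present.dtype) for _ in range(n_visits)]
    mask = rng.random((k, n_visits)) < 0.5
    empty_disease = ~mask.any(axis=1)
    if empty_disease.any():
        cols = rng.integers(0, n_visits, size=int(empty_disease.sum()))
        mask[np.flatnonzero(empty_disease), cols] = True
    empty_visit = ~mask.any(axis=0)
    if empty_visit.any():
        rows = rng.integers(0, k, size=int(empty_visit.sum()))
        mask[rows, np.flatnonzero(empty_visit)] = True
    return [present[mask[:, v]] for v in range(n_visits)]


def _emit_records(
    pid: str, visit_sets: Sequence[np.ndarray], codes: Sequence[str], out: list[DiagnosisRecord]
) -> None:
    for v, idxs in enumerate(visit_sets):
        for d in sorted(codes[i] for i in idxs):
            out.append(DiagnosisRecord(pid, v, d))


def _sample_patient_sequential(
    rng: np.random.Generator,
    base: np.ndarray,
    group_levels: Sequence[np.ndarray],
    level_boosts: Sequence[float],
    hub_mask: np.ndarray | None,
    hub_boost: float,
) -> np.ndarray:
    """Sequential conditional draw of one patient's disease indicator vector.

    Diseases are visited in a fresh random order; each disease's probability
    is its baseline times the strongest applicable boost given diseases
    already drawn (same group at any nesting level, or hub coupling).
    """
    n = base.size
    order = rng.permutation(n)
    u = rng.random(n)
    present = np.zeros(n, dtype=bool)
    group_counts = [np.zeros(int(g.max()) + 1, dtype=np.int64) for g in group_levels]
    any_present = False
    hub_present = False
    for d in order:
        p = base[d]
        factor = 1.0
        for lvl, g in enumerate(group_levels):
            if group_counts[lvl][g[d]] > 0:
                factor = max(factor, level_boosts[lvl])
        if hub_mask is not None:
            if hub_mask[d] and any_present:
                factor = max(factor, hub_boost)
            elif not hub_mask[d] and hub_present:
                factor = max(factor, hub_boost)
        p = min(p * factor, _PROB_CLAMP)
        if u[d] < p:
            present[d] = True
            any_present = True
            if hub_mask is not None and hub_mask[d]:
                hub_present = True
            for lvl, g in enumerate(group_levels):
                group_counts[lvl][g[d]] += 1
    return np.flatnonzero(present)


def _generate(
    n_patients: int,
    codes: list[str],
    base: np.ndarray,
    group_levels: Sequence[np.ndarray],
    level_boosts: Sequence[float],
    n_visits_range: tuple[int, int],
    seed: int,
    hub_mask: np.ndarray | None = None,
    hub_boost: float = 1.0,
) -> list[DiagnosisRecord]:
    rng = np.random.default_rng(seed)
    lo, hi = n_visits_range
    records: list[DiagnosisRecord] = []
    boosted = any(b > 1.0 for b in level_boosts) or (hub_mask is not None and hub_boost > 1.0)
    width = len(str(max(n_patients - 1, 1)))
    for i in range(n_patients):
        n_visits = int(rng.integers(lo, hi + 1))
        if boosted:
            present = _sample_patient_sequential(
                rng, base, group_levels, level_boosts, hub_mask, hub_boost
            )
        else:
            # independent draws; still one uniform per disease for determinism
            present = np.flatnonzero(rng.random(base.size) < base)
        visit_sets = _distribute_to_visits(rng, present, n_visits)
        _emit_records(f"P{i:0{width}d}", visit_sets, codes, records)
    return records


def generate_cohort(config: CohortConfig) -> list[DiagnosisRecord]:
    """Generate a flat modular cohort of multi-visit diagnosis records.

    Per patient, diseases are drawn sequentially in a random order; a
    disease's probability is multiplied by ``within_module_boost`` when the
    patient already carries another disease of the same module.  The
    patient's disease set is then distributed over visits so that the union
    over visits equals the sampled set.
    """
    codes = config.codes
    base = np.array([config.baseline_prevalence[c] for c in codes])
    modules = np.array([config.module_assignment[c] for c in codes])
    return _generate(
        config.n_patients,
        codes,
        base,
        [modules],
        [config.within_module_boost],
        config.n_visits_range,
        config.seed,
    )


def generate_hierarchical_cohort(
    config: CohortConfig,
    nesting_depth: int = 2,
    *,
    n_submodules: int = 3,
    n_hubs: int = 4,
    hub_prevalence: float = 0.15,
    hub_boost: float = 2.5,
    parent_boost: float | None = None,
) -> tuple[list[DiagnosisRecord], dict[str, int]]:
    """Generate a cohort with nested modules plus cross-module hub diseases.

    Each top-level module is split into ``n_submodules`` sub-modules; the
    full ``within_module_boost`` applies within a sub-module and a weaker
    ``parent_boost`` (default ``sqrt(boost)``) within the parent module.
    ``n_hubs`` extra high-prevalence diseases (chapter ``Z``) are coupled to
    every other disease with ``hub_boost``, producing high-degree /
    low-clustering hubs next to low-degree / high-clustering leaves.

    Returns the records together with the full disease -> top-level-module
    map (hubs get module id -1).
    """
    if nesting_depth < 1:
        raise ValueError("nesting_depth must be >= 1")
    if n_hubs < 0:
        raise ValueError("n_hubs must be >= 0")
    codes = config.codes
    base = list(config.baseline_prevalence[c] for c in codes)
    modules = [config.module_assignment[c] for c in codes]

    boost = config.within_module_boost
    if parent_boost is None:
        parent_boost = math.sqrt(boost)

    group_levels: list[np.ndarray] = [np.array(modules)]
    level_boosts: list[float] = [parent_boost if nesting_depth > 1 else boost]
    if nesting_depth > 1:
        # split each module's disease block into contiguous sub-modules
        sub = np.zeros(len(codes), dtype=np.int64)
        next_id = 0
        mod_arr = np.array(modules)
        for m in sorted(set(modules)):
            members = np.flatnonzero(mod_arr == m)
            chunks = np.array_split(members, max(1, min(n_submodules, members.size)))
            for chunk in chunks:
                sub[chunk] = next_id
                next_id += 1
        group_levels.append(sub)
        level_boosts.append(boost)

    hub_mask = None
    if n_hubs > 0:
        if hub_prevalence * hub_boost >= _PROB_CLAMP:
            raise ValueError("hub_prevalence * hub_boost reaches the clamp threshold")
        hub_codes = [f"Z9{i:02d}" for i in range(n_hubs)]
        codes = codes + hub_codes
        base = base + [hub_prevalence] * n_hubs
        modules = modules + [-1] * n_hubs
        hub_mask = np.zeros(len(codes), dtype=bool)
        hub_mask[-n_hubs:] = True
        group_levels = [np.concatenate([g, np.full(n_hubs, g.max() + 1)]) for g in group_levels]

    records = _generate(
        config.n_patients,
        codes,
        np.array(base),
        group_levels,
        level_boosts,
        config.n_visits_range,
        config.seed,
        hub_mask=hub_mask,
        hub_boost=hub_boost,
    )
    return records, dict(zip(codes, modules))


def generate_molecular_tables(
    cohort_modules: Mapping[str, int],
    config: MolecularConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate MalaCards-style disease-gene and KEGG-style pathway-gene tables.

    With coupling ``c``, a disease with ``k`` genes draws ``round(c*k)`` of
    them from its module's shared pool (disjoint pools per module) and the
    rest uniformly from the whole gene universe.  Pathways are uniform
    random gene sets.
    """
    modules = sorted(set(cohort_modules.values()))
    if config.module_pool_size * len(modules) > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {len(modules)} disjoint "
            f"module pools of size {config.module_pool_size}"
        )
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    pools = {
        m: genes[i * config.module_pool_size : (i + 1) * config.module_pool_size]
        for i, m in enumerate(modules)
    }
    lo, hi = config.genes_per_disease_range
    dg_rows: list[tuple[str, str]] = []
    for disease in sorted(cohort_modules):
        k = int(rng.integers(lo, hi + 1))
        n_shared = round(config.coupling * k)
        pool = pools[cohort_modules[disease]]
        shared = rng.choice(pool, size=n_shared, replace=False)
        remaining = np.setdiff1d(genes, shared, assume_unique=False)
        rest = rng.choice(remaining, size=k - n_shared, replace=False)
        for g in sorted(np.concatenate([shared, rest])):
            dg_rows.append((disease, str(g)))
    plo, phi = config.pathway_size_range
    pg_rows: list[tuple[str, str]] = []
    for p in range(config.n_pathways):
        size = int(rng.integers(plo, phi + 1))
        members = rng.choice(genes, size=min(size, config.n_genes), replace=False)
        for g in sorted(members):
            pg_rows.append((f"PW{p:04d}", str(g)))
    disease_gene = pd.DataFrame(dg_rows, columns=["disease", "gene"])
    pathway_gene = pd.DataFrame(pg_rows, columns=["pathway", "gene"])
    return disease_gene, pathway_gene


def generate_trajectory_cohort(
    base: CohortConfig, rule: RiskRuleConfig
) -> list[DiagnosisRecord]:
    """Generate ordered visit trajectories with a planted temporal risk rule.

    Non-target diseases follow the base generator.  The target disease is
    then drawn per visit: with ``trigger_probability`` if any risk disease
    occurred at a strictly earlier visit of the same patient, else with
    ``background_probability``.
    """
    universe = set(base.module_assignment)
    if rule.target_disease not in universe:
        raise ValueError(f"target disease {rule.target_disease} not in the disease universe")
    missing = rule.risk_diseases - universe
    if missing:
        raise ValueError(f"risk diseases outside the disease universe: {sorted(missing)}")

    codes = [c for c in base.codes if c != rule.target_disease]
    code_idx = {c: i for i, c in enumerate(codes)}
    base_p = np.array([base.baseline_prevalence[c] for c in codes])
    modules = np.array([base.module_assignment[c] for c in codes])
    boosted = base.within_module_boost > 1.0

    rng = np.random.default_rng(base.seed)
    lo, hi = base.n_visits_range
    risk_idx = np.array(sorted(code_idx[c] for c in rule.risk_diseases))
    records: list[DiagnosisRecord] = []
    width = len(str(max(base.n_patients - 1, 1)))
    for i in range(base.n_patients):
        n_visits = int(rng.integers(lo, hi + 1))
        if boosted:
            present = _sample_patient_sequential(
                rng, base_p, [modules], [base.within_module_boost], None, 1.0
            )
        else:
            present = np.flatnonzero(rng.random(base_p.size) < base_p)
        visit_sets = _distribute_to_visits(rng, present, n_visits)
        pid = f"P{i:0{width}d}"
        risk_seen = False
        for v, idxs in enumerate(visit_sets):
            p_target = rule.trigger_probability if risk_seen else rule.background_probability
            has_target = rng.random() < p_target
            visit_codes = [codes[j] for j in idxs]
            if has_target:
                visit_codes.append(rule.target_disease)
            for d in sorted(visit_codes):
                records.append(DiagnosisRecord(pid, v, d))
            if np.intersect1d(idxs, risk_idx, assume_unique=False).size > 0:
                risk_seen = True
    return records
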