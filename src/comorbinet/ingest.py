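"""Reading, validation and normalization of diagnosis records and molecular tables.

Canonical record layout is one row per (patient_id, visit_index, icd10_code).
Codes are normalized to at most four significant characters: uppercased,
dot removed, truncated (``I25.1`` -> ``I251``).  Rows with missing codes are
dropped and counted in a quality report.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "visit_index", "icd10_code")

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")


class DiagnosisRecord(NamedTuple):
    """One patient-visit-diagnosis triple; the atomic input unit."""

    patient_id: str
    visit_index: int
    code: str


@dataclass(frozen=True)
class PatientProfile:
    """A patient's disease history: per-visit code sets plus their union."""

    patient_id: str
    visit_sequence: tuple[frozenset[str], ...]
    disease_set: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        union: frozenset[str] = frozenset().union(*self.visit_sequence) if self.visit_sequence else frozenset()
        object.__setattr__(self, "disease_set", union)

    @property
    def n_visits(self) -> int:
        return len(self.visit_sequence)


@dataclass
class QualityReport:
    """Counters accumulated while reading a records file."""

    n_rows_read: int = 0
    n_dropped_missing_code: int = 0
    n_duplicates_collapsed: int = 0
    n_records: int = 0


def normalize_code(raw: str) -> str:
    """Normalize an ICD-10-like code: uppercase, drop dots, keep 4 characters.

    Idempotent: normalizing a normalized code is a no-op.
    """
    return raw.strip().upper().replace(".", "")[:4]


def is_valid_code(code: str) -> bool:
    """True if ``code`` is a normalized letter + 2-3 digit ICD-10-like code."""
    return bool(_CODE_RE.match(code))


def read_records(
    path: str | Path,
    *,
    delimiter: str | None = None,
) -> tuple[list[DiagnosisRecord], QualityReport]:
    """Read diagnosis records from a delimited text file.

    Parameters
    ----------
    path:
        File with columns ``patient_id,visit_index,icd10_code``.
    delimiter:
        Explicit field delimiter; ``None`` auto-detects comma vs tab.

    Returns
    -------
    records, report:
        Normalized, de-duplicated records plus a :class:`QualityReport`.

    Raises
    ------
    ValueError
        If a required column is missing or no rows survive filtering.
    """
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")

    report = QualityReport(n_rows_read=len(df))
    code = df["icd10_code"].str.strip()
    missing = code == ""
    report.n_dropped_missing_code = int(missing.sum())
    df = df.loc[~missing].copy()
    if df.empty:
        raise ValueError(f"no rows with a diagnosis code survive in {path}")

    df["code"] = df["icd10_code"].map(normalize_code)
    df["visit_index"] = df["visit_index"].astype(int)
    n_before = len(df)
    df = df.drop_duplicates(subset=["patient_id", "visit_index", "code"])
    report.n_duplicates_collapsed = n_before - len(df)
    report.n_records = len(df)
    logger.info(
        "read %d rows from %s: %d dropped (missing code), %d duplicates collapsed, %d kept",
        report.n_rows_read, path, report.n_dropped_missing_code,
        report.n_duplicates_collapsed, report.n_records,
    )
    records = [
        DiagnosisRecord(str(p), int(v), str(c))
        for p, v, c in df[["patient_id", "visit_index", "code"]].itertuples(index=False, name=None)
    ]
    return records, report


def write_records(records: Iterable[DiagnosisRecord], path: str | Path, *, delimiter: str = ",") -> None:
    """Write records as delimited text with the canonical three-column header."""
    df = pd.DataFrame(records, columns=["patient_id", "visit_index", "icd10_code"])
    df.to_csv(path, sep=delimiter, index=False)


def build_profiles(records: Sequence[DiagnosisRecord]) -> list[PatientProfile]:
    """Group records into per-patient profiles with visit sets ordered by index.

    One profile per distinct patient_id; per-visit duplicate codes removed.
    Visit sets are ordered by ``visit_index``; gaps are allowed.
    """
    if not records:
        raise ValueError("cannot build profiles from an empty record collection")
    by_patient: dict[str, dict[int, set[str]]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, {}).setdefault(rec.visit_index, set()).add(rec.code)
    profiles = []
    for pid in sorted(by_patient):
        visits = by_patient[pid]
        seq = tuple(frozenset(visits[v]) for v in sorted(visits))
        profiles.append(PatientProfile(patient_id=pid, visit_sequence=seq))
    return profiles


def _read_two_column(path: str | Path, columns: tuple[str, str]) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    df = df.dropna()
    if df.empty:
        raise ValueError(f"empty association table: {path}")
    return df


def link_diseases_to_pathways(
    disease_genes: Mapping[str, frozenset[str]],
    pathway_genes: Mapping[str, frozenset[str]],
    *,
    min_shared_genes: int = 1,
) -> dict[str, frozenset[str]]:
    """Link a disease to every pathway sharing >= ``min_shared_genes`` genes with it."""
    out: dict[str, frozenset[str]] = {}
    for disease, genes in disease_genes.items():
        linked = frozenset(
            pw for pw, pw_genes in pathway_genes.items()
            if len(genes & pw_genes) >= min_shared_genes
        )
        out[disease] = linked
    return out


def read_molecular_tables(
    disease_gene_path: str | Path,
    pathway_gene_path: str | Path,
    *,
    min_shared_genes: int = 1,
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Read disease-gene and pathway-gene tables and derive disease-pathway links.

    Returns ``(disease -> genes, pathway -> genes, disease -> pathways)``
    where the last map links a disease to a pathway iff they share at least
    ``min_shared_genes`` genes.
    """
    dg = _read_two_column(disease_gene_path, ("disease", "gene"))
    pg = _read_two_column(pathway_gene_path, ("pathway", "gene"))
    disease_genes = {d: frozenset(g) for d, g in dg.groupby("disease")["gene"]}
    pathway_genes = {p: frozenset(g) for p, g in pg.groupby("pathway")["gene"]}
    disease_pathways = link_diseases_to_pathways(
        disease_genes, pathway_genes, min_shared_genes=min_shared_genes
    )
    return disease_genes, pathway_genes, disease_pathways
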