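"""Readers/writers for the package's tabular formats and JSON reports.

Count and study tables are TSV, individual records CSV, reports JSON. All
numeric output is serialized at full double precision; rounding happens only
in human-readable summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import GenotypeCountTable, RECORD_COLUMNS, StudySummary

__all__ = [
    "read_count_table",
    "load_reference_tables",
    "read_records",
    "write_records",
    "read_study_table",
    "write_funnel",
    "AnalysisReport",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = "1.0"

COUNT_COLUMNS = (
    "label", "risk_allele", "stratum",
    "cases_0", "cases_1", "cases_2", "controls_0", "controls_1", "controls_2",
)

_STATUS = {"case", "control"}
_SMOKING = {"never", "former", "current"}


def read_count_table(path: Union[str, Path]) -> list[GenotypeCountTable]:
    """Parse a TSV of genotype count tables (one stratum per row)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty count table file") from exc
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    tables = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            cases = tuple(int(row[f"cases_{g}"]) for g in range(3))
            controls = tuple(int(row[f"controls_{g}"]) for g in range(3))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {line}: non-integer count") from exc
        if min(cases + controls) < 0:
            raise ValueError(f"{path} line {line}: negative count")
        tables.append(
            GenotypeCountTable(
                label=str(row["label"]), cases=cases, controls=controls,
                risk_allele=str(row["risk_allele"]), stratum=str(row["stratum"]),
            )
        )
    return tables


def load_reference_tables() -> list[GenotypeCountTable]:
    """The shipped per-stratum genotype count tables for the two 15q25 variants."""
    with resources.as_file(
        resources.files("mediassoc.data") / "reference_counts_15q25.tsv"
    ) as p:
        return read_count_table(p)


def read_records(path: Union[str, Path]) -> pd.DataFrame:
    """Parse an individual-records CSV into the canonical records frame.

    Enums are case-insensitive; never-smokers carrying CPD values are
    flagged with a warning; non-numeric numeric fields raise with the line.
    """
    import warnings

    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = pd.DataFrame()
    out["id"] = df["id"].astype(str)
    out["status"] = df["status"].astype(str).str.strip().str.lower()
    bad = ~out["status"].isin(_STATUS)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path} line {line}: unknown status {df['status'][bad].iloc[0]!r}")
    out["smoking_status"] = df["smoking_status"].astype(str).str.strip().str.lower()
    bad = ~out["smoking_status"].isin(_SMOKING)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(
            f"{path} line {line}: unknown smoking_status "
            f"{df['smoking_status'][bad].iloc[0]!r}"
        )
    for col, kind in (("dosage", int), ("age", float), ("cpd", float),
                      ("duration_years", float)):
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_present = df[col].notna() & (df[col].astype(str).str.strip() != "")
        bad = raw_present & vals.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path} line {line}: non-numeric {col} {df[col][bad].iloc[0]!r}")
        out[col] = vals
    if not out["dosage"].dropna().isin([0, 1, 2]).all():
        raise ValueError(f"{path}: dosage values must be 0, 1 or 2")
    out["sex"] = df["sex"].astype(str).str.strip().str.lower()
    fh = df["family_history"].astype(str).str.strip().str.lower()
    out["family_history"] = fh.map(
        {"true": True, "false": False, "1": True, "0": False}
    ).astype(object)
    inconsistent = (out["smoking_status"] == "never") & out["cpd"].notna()
    if inconsistent.any():
        warnings.warn(
            f"{path}: {int(inconsistent.sum())} never-smoker record(s) carry CPD values",
            stacklevel=2,
        )
    return out[list(RECORD_COLUMNS)]


def write_records(records: pd.DataFrame, path: Union[str, Path]) -> None:
    records[list(RECORD_COLUMNS)].to_csv(path, index=False)


def read_study_table(path: Union[str, Path]) -> list[StudySummary]:
    """Parse a meta-analysis study TSV.

    Accepts either allelic counts (columns label ancestry cases_risk
    cases_nonrisk controls_risk controls_nonrisk) or effect rows (label
    log_or se).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if {"log_or", "se"}.issubset(df.columns):
        return [
            StudySummary(
                label=str(r["label"]),
                ancestry=str(r.get("ancestry", "")),
                log_or=float(r["log_or"]), se_log=float(r["se"]),
            )
            for _, r in df.iterrows()
        ]
    needed = {"label", "cases_risk", "cases_nonrisk", "controls_risk", "controls_nonrisk"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: need {sorted(needed)} or (label, log_or, se)")
    out = []
    for idx, r in df.iterrows():
        ac = tuple(int(r[c]) for c in ("cases_risk", "cases_nonrisk",
                                       "controls_risk", "controls_nonrisk"))
        if min(ac) < 0:
            raise ValueError(f"{path} line {idx + 2}: negative allele count")
        out.append(
            StudySummary(label=str(r["label"]),
                         ancestry=str(r["ancestry"]) if "ancestry" in df.columns else "",
                         allele_counts=ac)
        )
    return out


def write_funnel(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write funnel data (label, log_or, se) as TSV at full precision."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class AnalysisReport:
    """Named result blocks plus run metadata, serialized as ordered JSON."""

    results: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def file_checksum(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(report: AnalysisReport, path: Union[str, Path, None]) -> str:
    """Serialize a report deterministically (sorted keys); returns the JSON."""
    payload = {
        "schema_version": report.schema_version,
        "metadata": _jsonable(report.metadata),
        "results": _jsonable(report.results),
    }
    text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_report(path: Union[str, Path]) -> AnalysisReport:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"report schema version {version!r} does not match {SCHEMA_VERSION!r}"
        )
    return AnalysisReport(
        results=payload["results"], metadata=payload["metadata"],
        schema_version=version,
    )
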