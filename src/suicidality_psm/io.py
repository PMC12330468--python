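"""Plain-text readers/writers for encounter tables and pipeline artifacts.

Encounters travel as CSV (list-valued columns semicolon-joined) or
JSON-lines (list-valued columns as arrays), one row per ED visit.
"""

from __future__ import annotations

import json

import pandas as pd

from .case_definition import ENCOUNTER_COLUMNS, CaseLabel

_LIST_COLUMNS = ("icd10_codes", "note_types")


def _join(values) -> str:
    return ";".join(values)


def _split(text: str) -> tuple[str, ...]:
    return tuple(text.split(";")) if text else ()


def write_encounters(encounters: pd.DataFrame, path, format: str = "csv") -> None:
    df = encounters.loc[:, list(ENCOUNTER_COLUMNS)].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    if format == "csv":
        for col in _LIST_COLUMNS:
            df[col] = df[col].map(_join)
        df.to_csv(path, index=False)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in df.to_dict(orient="records"):
                for col in _LIST_COLUMNS:
                    rec[col] = list(rec[col])
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_encounters(path, format: str = "csv") -> pd.DataFrame:
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if df.empty:
            return pd.DataFrame(columns=list(ENCOUNTER_COLUMNS))
        for col in _LIST_COLUMNS:
            df[col] = df[col].map(_split)
    elif format == "jsonl":
        records = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    records.append(json.loads(line))
        df = pd.DataFrame(records, columns=list(ENCOUNTER_COLUMNS))
        if df.empty:
            return pd.DataFrame(columns=list(ENCOUNTER_COLUMNS))
        for col in _LIST_COLUMNS:
            df[col] = df[col].map(tuple)
    else:
        raise ValueError(f"unknown format {format!r}")
    df["date"] = pd.to_datetime(df["date"])
    df["age_at_visit"] = df["age_at_visit"].astype(int)
    return df.loc[:, list(ENCOUNTER_COLUMNS)]


def write_table(df: pd.DataFrame, path, format: str = "csv") -> None:
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec, default=str) + "\n")  # keep column order
    else:
        raise ValueError(f"unknown format {format!r}")


def read_table(path, format: str = "csv") -> pd.DataFrame:
    if format == "csv":
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    if format == "jsonl":
        records = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    records.append(json.loads(line))
        return pd.DataFrame(records)
    raise ValueError(f"unknown format {format!r}")


def write_labels(labels: dict[str, CaseLabel], path) -> None:
    rows = []
    for pid in sorted(labels):
        lab = labels[pid]
        rows.append(
            {
                "patient_id": pid,
                "is_case": lab.is_case,
                "subtypes": ";".join(sorted(lab.subtypes)),
                "index_date": lab.index_date.isoformat() if lab.index_date else "",
            }
        )
    pd.DataFrame(rows, columns=["patient_id", "is_case", "subtypes", "index_date"]).to_csv(
        path, index=False
    )


def read_labels(path) -> dict[str, CaseLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, CaseLabel] = {}
    for rec in df.to_dict(orient="records"):
        subtypes = frozenset(_split(rec["subtypes"]))
        out[rec["patient_id"]] = CaseLabel(
            is_case=rec["is_case"] == "True",
            subtypes=subtypes,
            index_date=pd.Timestamp(rec["index_date"]).date() if rec["index_date"] else None,
        )
    return out
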