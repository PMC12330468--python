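"""ICD-10 suicidality case definition and study-population selection.

The phenotype is operationalized purely through ICD-10 diagnosis codes,
with three severity subtypes:

``ideation``
    Suicidal ideation, documented only for the present encounter
    (R45.851); ICD-10 has no history-of-ideation code.
``self_harm``
    Self-harm, including the four personal-history codes
    (R45.88, Z91.5, Z91.51, Z91.52).  The full self-harm family runs to
    well over a thousand codes; the packaged default ships the
    personal-history subset and accepts user-supplied extensions
    (including ``*`` prefix patterns) through the codeset file.
``attempt``
    Suicide attempt: T14.91 plus its encounter-type extensions
    (T14.91XA initial, T14.91XD subsequent, T14.91XS sequela).

A patient is a *case* if any of their encounters carries a code matching
any subtype; the *index date* is the first such encounter.  Matching is
exact on normalized tokens (uppercase, dots stripped); prefix semantics
must be requested explicitly with a trailing ``*`` so that broad families
cannot silently inflate the definition.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from collections.abc import Iterable, Mapping
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "SUBTYPE_LABELS",
    "ADOLESCENT_MIN_AGE",
    "ValidationError",
    "CodesetSchemaError",
    "CodeSet",
    "EncounterRecord",
    "CaseLabel",
    "normalize_code",
    "normalize_pattern",
    "classify_encounter",
    "label_patients",
    "select_study_population",
]

#: The three severity subtypes, from least to most severe.
SUBTYPE_LABELS = ("ideation", "self_harm", "attempt")

#: Age (years) at which a patient counts as an adolescent rather than a child.
ADOLESCENT_MIN_AGE = 12


class ValidationError(ValueError):
    """Invalid input to a case-definition operation."""


class CodesetSchemaError(ValidationError):
    """Malformed codeset definition file."""


def normalize_code(raw: str) -> str:
    """Normalize an ICD-10 code token: strip, uppercase, remove dots.

    Idempotent.  Raises :class:`ValidationError` on empty/blank input.

    >>> normalize_code("T14.91XA")
    'T1491XA'
    """
    if not isinstance(raw, str):
        raise ValidationError(f"ICD-10 code must be a nonempty string, got {raw!r}")
    token = raw.upper().replace(".", "").strip()
    if not token:
        raise ValidationError(f"ICD-10 code must be a nonempty string, got {raw!r}")
    return token


def normalize_pattern(raw: str) -> str:
    """Normalize a code pattern; a single trailing ``*`` (prefix match) is kept."""
    token = normalize_code(raw)
    if token == "*" or token.count("*") > 1 or ("*" in token and not token.endswith("*")):
        raise CodesetSchemaError(f"malformed code pattern {raw!r}: '*' may only be a suffix")
    return token


@dataclasses.dataclass(frozen=True)
class CodeSet:
    """Named ICD-10 code collection defining the phenotype and its subtypes.

    ``subtype_map`` maps each subtype label to a set of normalized
    patterns; a pattern ending in ``*`` matches by prefix, otherwise
    matching is exact.  Subtype sets may overlap only when
    ``allow_overlap`` is set (mirroring an explicit flag in the source
    file).
    """

    name: str
    subtype_map: Mapping[str, frozenset[str]]
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        cleaned: dict[str, frozenset[str]] = {}
        for label, patterns in self.subtype_map.items():
            if label not in SUBTYPE_LABELS:
                raise CodesetSchemaError(
                    f"unknown subtype label {label!r}; expected one of {SUBTYPE_LABELS}"
                )
            pats = frozenset(normalize_pattern(p) for p in patterns)
            if not pats:
                raise CodesetSchemaError(f"subtype {label!r} has an empty pattern set")
            cleaned[label] = pats
        if not cleaned:
            raise CodesetSchemaError("codeset defines no subtypes")
        if not self.allow_overlap:
            seen: dict[str, str] = {}
            for label, pats in cleaned.items():
                for p in pats:
                    if p in seen:
                        raise CodesetSchemaError(
                            f"pattern {p!r} appears in both {seen[p]!r} and {label!r} "
                            "(set allow_overlap to permit this)"
                        )
                    seen[p] = label
        object.__setattr__(self, "subtype_map", cleaned)
        exact: dict[str, dict[str, None]] = {}
        prefixes: dict[str, tuple[str, ...]] = {}
        for label, pats in cleaned.items():
            exact[label] = {p: None for p in pats if not p.endswith("*")}
            prefixes[label] = tuple(sorted(p[:-1] for p in pats if p.endswith("*")))
        object.__setattr__(self, "_exact", exact)
        object.__setattr__(self, "_prefixes", prefixes)

    # -- matching ---------------------------------------------------------

    def match_subtypes(self, code: str) -> frozenset[str]:
        """Subtype labels whose patterns match a (normalized) code."""
        hit = []
        for label in self.subtype_map:
            if code in self._exact[label] or any(
                code.startswith(pre) for pre in self._prefixes[label]
            ):
                hit.append(label)
        return frozenset(hit)

    def matches_any(self, code: str) -> bool:
        return bool(self.match_subtypes(code))

    def strip(self, codes: Iterable[str]) -> frozenset[str]:
        """Remove every code matching the definition (leakage guard)."""
        return frozenset(c for c in codes if not self.matches_any(c))

    @property
    def all_patterns(self) -> frozenset[str]:
        out: set[str] = set()
        for pats in self.subtype_map.values():
            out |= pats
        return frozenset(out)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CodeSet":
        try:
            name = payload["name"]
            subtypes = payload["subtypes"]
        except (KeyError, TypeError) as exc:
            raise CodesetSchemaError(f"codeset payload missing required key: {exc}") from exc
        if not isinstance(subtypes, Mapping):
            raise CodesetSchemaError("'subtypes' must be a mapping of label -> code list")
        return cls(
            name=name,
            subtype_map={k: frozenset(v) for k, v in subtypes.items()},
            allow_overlap=bool(payload.get("allow_overlap", False)),
        )

    @classmethod
    def from_file(cls, path) -> "CodeSet":
        with open(path, encoding="utf-8") as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise CodesetSchemaError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        return cls.from_dict(payload)

    @classmethod
    def default(cls) -> "CodeSet":
        """The packaged suicidality case definition."""
        ref = resources.files("suicidality_psm.data") / "suicidality_codeset.json"
        return cls.from_dict(json.loads(ref.read_text(encoding="utf-8")))


@dataclasses.dataclass(frozen=True)
class EncounterRecord:
    """One ED visit: who, when, which diagnosis codes, which note types."""

    patient_id: str
    encounter_id: str
    date: datetime.date
    age_at_visit: int
    sex: str
    race: str
    codes: frozenset[str]
    note_types: frozenset[str]

    def __post_init__(self) -> None:
        if self.age_at_visit < 0:
            raise ValidationError(f"age_at_visit must be >= 0, got {self.age_at_visit}")


@dataclasses.dataclass(frozen=True)
class CaseLabel:
    """Case status of one patient: subtypes ever observed and index date."""

    is_case: bool
    subtypes: frozenset[str]
    index_date: Optional[datetime.date] = None

    def __post_init__(self) -> None:
        if self.is_case != bool(self.subtypes):
            raise ValidationError("is_case must hold exactly when subtypes is nonempty")
        if self.is_case and self.index_date is None:
            raise ValidationError("cases must carry an index_date")


# ---------------------------------------------------------------------------
# Encounter tables
#
# Bulk operations work on a pandas DataFrame with one row per encounter and
# columns: patient_id, encounter_id, date (datetime64), age_at_visit, sex,
# race, icd10_codes (tuple of normalized codes), note_types (tuple of str).
# ---------------------------------------------------------------------------

ENCOUNTER_COLUMNS = (
    "patient_id",
    "encounter_id",
    "date",
    "age_at_visit",
    "sex",
    "race",
    "icd10_codes",
    "note_types",
)


def classify_encounter(encounter, codeset: CodeSet) -> frozenset[str]:
    """Subtype labels matched by an encounter's codes.

    Accepts an :class:`EncounterRecord` or any iterable of normalized
    codes.  Monotone: adding codes can only add subtypes.
    """
    codes = encounter.codes if isinstance(encounter, EncounterRecord) else encounter
    out: set[str] = set()
    for code in codes:
        out |= codeset.match_subtypes(code)
    return frozenset(out)


def _encounter_subtypes_column(encounters: pd.DataFrame, codeset: CodeSet) -> list[frozenset[str]]:
    """Per-row subtype sets, with a per-unique-code match cache."""
    cache: dict[str, frozenset[str]] = {}
    out = []
    for codes in encounters["icd10_codes"]:
        labels: set[str] = set()
        for code in codes:
            hit = cache.get(code)
            if hit is None:
                hit = cache[code] = codeset.match_subtypes(code)
            labels |= hit
        out.append(frozenset(labels))
    return out


def label_patients(encounters: pd.DataFrame, codeset: CodeSet) -> dict[str, CaseLabel]:
    """Patient-level case labels from an encounter table.

    A patient is a case iff any encounter matches; subtypes are the union
    over encounters and the index date is the earliest matching
    encounter's date.
    """
    if encounters.empty:
        return {}
    subtype_col = _encounter_subtypes_column(encounters, codeset)
    agg: dict[str, dict] = {}
    for pid, date, labels in zip(
        encounters["patient_id"], encounters["date"], subtype_col
    ):
        slot = agg.setdefault(pid, {"subtypes": set(), "index": None})
        if labels:
            slot["subtypes"] |= labels
            ts = pd.Timestamp(date)
            if slot["index"] is None or ts < slot["index"]:
                slot["index"] = ts
    out: dict[str, CaseLabel] = {}
    for pid, slot in agg.items():
        if slot["subtypes"]:
            out[pid] = CaseLabel(
                is_case=True,
                subtypes=frozenset(slot["subtypes"]),
                index_date=slot["index"].date(),
            )
        else:
            out[pid] = CaseLabel(is_case=False, subtypes=frozenset())
    return out


def select_study_population(
    encounters: pd.DataFrame,
    age_range: tuple[int, int] = (6, 18),
    date_range: tuple[str, str] | None = None,
    required_note_type: str | None = "ED",
) -> pd.DataFrame:
    """Filter encounters to the study population.

    Keeps rows with ``age_at_visit`` inside ``age_range`` (inclusive on
    both ends), date inside ``date_range`` (inclusive start, exclusive
    end — the half-open convention), and ``required_note_type`` present.
    Idempotent and order-independent.
    """
    lo, hi = age_range
    if lo > hi:
        raise ValidationError(f"inverted age_range {age_range}")
    mask = (encounters["age_at_visit"] >= lo) & (encounters["age_at_visit"] <= hi)
    if date_range is not None:
        start, end = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
        if start >= end:
            raise ValidationError(f"inverted date_range {date_range}")
        dates = pd.to_datetime(encounters["date"])
        mask &= (dates >= start) & (dates < end)
    if required_note_type is not None:
        mask &= encounters["note_types"].map(lambda nts: required_note_type in nts)
    return encounters.loc[mask].copy()
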