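"""Propensity-model feature matrix construction.

A *unit* is one encounter: every case-defining encounter of a case
patient (label 1), and every encounter of a non-case patient (label 0).
Patients never straddle groups — a case patient's non-matching
encounters contribute no unit at all.

Features are aggregated cumulatively per patient: a DSM-5 category or
significant-code indicator is 1 iff the code was observed at any
encounter up to and including the unit encounter (encounters ordered by
(date, encounter_id); the inclusive convention reflects that the
diagnoses motivating a visit are recorded at that visit, and an
exclusive variant is selectable).  Utilization counts (encounters so
far, distinct note types seen) use the same window; demographics come
from the unit encounter itself.  Codes matching the suicidality
codeset are stripped before any feature is computed, so the outcome
cannot leak into the covariates.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from typing import Optional

import numpy as np
import pandas as pd

from .case_definition import (
    ADOLESCENT_MIN_AGE,
    CaseLabel,
    CodeSet,
    ValidationError,
    classify_encounter,
)
from .comorbidity import Dsm5Mapping

__all__ = ["FeatureSpec", "FeatureMatrix", "build_units", "cumulative_features", "assemble_matrix"]


@dataclasses.dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of the feature blocks.

    ``race_levels`` must cover every race value in the data;
    ``reference_race`` is the dropped one-hot level.  ``inclusive``
    selects whether the unit encounter itself contributes to the
    cumulative window.
    """

    dsm5_categories: tuple[str, ...]
    significant_codes: tuple[str, ...]
    race_levels: tuple[str, ...] = ("white", "black", "hispanic", "asian", "other", "unknown")
    reference_race: str = "white"
    inclusive: bool = True
    mapping: Dsm5Mapping = dataclasses.field(default_factory=Dsm5Mapping.default)

    def __post_init__(self) -> None:
        if self.reference_race not in self.race_levels:
            raise ValidationError(
                f"reference_race {self.reference_race!r} not among race_levels"
            )
        if len(set(self.significant_codes)) != len(self.significant_codes):
            raise ValidationError("significant_codes must be unique")
        names = self.feature_names()
        if len(set(names)) != len(names):
            raise ValidationError("feature names collide")

    def validate_against_codeset(self, codeset: CodeSet) -> None:
        bad = [c for c in self.significant_codes if codeset.matches_any(c)]
        if bad:
            raise ValidationError(
                f"suicidality-codeset codes may not be features: {bad}"
            )

    # Deterministic column order: demographics, utilization, DSM-5, codes,
    # each alphabetical within its block.
    def blocks(self) -> dict[str, list[str]]:
        demo = sorted(
            ["age_adolescent", "sex_female"]
            + [f"race_{lvl}" for lvl in self.race_levels if lvl != self.reference_race]
        )
        util = sorted(["prior_encounters", "note_types_seen"])
        dsm5 = sorted(f"dsm5_{c}" for c in self.dsm5_categories)
        codes = sorted(f"code_{c}" for c in self.significant_codes)
        return {"demographics": demo, "utilization": util, "dsm5": dsm5, "codes": codes}

    def feature_names(self) -> list[str]:
        out: list[str] = []
        for block in self.blocks().values():
            out.extend(block)
        return out


@dataclasses.dataclass
class FeatureMatrix:
    """Unit-by-feature design matrix with case/comparator labels.

    ``X`` is indexed by (patient_id, encounter_id); ``y`` shares the
    index (1 = case unit, 0 = comparator unit).
    """

    X: pd.DataFrame
    y: pd.Series
    spec: FeatureSpec

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValidationError("X and y must share an index")
        case_pids = set(self.y[self.y == 1].index.get_level_values(0))
        comp_pids = set(self.y[self.y == 0].index.get_level_values(0))
        if case_pids & comp_pids:
            raise ValidationError("a patient appears in both case and comparator units")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def build_units(
    encounters: pd.DataFrame,
    labels: Mapping[str, CaseLabel],
    codeset: CodeSet,
) -> pd.DataFrame:
    """Unit table: case-defining encounters of cases; all encounters of non-cases."""
    if encounters.empty:
        return pd.DataFrame(columns=["patient_id", "encounter_id", "date", "label"])
    rows = []
    for rec in encounters.itertuples(index=False):
        label = labels.get(rec.patient_id)
        if label is not None and label.is_case:
            if classify_encounter(rec.icd10_codes, codeset):
                rows.append((rec.patient_id, rec.encounter_id, rec.date, 1))
        else:
            rows.append((rec.patient_id, rec.encounter_id, rec.date, 0))
    return pd.DataFrame(rows, columns=["patient_id", "encounter_id", "date", "label"])


def _order_key(encounters: pd.DataFrame) -> pd.DataFrame:
    return encounters.sort_values(["patient_id", "date", "encounter_id"], kind="mergesort")


def cumulative_features(
    unit: Mapping,
    patient_history: pd.DataFrame,
    spec: FeatureSpec,
    codeset: CodeSet,
) -> pd.Series:
    """Feature vector for a single unit, from that patient's encounter history.

    Reference implementation used for auditing; :func:`assemble_matrix`
    computes the same quantities vectorized.  ``unit`` must be one of
    the history rows (matched by encounter_id).
    """
    hist = patient_history
    match = hist["encounter_id"] == unit["encounter_id"]
    if not match.any():
        raise ValidationError(f"unit {unit['encounter_id']!r} not found in patient history")
    unit_row = hist.loc[match].iloc[0]
    key = (pd.Timestamp(unit_row["date"]), unit_row["encounter_id"])
    in_window = [
        (pd.Timestamp(d), e) <= key if spec.inclusive else (pd.Timestamp(d), e) < key
        for d, e in zip(hist["date"], hist["encounter_id"])
    ]
    window = hist.loc[in_window]
    seen_codes: set[str] = set()
    for codes in window["icd10_codes"]:
        seen_codes |= codeset.strip(codes)
    note_types: set[str] = set()
    for nts in window["note_types"]:
        note_types |= set(nts)
    values: dict[str, float] = {}
    values["age_adolescent"] = float(unit_row["age_at_visit"] >= ADOLESCENT_MIN_AGE)
    values["sex_female"] = float(unit_row["sex"] == "female")
    for lvl in spec.race_levels:
        if lvl != spec.reference_race:
            values[f"race_{lvl}"] = float(unit_row["race"] == lvl)
    values["prior_encounters"] = float(len(window))
    values["note_types_seen"] = float(len(note_types))
    seen_cats = {spec.mapping.map_code(c) for c in seen_codes}
    for cat in spec.dsm5_categories:
        values[f"dsm5_{cat}"] = float(cat in seen_cats)
    for code in spec.significant_codes:
        values[f"code_{code}"] = float(code in seen_codes)
    return pd.Series(values).reindex(spec.feature_names())


def assemble_matrix(
    encounters: pd.DataFrame,
    labels: Mapping[str, CaseLabel],
    spec: FeatureSpec,
    codeset: CodeSet,
    drop_constant: bool = False,
) -> FeatureMatrix:
    """Build the full unit-by-feature matrix.

    Row order follows (patient_id, date, encounter_id); permuting the
    input rows changes nothing but that canonical order.
    """
    spec.validate_against_codeset(codeset)
    units = build_units(encounters, labels, codeset)
    if units.empty:
        raise ValidationError("no units to featurize")
    enc = _order_key(encounters).reset_index(drop=True)

    clean_codes = [codeset.strip(codes) for codes in enc["icd10_codes"]]
    unique_codes = sorted(set().union(*clean_codes)) if clean_codes else []
    code_to_cat = {c: spec.mapping.map_code(c) for c in unique_codes}

    indicator_cols: dict[str, np.ndarray] = {}
    for cat in spec.dsm5_categories:
        members = {c for c, k in code_to_cat.items() if k == cat}
        indicator_cols[f"dsm5_{cat}"] = np.fromiter(
            (bool(codes & members) for codes in clean_codes), dtype=np.int8, count=len(enc)
        )
    for code in spec.significant_codes:
        indicator_cols[f"code_{code}"] = np.fromiter(
            (code in codes for codes in clean_codes), dtype=np.int8, count=len(enc)
        )

    frame = pd.DataFrame(indicator_cols, index=enc.index)
    grouped = frame.groupby(enc["patient_id"], sort=False)
    cum = grouped.cummax()
    if not spec.inclusive:
        cum = cum.groupby(enc["patient_id"], sort=False).shift(1, fill_value=0)

    order_in_patient = enc.groupby("patient_id", sort=False).cumcount()
    prior = order_in_patient + 1 if spec.inclusive else order_in_patient

    # Distinct note types seen so far: count first occurrences per patient.
    nt_long = enc["note_types"].explode().dropna()
    new_nt = ~pd.DataFrame(
        {"pid": enc["patient_id"].reindex(nt_long.index), "nt": nt_long}
    ).duplicated()
    new_per_enc = new_nt.groupby(level=0).sum().reindex(enc.index, fill_value=0)
    nts_seen = new_per_enc.groupby(enc["patient_id"], sort=False).cumsum()
    if not spec.inclusive:
        nts_seen = nts_seen.groupby(enc["patient_id"], sort=False).shift(1, fill_value=0)

    demo = pd.DataFrame(index=enc.index)
    demo["age_adolescent"] = (enc["age_at_visit"] >= ADOLESCENT_MIN_AGE).astype(np.int8)
    demo["sex_female"] = (enc["sex"] == "female").astype(np.int8)
    for lvl in spec.race_levels:
        if lvl != spec.reference_race:
            demo[f"race_{lvl}"] = (enc["race"] == lvl).astype(np.int8)

    full = pd.concat(
        [demo, pd.DataFrame({"prior_encounters": prior, "note_types_seen": nts_seen}), cum],
        axis=1,
    )[spec.feature_names()].astype(float)
    full.index = pd.MultiIndex.from_arrays(
        [enc["patient_id"], enc["encounter_id"]], names=["patient_id", "encounter_id"]
    )

    unit_index = pd.MultiIndex.from_arrays(
        [units["patient_id"], units["encounter_id"]], names=["patient_id", "encounter_id"]
    )
    X = full.loc[full.index.isin(unit_index)]
    y = pd.Series(
        units.set_index(["patient_id", "encounter_id"])["label"].reindex(X.index),
        name="label",
    ).astype(np.int8)
    if drop_constant:
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        if constant:
            X = X.drop(columns=constant)
    return FeatureMatrix(X=X, y=y, spec=spec)
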