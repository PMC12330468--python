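"""Stratified conditional-probability comorbidity screen.

The screen quantifies how strongly each ICD-10 diagnosis code B is
associated with the suicidality case definition A through the
conditional probability

    P(A | B) = P(A and B) / P(B)

computed over *patients* (codes co-occurring anywhere in a patient's
study-period encounters), per stratum of age group, sex, and suicidality
subtype.  Candidate codes carried by fewer than ``min_patients``
patients are dropped to damp rare-event noise, the ``top_k``
highest-conditional codes per stratum are retained, each retained code
is tested with a Pearson chi-square test of independence on its 2x2
patient table, and a Bonferroni correction is applied over the whole
family of retained tests in the run.  Codes significant in any stratum
form the risk-factor list consumed by the feature builder.

ICD-10 codes are additionally pooled into DSM-5 disorder categories
(ordered prefix mapping, first match wins) for the category-level
prevalence and conditional-probability summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Iterable, Mapping, Set
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .case_definition import (
    ADOLESCENT_MIN_AGE,
    CaseLabel,
    CodeSet,
    ValidationError,
    normalize_pattern,
)

__all__ = [
    "AGE_GROUPS",
    "StratumSpec",
    "ComorbidityStat",
    "Dsm5Mapping",
    "DegenerateTableError",
    "patient_code_profiles",
    "patient_demographics",
    "conditional_probability",
    "chi_square_2x2",
    "bonferroni",
    "comorbidity_scan",
    "run_scans",
    "default_strata",
    "grid_strata",
    "significant_union",
    "dsm5_category_stats",
]

logger = logging.getLogger(__name__)

AGE_GROUPS = ("children_6_11", "adolescents_12_18", "all")
_SEXES = ("male", "female", "all")
_SUBTYPES = ("ideation", "self_harm", "attempt", "any")


class DegenerateTableError(ValueError):
    """2x2 table with a zero margin; the test statistic is undefined."""


@dataclasses.dataclass(frozen=True)
class StratumSpec:
    """One stratification cell: age group x sex x suicidality subtype."""

    age_group: str = "all"
    sex: str = "all"
    subtype: str = "any"

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"age_group must be one of {AGE_GROUPS}")
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {_SEXES}")
        if self.subtype not in _SUBTYPES:
            raise ValidationError(f"subtype must be one of {_SUBTYPES}")

    def __str__(self) -> str:
        return f"age={self.age_group}|sex={self.sex}|subtype={self.subtype}"


@dataclasses.dataclass(frozen=True)
class ComorbidityStat:
    """Screen result for one candidate code within one stratum."""

    code: str
    stratum: StratumSpec
    n_B: int
    n_AB: int
    p_A_given_B: float
    p_B_given_A: float
    chi2: float
    p_value: float
    p_bonferroni: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0 <= self.n_AB <= self.n_B:
            raise ValidationError(f"require 0 <= n_AB <= n_B, got {self.n_AB}, {self.n_B}")


def patient_code_profiles(encounters: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Union of all ICD-10 codes per patient over the study period."""
    profiles: dict[str, set[str]] = {}
    for pid, codes in zip(encounters["patient_id"], encounters["icd10_codes"]):
        profiles.setdefault(pid, set()).update(codes)
    return {pid: frozenset(codes) for pid, codes in profiles.items()}


def patient_demographics(encounters: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """Per-patient (age_group, sex), taken from the first encounter by date.

    The age group is fixed at study entry so each patient belongs to
    exactly one stratum.
    """
    out: dict[str, tuple[str, str]] = {}
    ordered = encounters.sort_values(["date", "encounter_id"], kind="mergesort")
    for pid, age, sex in zip(
        ordered["patient_id"], ordered["age_at_visit"], ordered["sex"]
    ):
        if pid not in out:
            group = "adolescents_12_18" if age >= ADOLESCENT_MIN_AGE else "children_6_11"
            out[pid] = (group, sex)
    return out


def conditional_probability(n_AB: int, n_B: int) -> float:
    """P(A|B) = n_AB / n_B over patients; undefined (raised) when n_B = 0."""
    if n_B <= 0:
        raise ValidationError("conditional probability undefined for n_B = 0")
    if not 0 <= n_AB <= n_B:
        raise ValidationError(f"require 0 <= n_AB <= n_B, got {n_AB}, {n_B}")
    return n_AB / n_B


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on [[a, b], [c, d]], df=1.

    Closed form N(ad - bc)^2 / (r1 r2 c1 c2); raises
    :class:`DegenerateTableError` on any zero row/column margin.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("cell counts must be nonnegative")
    n = a + b + c + d
    if n == 0:
        raise ValidationError("empty table")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise DegenerateTableError(f"zero margin in table [[{a},{b}],[{c},{d}]]")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(_chi2_dist.sf(stat, df=1))


def bonferroni(p_values: Iterable[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni-adjust p-values: min(1, m * p) with family size m."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValidationError(f"family size m={m} smaller than number of tests {len(ps)}")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in ps]


def _in_stratum(pid: str, stratum: StratumSpec, demographics) -> bool:
    if stratum.age_group == "all" and stratum.sex == "all":
        return True
    if demographics is None:
        raise ValidationError(
            "demographics mapping required for age/sex-restricted strata"
        )
    entry = demographics.get(pid)
    if entry is None:
        return False
    group, sex = entry
    if stratum.age_group != "all" and group != stratum.age_group:
        return False
    if stratum.sex != "all" and sex != stratum.sex:
        return False
    return True


def _is_case_for(label: Optional[CaseLabel], subtype: str) -> bool:
    if label is None or not label.is_case:
        return False
    return subtype == "any" or subtype in label.subtypes


def comorbidity_scan(
    profiles: Mapping[str, Set[str]],
    labels: Mapping[str, CaseLabel],
    stratum: StratumSpec,
    codeset: CodeSet,
    *,
    demographics: Optional[Mapping[str, tuple[str, str]]] = None,
    min_patients: int = 20,
    top_k: Optional[int] = 20,
    alpha: float = 0.05,
    rare_filter_on: str = "n_B",
    family_size: Optional[int] = None,
) -> list[ComorbidityStat]:
    """Screen one stratum; deterministic given its inputs.

    Candidate codes are every observed code outside the suicidality
    codeset; codes with fewer than ``min_patients`` carriers (or case
    carriers, when ``rare_filter_on="n_AB"``) are dropped; the ``top_k``
    codes by P(A|B) are kept (ties broken by larger n_B then
    lexicographic code) and chi-square tested.  ``family_size`` defaults
    to the number of tests performed here; :func:`run_scans` overrides
    it with the run-wide family.
    """
    if rare_filter_on not in ("n_B", "n_AB"):
        raise ValidationError("rare_filter_on must be 'n_B' or 'n_AB'")
    pids = [pid for pid in profiles if _in_stratum(pid, stratum, demographics)]
    if not pids:
        logger.warning("empty stratum %s", stratum)
        return []
    n_total = len(pids)
    case_flags = {pid: _is_case_for(labels.get(pid), stratum.subtype) for pid in pids}
    n_A = sum(case_flags.values())

    carriers: dict[str, int] = {}
    case_carriers: dict[str, int] = {}
    for pid in pids:
        is_case = case_flags[pid]
        for code in profiles[pid]:
            if codeset.matches_any(code):
                continue
            carriers[code] = carriers.get(code, 0) + 1
            if is_case:
                case_carriers[code] = case_carriers.get(code, 0) + 1

    rows = []
    for code, n_B in carriers.items():
        n_AB = case_carriers.get(code, 0)
        count = n_B if rare_filter_on == "n_B" else n_AB
        if count < min_patients:
            continue
        rows.append((code, n_B, n_AB, conditional_probability(n_AB, n_B)))
    # Rank by conditional probability; ties by larger n_B, then code string.
    rows.sort(key=lambda r: (-r[3], -r[1], r[0]))
    if top_k is not None:
        rows = rows[:top_k]

    stats: list[ComorbidityStat] = []
    for code, n_B, n_AB, p_a_b in rows:
        a, b = n_AB, n_A - n_AB
        c, d = n_B - n_AB, n_total - n_A - (n_B - n_AB)
        try:
            chi2, p_value = chi_square_2x2(a, b, c, d)
        except DegenerateTableError:
            chi2, p_value = float("nan"), 1.0
        p_b_a = conditional_probability(n_AB, n_A) if n_A > 0 else 0.0
        stats.append(
            ComorbidityStat(
                code=code,
                stratum=stratum,
                n_B=n_B,
                n_AB=n_AB,
                p_A_given_B=p_a_b,
                p_B_given_A=p_b_a,
                chi2=chi2,
                p_value=p_value,
                p_bonferroni=1.0,
                significant=False,
            )
        )
    m = family_size if family_size is not None else max(1, len(stats))
    return _apply_bonferroni(stats, m, alpha)


def _apply_bonferroni(stats: list[ComorbidityStat], m: int, alpha: float) -> list[ComorbidityStat]:
    adjusted = bonferroni([s.p_value for s in stats], m=m) if stats else []
    out = []
    for s, p_adj in zip(stats, adjusted):
        out.append(
            dataclasses.replace(
                s,
                p_bonferroni=p_adj,
                significant=bool(p_adj < alpha and np.isfinite(s.chi2)),
            )
        )
    return out


def default_strata() -> list[StratumSpec]:
    """Overall plus each marginal stratification (8 cells)."""
    strata = [StratumSpec()]
    strata += [StratumSpec(age_group=g) for g in AGE_GROUPS if g != "all"]
    strata += [StratumSpec(sex=s) for s in _SEXES if s != "all"]
    strata += [StratumSpec(subtype=t) for t in _SUBTYPES if t != "any"]
    return strata


def grid_strata() -> list[StratumSpec]:
    """The full age x sex x subtype cross (36 cells)."""
    return [
        StratumSpec(age_group=g, sex=s, subtype=t)
        for g in AGE_GROUPS
        for s in _SEXES
        for t in _SUBTYPES
    ]


def run_scans(
    profiles: Mapping[str, Set[str]],
    labels: Mapping[str, CaseLabel],
    codeset: CodeSet,
    *,
    demographics: Optional[Mapping[str, tuple[str, str]]] = None,
    strata: Optional[Iterable[StratumSpec]] = None,
    min_patients: int = 20,
    top_k: Optional[int] = 20,
    alpha: float = 0.05,
    rare_filter_on: str = "n_B",
) -> dict[StratumSpec, list[ComorbidityStat]]:
    """Scan several strata with a joint Bonferroni family.

    The family size m is the total number of chi-square tests actually
    performed across all strata in the run, and is recorded implicitly
    in every adjusted p-value (p_bonferroni = min(1, m * p)).
    """
    strata = list(strata) if strata is not None else default_strata()
    raw: dict[StratumSpec, list[ComorbidityStat]] = {}
    for stratum in strata:
        raw[stratum] = comorbidity_scan(
            profiles,
            labels,
            stratum,
            codeset,
            demographics=demographics,
            min_patients=min_patients,
            top_k=top_k,
            alpha=alpha,
            rare_filter_on=rare_filter_on,
        )
    m = sum(sum(1 for s in stats if np.isfinite(s.chi2)) for stats in raw.values())
    m = max(1, m)
    return {stratum: _apply_bonferroni(stats, m, alpha) for stratum, stats in raw.items()}


def significant_union(
    per_stratum_results: Mapping[StratumSpec, Iterable[ComorbidityStat]],
) -> dict[str, list[StratumSpec]]:
    """Codes significant in at least one stratum, with stratum provenance."""
    out: dict[str, list[StratumSpec]] = {}
    for stratum, stats in per_stratum_results.items():
        for s in stats:
            if s.significant:
                out.setdefault(s.code, []).append(stratum)
    return dict(sorted(out.items()))


def stats_to_frame(
    per_stratum_results: Mapping[StratumSpec, Iterable[ComorbidityStat]],
) -> pd.DataFrame:
    """Flatten scan results to one row per (stratum, code)."""
    rows = []
    for stratum, stats in per_stratum_results.items():
        for s in stats:
            rows.append(
                {
                    "age_group": stratum.age_group,
                    "sex": stratum.sex,
                    "subtype": stratum.subtype,
                    "code": s.code,
                    "n_B": s.n_B,
                    "n_AB": s.n_AB,
                    "p_A_given_B": s.p_A_given_B,
                    "p_B_given_A": s.p_B_given_A,
                    "chi2": s.chi2,
                    "p_value": s.p_value,
                    "p_bonferroni": s.p_bonferroni,
                    "significant": s.significant,
                }
            )
    columns = [
        "age_group", "sex", "subtype", "code", "n_B", "n_AB",
        "p_A_given_B", "p_B_given_A", "chi2", "p_value", "p_bonferroni", "significant",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# DSM-5 category pooling
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Dsm5Mapping:
    """Ordered (pattern, category) crosswalk with first-match-wins semantics."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        cleaned = tuple((normalize_pattern(p), str(c)) for p, c in self.entries)
        object.__setattr__(self, "entries", cleaned)
        object.__setattr__(self, "_cache", {})

    @property
    def categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, cat in self.entries:
            seen.setdefault(cat)
        return tuple(seen)

    def map_code(self, code: str) -> Optional[str]:
        if code in self._cache:
            return self._cache[code]
        result = None
        for pattern, category in self.entries:
            if pattern.endswith("*"):
                if code.startswith(pattern[:-1]):
                    result = category
                    break
            elif code == pattern:
                result = category
                break
        self._cache[code] = result
        return result

    @classmethod
    def from_file(cls, path) -> "Dsm5Mapping":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(entries=tuple((e["pattern"], e["category"]) for e in payload))

    @classmethod
    def default(cls) -> "Dsm5Mapping":
        ref = resources.files("suicidality_psm.data") / "dsm5_mapping.json"
        payload = json.loads(ref.read_text(encoding="utf-8"))
        return cls(entries=tuple((e["pattern"], e["category"]) for e in payload))


def dsm5_category_stats(
    profiles: Mapping[str, Set[str]],
    labels: Mapping[str, CaseLabel],
    mapping: Dsm5Mapping,
    codeset: Optional[CodeSet] = None,
) -> tuple[pd.DataFrame, int]:
    """Per-category prevalence and both conditional directions.

    A patient "has" a category when any profile code maps to it
    (suicidality-codeset codes are excluded from mapping when a codeset
    is supplied).  Returns the stats frame and the number of distinct
    unmapped codes encountered.
    """
    pids = list(profiles)
    n_total = len(pids)
    n_A = sum(1 for pid in pids if labels.get(pid) is not None and labels[pid].is_case)
    unmapped: set[str] = set()
    cat_patients: dict[str, int] = {c: 0 for c in mapping.categories}
    cat_cases: dict[str, int] = {c: 0 for c in mapping.categories}
    for pid in pids:
        is_case = labels.get(pid) is not None and labels[pid].is_case
        cats: set[str] = set()
        for code in profiles[pid]:
            if codeset is not None and codeset.matches_any(code):
                continue
            cat = mapping.map_code(code)
            if cat is None:
                unmapped.add(code)
            else:
                cats.add(cat)
        for cat in cats:
            cat_patients[cat] += 1
            if is_case:
                cat_cases[cat] += 1
    if unmapped:
        logger.info("dsm5_category_stats: %d distinct unmapped codes ignored", len(unmapped))
    rows = []
    for cat in mapping.categories:
        n_B, n_AB = cat_patients[cat], cat_cases[cat]
        rows.append(
            {
                "category": cat,
                "n_patients": n_B,
                "n_with_suicidality": n_AB,
                "prevalence": n_B / n_total if n_total else float("nan"),
                "p_suicidality_given_category": (
                    conditional_probability(n_AB, n_B) if n_B > 0 else float("nan")
                ),
                "p_category_given_suicidality": (
                    conditional_probability(n_AB, n_A) if n_A > 0 else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows).set_index("category"), len(unmapped)
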