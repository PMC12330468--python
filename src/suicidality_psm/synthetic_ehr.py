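"""Seeded synthetic pediatric ED cohort generator.

Real encounter data behind this kind of study are protected EHR extracts,
so the package ships a generator whose *statistical structure* matches
what the downstream analysis assumes:

* a latent true-suicidality status per patient, drawn from a logistic
  model over independently planted comorbidity-code flags plus fixed
  female/adolescent skew terms;
* imperfect documentation — a truly suicidal patient receives an ICD-10
  suicidality code only with probability ``documentation_sensitivity``
  (default 0.5, emulating the roughly-half chart-review finding);
* planted comorbidity codes whose population-level conditional
  probabilities of suicidality, P(latent | code), hit configured targets
  exactly in expectation (the coefficients are solved for by
  :func:`solve_coefficients`, an inverse problem, so the planted
  conditionals are interpretable);
* unintentional-injury codes emitted preferentially among latent
  cases, background "noise" codes independent of everything, an ED note
  on every encounter, and 1 + Poisson encounters per patient.

Ground truth (``latent_suicidality``) lives only in the patients table,
never in any code list, so pipeline stages cannot accidentally consume
it.  Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import os
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit as _logit

from .case_definition import (
    ADOLESCENT_MIN_AGE,
    ENCOUNTER_COLUMNS,
    CodeSet,
    normalize_code,
)

__all__ = [
    "ComorbiditySpec",
    "SimConfig",
    "LatentModel",
    "SyntheticDataset",
    "ConfigurationError",
    "ConvergenceError",
    "solve_coefficients",
    "generate_population",
    "write_dataset",
    "read_dataset",
    "null_config",
]


class ConfigurationError(ValueError):
    """Invalid or unsatisfiable simulation configuration."""


class ConvergenceError(RuntimeError):
    """Coefficient solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclasses.dataclass(frozen=True)
class ComorbiditySpec:
    """One planted comorbidity code.

    ``prevalence`` is the marginal P(code) in the population;
    ``target_p_suicidality`` is the population-level P(latent | code)
    the solved latent model must reproduce.
    """

    code: str
    prevalence: float
    target_p_suicidality: float


def _as_specs(specs) -> tuple[ComorbiditySpec, ...]:
    out = []
    for s in specs:
        if isinstance(s, ComorbiditySpec):
            out.append(s)
        else:
            code, prev, target = s
            out.append(ComorbiditySpec(code, float(prev), float(target)))
    return tuple(out)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a six-year pediatric ED extract: ages 6-18, sex and
    race mix per the study table, ~1.5 encounters per patient, a 2.9%
    suicidality baseline among patients with no planted comorbidity,
    planted conditionals in the 32-44% band for the high-risk diagnosis
    groups, and 50% documentation sensitivity.
    """

    n_patients: int = 20_000
    date_range: tuple[str, str] = ("2016-06-01", "2022-06-01")
    age_range: tuple[int, int] = (6, 18)
    p_female: float = 0.483
    race_distribution: tuple[tuple[str, float], ...] = (
        ("white", 0.45),
        ("black", 0.18),
        ("hispanic", 0.18),
        ("asian", 0.05),
        ("other", 0.09),
        ("unknown", 0.05),
    )
    mean_extra_encounters: float = 0.52
    comorbidity_specs: tuple[ComorbiditySpec, ...] = (
        ComorbiditySpec("F329", 0.090, 0.339),   # major depressive disorder, unspecified
        ComorbiditySpec("F319", 0.070, 0.361),   # bipolar disorder, unspecified
        ComorbiditySpec("F648", 0.070, 0.429),   # other gender identity disorders
        ComorbiditySpec("F603", 0.070, 0.442),   # borderline personality disorder
    )
    baseline_p_suicidality: float = 0.029
    documentation_sensitivity: float = 0.5
    female_latent_log_odds: float = 0.8
    adolescent_latent_log_odds: float = 2.1
    unintentional_injury_codes: tuple[str, ...] = (
        "T50901A",  # accidental poisoning, unspecified drug
        "T39011A",  # accidental aspirin poisoning
        "S51812A",  # laceration of forearm
        "S61411A",  # laceration of hand
    )
    p_injury_base: float = 0.02
    injury_latent_rate_ratio: float = 5.0
    background_code_prevalence: tuple[tuple[str, float], ...] = (
        ("J069", 0.15),    # acute upper respiratory infection
        ("R509", 0.10),    # fever, unspecified
        ("S0990XA", 0.08), # head injury, unspecified
        ("K529", 0.06),    # gastroenteritis
        ("R1084", 0.05),   # generalized abdominal pain
        ("J45909", 0.07),  # asthma, uncomplicated
    )
    note_type_distribution: tuple[tuple[str, float], ...] = (
        ("discharge summary", 0.5),
        ("psychiatry", 0.3),
        ("social work", 0.2),
    )
    mean_extra_note_types: float = 0.6
    ed_note_type: str = "ED"
    suicidality_subtype_weights: tuple[tuple[str, float], ...] = (
        ("ideation", 0.86),
        ("self_harm", 0.39),
        ("attempt", 0.067),
    )
    seed: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "comorbidity_specs", _as_specs(self.comorbidity_specs))
        object.__setattr__(
            self,
            "race_distribution",
            tuple((str(r), float(p)) for r, p in self.race_distribution),
        )
        object.__setattr__(
            self,
            "note_type_distribution",
            tuple((str(t), float(p)) for t, p in self.note_type_distribution),
        )
        object.__setattr__(
            self,
            "background_code_prevalence",
            tuple((normalize_code(c), float(p)) for c, p in self.background_code_prevalence),
        )
        object.__setattr__(
            self,
            "unintentional_injury_codes",
            tuple(normalize_code(c) for c in self.unintentional_injury_codes),
        )
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be nonnegative")
        for name in ("p_female", "baseline_p_suicidality", "documentation_sensitivity",
                     "p_injury_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for dist_name in ("race_distribution", "note_type_distribution"):
            probs = [p for _, p in getattr(self, dist_name)]
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{dist_name} must be nonnegative and sum to 1")
        lo, hi = self.age_range
        if lo > hi or lo < 0:
            raise ConfigurationError(f"invalid age_range {self.age_range}")
        if pd.Timestamp(self.date_range[0]) >= pd.Timestamp(self.date_range[1]):
            raise ConfigurationError(f"invalid date_range {self.date_range}")
        if self.mean_extra_encounters < 0 or self.mean_extra_note_types < 0:
            raise ConfigurationError("encounter/note rates must be nonnegative")
        if self.injury_latent_rate_ratio < 0:
            raise ConfigurationError("injury_latent_rate_ratio must be nonnegative")
        codes = [s.code for s in self.comorbidity_specs]
        if len(set(codes)) != len(codes):
            raise ConfigurationError("comorbidity codes must be distinct")
        codeset = CodeSet.default()
        for spec in self.comorbidity_specs:
            if codeset.matches_any(normalize_code(spec.code)):
                raise ConfigurationError(
                    f"comorbidity code {spec.code} belongs to the suicidality codeset"
                )
            if not 0.0 < spec.prevalence < 1.0:
                raise ConfigurationError(
                    f"code {spec.code}: prevalence {spec.prevalence} outside (0, 1)"
                )
            if not 0.0 <= spec.target_p_suicidality <= 1.0:
                raise ConfigurationError(
                    f"code {spec.code}: target {spec.target_p_suicidality} outside [0, 1]"
                )

    @property
    def p_adolescent(self) -> float:
        """Fraction of uniformly drawn integer ages that are adolescent."""
        lo, hi = self.age_range
        ages = np.arange(lo, hi + 1)
        return float(np.mean(ages >= ADOLESCENT_MIN_AGE))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comorbidity_specs"] = [
            [s.code, s.prevalence, s.target_p_suicidality] for s in self.comorbidity_specs
        ]
        return d

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimConfig":
        kwargs = dict(payload)
        for key in ("date_range", "age_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("race_distribution", "note_type_distribution",
                    "background_code_prevalence", "suicidality_subtype_weights"):
            if key in kwargs:
                kwargs[key] = tuple(tuple(item) for item in kwargs[key])
        if "comorbidity_specs" in kwargs:
            kwargs["comorbidity_specs"] = _as_specs(kwargs["comorbidity_specs"])
        if "unintentional_injury_codes" in kwargs:
            kwargs["unintentional_injury_codes"] = tuple(kwargs["unintentional_injury_codes"])
        return cls(**kwargs)


def null_config(**overrides) -> SimConfig:
    """A no-effect configuration for null simulations.

    Every planted conditional equals the baseline and injury codes are
    emitted at the same rate regardless of latent status, so no code is
    truly associated with suicidality.
    """
    base = SimConfig()
    specs = tuple(
        ComorbiditySpec(s.code, s.prevalence, base.baseline_p_suicidality)
        for s in base.comorbidity_specs
    )
    kwargs = dict(comorbidity_specs=specs, injury_latent_rate_ratio=1.0)
    kwargs.update(overrides)
    return dataclasses.replace(base, **kwargs)


@dataclasses.dataclass(frozen=True)
class LatentModel:
    """Solved logistic model for the latent-suicidality indicator."""

    intercept: float
    code_log_odds: tuple[tuple[str, float], ...]
    female_log_odds: float
    adolescent_log_odds: float
    p_female: float
    p_adolescent: float

    def as_mapping(self) -> dict[str, float]:
        return dict(self.code_log_odds)


def _marginal_conditional(
    b0: float,
    beta_target: float,
    other: list[tuple[float, float]],
) -> float:
    """P(latent=1 | focal covariate = 1), marginalizing independent others.

    ``other`` lists (prevalence, coefficient) for every other covariate.
    Exact enumeration over the 2^m support of the others.
    """
    m = len(other)
    if m > 18:
        raise ConfigurationError(
            "coefficient solver enumerates covariate combinations exactly and "
            f"supports at most 18 covariates; got {m + 1}"
        )
    if m == 0:
        return float(expit(b0 + beta_target))
    probs = np.array([p for p, _ in other])
    coefs = np.array([c for _, c in other])
    combos = np.array(list(itertools.product((0, 1), repeat=m)), dtype=float)
    weights = np.prod(np.where(combos == 1, probs, 1.0 - probs), axis=1)
    eta = b0 + beta_target + combos @ coefs
    return float(np.sum(weights * expit(eta)))


_BRACKET = 40.0


def solve_coefficients(config: SimConfig) -> LatentModel:
    """Solve the latent-model coefficients for the planted conditionals.

    The intercept is chosen so that P(latent | no comorbidity flags),
    marginalized over the female/adolescent skew terms, equals
    ``baseline_p_suicidality``; each comorbidity coefficient is then
    solved by 1-D root finding (marginalizing over all other covariates)
    and iterated to joint convergence.  Plug-back error is verified to
    1e-6.
    """
    baseline = config.baseline_p_suicidality
    if not 0.0 < baseline < 1.0:
        raise ConfigurationError(
            f"baseline_p_suicidality={baseline} must lie strictly inside (0, 1)"
        )
    for spec in config.comorbidity_specs:
        if not 0.0 < spec.target_p_suicidality < 1.0:
            raise ConfigurationError(
                f"target P(suicidality | {spec.code}) = {spec.target_p_suicidality} "
                "is not achievable: targets must lie strictly inside (0, 1)"
            )
    demo = [
        (config.p_female, config.female_latent_log_odds),
        (config.p_adolescent, config.adolescent_latent_log_odds),
    ]
    # Intercept depends only on the fixed demographic terms.
    b0 = brentq(
        lambda b: _marginal_conditional(b, 0.0, demo) - baseline,
        -_BRACKET,
        _BRACKET,
        xtol=1e-13,
    )
    specs = config.comorbidity_specs
    m = len(specs)
    betas = np.zeros(m)
    prevs = [s.prevalence for s in specs]
    targets = [s.target_p_suicidality for s in specs]
    max_iter = 200
    for iteration in range(1, max_iter + 1):
        delta = 0.0
        for j in range(m):
            other = demo + [
                (prevs[i], betas[i]) for i in range(m) if i != j
            ]
            new = brentq(
                lambda b: _marginal_conditional(b0, b, other) - targets[j],
                -_BRACKET,
                _BRACKET,
                xtol=1e-13,
            )
            delta = max(delta, abs(new - betas[j]))
            betas[j] = new
        if delta < 1e-12:
            break
    else:
        iteration = max_iter
    residuals = {}
    for j, spec in enumerate(specs):
        other = demo + [(prevs[i], betas[i]) for i in range(m) if i != j]
        residuals[spec.code] = _marginal_conditional(b0, betas[j], other) - targets[j]
    worst = max((abs(r) for r in residuals.values()), default=0.0)
    if worst > 1e-6:
        raise ConvergenceError(
            f"coefficient solver did not converge after {iteration} sweeps "
            f"(worst plug-back residual {worst:.2e})",
            diagnostics={"residuals": residuals, "betas": dict(zip([s.code for s in specs], betas))},
        )
    return LatentModel(
        intercept=float(b0),
        code_log_odds=tuple((spec.code, float(b)) for spec, b in zip(specs, betas)),
        female_log_odds=config.female_latent_log_odds,
        adolescent_log_odds=config.adolescent_latent_log_odds,
        p_female=config.p_female,
        p_adolescent=config.p_adolescent,
    )


@dataclasses.dataclass
class SyntheticDataset:
    """Patients (with ground truth) + encounters + the config that made them."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    config: SimConfig


def _empty_frames(config: SimConfig) -> SyntheticDataset:
    patients = pd.DataFrame(
        columns=["patient_id", "sex", "race", "birth_year",
                 "latent_suicidality", "documented_suicidality"]
        + [f"has_{s.code}" for s in config.comorbidity_specs]
    )
    encounters = pd.DataFrame(columns=list(ENCOUNTER_COLUMNS))
    return SyntheticDataset(patients=patients, encounters=encounters, config=config)


def generate_population(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic cohort (deterministic given the seed)."""
    model = solve_coefficients(config)
    if config.n_patients == 0:
        return _empty_frames(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    codeset = CodeSet.default()

    # --- patient-level draws (fixed order for determinism) ---------------
    female = rng.random(n) < config.p_female
    race_levels, race_p = zip(*config.race_distribution)
    race = rng.choice(np.array(race_levels, dtype=object), size=n, p=np.array(race_p))
    lo, hi = config.age_range
    age0 = rng.integers(lo, hi + 1, size=n)
    adolescent = age0 >= ADOLESCENT_MIN_AGE

    specs = config.comorbidity_specs
    m = len(specs)
    prevs = np.array([s.prevalence for s in specs]) if m else np.zeros((0,))
    flags = rng.random((n, m)) < prevs if m else np.zeros((n, 0), dtype=bool)
    betas = np.array([b for _, b in model.code_log_odds]) if m else np.zeros((0,))
    eta = (
        model.intercept
        + (flags @ betas if m else 0.0)
        + np.where(female, model.female_log_odds, 0.0)
        + np.where(adolescent, model.adolescent_log_odds, 0.0)
    )
    latent = rng.random(n) < expit(eta)
    documented = latent & (rng.random(n) < config.documentation_sensitivity)

    # --- encounters -------------------------------------------------------
    n_enc = 1 + rng.poisson(config.mean_extra_encounters, size=n)
    total = int(n_enc.sum())
    pid_idx = np.repeat(np.arange(n), n_enc)
    start = pd.Timestamp(config.date_range[0])
    end = pd.Timestamp(config.date_range[1])
    n_days = (end - start).days
    day_off = rng.integers(0, n_days, size=total)
    day_off = day_off[np.lexsort((day_off, pid_idx))]  # sort days within patient
    enc_offset = np.concatenate(([0], np.cumsum(n_enc)))
    dates = start + pd.to_timedelta(day_off, unit="D")
    first_day = day_off[enc_offset[:-1]]
    first_year = (start + pd.to_timedelta(first_day, unit="D")).year
    birth_year = np.asarray(first_year) - age0
    age_at_visit = np.asarray(dates.year) - birth_year[pid_idx]

    # --- scatter codes across encounters ---------------------------------
    emit_enc: list[np.ndarray] = []
    emit_code: list[np.ndarray] = []

    def scatter(patient_mask: np.ndarray, codes_for_patients: np.ndarray) -> None:
        idx = np.flatnonzero(patient_mask)
        if idx.size == 0:
            return
        chosen = enc_offset[idx] + rng.integers(0, n_enc[idx])
        emit_enc.append(chosen)
        emit_code.append(np.asarray(codes_for_patients, dtype=object))

    for j, spec in enumerate(specs):
        col = flags[:, j]
        scatter(col, np.full(int(col.sum()), spec.code, dtype=object))

    p_injury = np.where(
        latent,
        min(1.0, config.p_injury_base * config.injury_latent_rate_ratio),
        config.p_injury_base,
    )
    injury_mask = rng.random(n) < p_injury
    if config.unintentional_injury_codes and injury_mask.any():
        picks = rng.integers(0, len(config.unintentional_injury_codes), size=int(injury_mask.sum()))
        scatter(injury_mask, np.array(config.unintentional_injury_codes, dtype=object)[picks])

    for code, p in config.background_code_prevalence:
        mask = rng.random(n) < p
        scatter(mask, np.full(int(mask.sum()), code, dtype=object))

    # Documented suicidality codes: only documented (hence latent) patients
    # ever receive a code from the case-definition codeset.
    got_subtype = np.zeros(n, dtype=bool)
    subtype_codes = {
        label: sorted(p for p in patterns if not p.endswith("*"))
        for label, patterns in codeset.subtype_map.items()
    }
    for label, weight in config.suicidality_subtype_weights:
        mask = documented & (rng.random(n) < weight)
        got_subtype |= mask
        pool = np.array(subtype_codes[label], dtype=object)
        picks = rng.integers(0, len(pool), size=int(mask.sum()))
        scatter(mask, pool[picks])
    fallback = documented & ~got_subtype
    scatter(fallback, np.full(int(fallback.sum()), "R45851", dtype=object))

    codes_per_enc: list[list[str]] = [[] for _ in range(total)]
    if emit_enc:
        for e, c in zip(np.concatenate(emit_enc), np.concatenate(emit_code)):
            codes_per_enc[e].append(c)
    icd10_codes = [tuple(sorted(set(lst))) for lst in codes_per_enc]

    # --- note types -------------------------------------------------------
    extra_counts = rng.poisson(config.mean_extra_note_types, size=total)
    nt_levels, nt_p = zip(*config.note_type_distribution)
    draws = rng.choice(np.array(nt_levels, dtype=object), size=int(extra_counts.sum()),
                       p=np.array(nt_p))
    note_types: list[tuple[str, ...]] = []
    pos = 0
    ed = config.ed_note_type
    for c in extra_counts:
        note_types.append(tuple(sorted({ed, *draws[pos:pos + c]})))
        pos += c

    # --- assemble ---------------------------------------------------------
    pid_width = max(6, len(str(n)))
    eid_width = max(7, len(str(total)))
    patient_ids = np.array([f"P{i:0{pid_width}d}" for i in range(n)], dtype=object)
    encounter_ids = np.array([f"E{i:0{eid_width}d}" for i in range(total)], dtype=object)
    sex = np.where(female, "female", "male").astype(object)

    encounters = pd.DataFrame(
        {
            "patient_id": patient_ids[pid_idx],
            "encounter_id": encounter_ids,
            "date": dates,
            "age_at_visit": age_at_visit.astype(int),
            "sex": sex[pid_idx],
            "race": race[pid_idx],
            "icd10_codes": icd10_codes,
            "note_types": note_types,
        }
    )
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "sex": sex,
            "race": race,
            "birth_year": birth_year.astype(int),
            "latent_suicidality": latent,
            "documented_suicidality": documented,
        }
    )
    for j, spec in enumerate(specs):
        patients[f"has_{spec.code}"] = flags[:, j]
    return SyntheticDataset(patients=patients, encounters=encounters, config=config)


# ---------------------------------------------------------------------------
# Disk round trip.  Ground truth goes to a separate, clearly named file so
# pipeline stages cannot accidentally consume it.
# ---------------------------------------------------------------------------

_ENC_FILE = {"csv": "encounters.csv", "jsonl": "encounters.jsonl"}
_PAT_FILE = {"csv": "patients_ground_truth.csv", "jsonl": "patients_ground_truth.jsonl"}
_CFG_FILE = "sim_config.json"


def write_dataset(dataset: SyntheticDataset, path, format: str = "csv") -> dict[str, str]:
    """Write encounters, ground-truth patients, and config under ``path``.

    Returns the mapping of logical name to file path.  Round-trips
    losslessly through :func:`read_dataset`.
    """
    from . import io as _io

    if format not in _ENC_FILE:
        raise ValueError(f"format must be 'csv' or 'jsonl', got {format!r}")
    try:
        os.makedirs(path, exist_ok=True)
        enc_path = os.path.join(path, _ENC_FILE[format])
        pat_path = os.path.join(path, _PAT_FILE[format])
        cfg_path = os.path.join(path, _CFG_FILE)
        _io.write_encounters(dataset.encounters, enc_path, format=format)
        _io.write_table(dataset.patients, pat_path, format=format)
        with open(cfg_path, "w", encoding="utf-8") as fh:
            json.dump(dataset.config.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"failed writing dataset under {path!r}: {exc}") from exc
    return {"encounters": enc_path, "patients": pat_path, "config": cfg_path}


def read_dataset(path, format: str = "csv") -> SyntheticDataset:
    """Inverse of :func:`write_dataset`."""
    from . import io as _io

    if format not in _ENC_FILE:
        raise ValueError(f"format must be 'csv' or 'jsonl', got {format!r}")
    try:
        encounters = _io.read_encounters(os.path.join(path, _ENC_FILE[format]), format=format)
        patients = _io.read_table(os.path.join(path, _PAT_FILE[format]), format=format)
        with open(os.path.join(path, _CFG_FILE), encoding="utf-8") as fh:
            config = SimConfig.from_dict(json.load(fh))
    except OSError as exc:
        raise OSError(f"failed reading dataset under {path!r}: {exc}") from exc
    bool_cols = ["latent_suicidality", "documented_suicidality"] + [
        c for c in patients.columns if c.startswith("has_")
    ]
    for col in bool_cols:
        if col in patients.columns and len(patients):
            patients[col] = patients[col].map(
                lambda v: v if isinstance(v, (bool, np.bool_)) else str(v) == "True"
            )
    if "birth_year" in patients.columns and len(patients):
        patients["birth_year"] = patients["birth_year"].astype(int)
    return SyntheticDataset(patients=patients, encounters=encounters, config=config)
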