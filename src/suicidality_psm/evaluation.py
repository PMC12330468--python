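"""Cohort tables, enrichment statistics, and the end-to-end pipeline.

The headline check of the whole approach: among matched comparators —
every one of them *undiagnosed* by construction — how much higher is
the true-suicidality rate than in the comparator pool at large?  With
real data that comparison requires chart review; here the synthetic
generator's latent labels (or a user-supplied adjudication file) play
the ground-truth role, and the difference is quantified with a pooled
two-proportion z-test and a Woolf odds-ratio interval.
"""

from __future__ import annotations

import dataclasses
import decimal
import hashlib
import json
import logging
import os
from collections.abc import Iterable, Mapping
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io as _io
from .case_definition import (
    ADOLESCENT_MIN_AGE,
    CaseLabel,
    CodeSet,
    SUBTYPE_LABELS,
    ValidationError,
    label_patients,
    select_study_population,
)
from .comorbidity import (
    Dsm5Mapping,
    default_strata,
    dsm5_category_stats,
    grid_strata,
    patient_code_profiles,
    patient_demographics,
    run_scans,
    significant_union,
    stats_to_frame,
)
from .features import FeatureSpec, assemble_matrix
from .psm import balance_report, fit_propensity, match_nearest, score_distribution
from .synthetic_ehr import SimConfig, generate_population, write_dataset

__all__ = [
    "CohortTable",
    "EnrichmentReport",
    "PipelineConfig",
    "PipelineResult",
    "summarize_cohort",
    "two_proportion_z",
    "odds_ratio_ci",
    "enrichment_report",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_ROWS = ("total", "age_6_11", "age_12_18", "male", "female")
_COLS = ("all", "any_suicidality", "ideation", "self_harm", "attempt")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, as printed in clinical tables."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclasses.dataclass
class CohortTable:
    """Encounter-level cohort characteristics table.

    Rows: total, the two age groups, and the two sexes; columns: all
    encounters, encounters matching any suicidality subtype, and each
    subtype.  Percentages are within-column shares of the column total.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(index=list(_ROWS), columns=list(_COLS))
        if self.counts.isna().any().any():
            raise ValidationError(f"counts must cover rows {_ROWS} and columns {_COLS}")
        self.counts = self.counts.astype(int)

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping[str, int]]) -> "CohortTable":
        return cls(pd.DataFrame(counts).T)

    def validate(self) -> None:
        """Internal-consistency checks.

        Age rows must sum exactly to the total per column.  Sex rows may
        sum to slightly less than the total (encounters with unreported
        sex are simply absent from both rows), never more.
        """
        for col in _COLS:
            total = self.counts.loc["total", col]
            ages = self.counts.loc["age_6_11", col] + self.counts.loc["age_12_18", col]
            sexes = self.counts.loc["male", col] + self.counts.loc["female", col]
            if ages != total:
                raise ValidationError(f"column {col!r}: age rows sum {ages} != total {total}")
            if sexes > total:
                raise ValidationError(f"column {col!r}: sex rows sum {sexes} > total {total}")

    def percentages(self, decimals: int = 1) -> pd.DataFrame:
        """Within-column percentages, half-up rounded for display."""
        out = {}
        for col in _COLS:
            total = self.counts.loc["total", col]
            out[col] = {
                row: round_half_up(100.0 * self.counts.loc[row, col] / total, decimals)
                if total
                else 0.0
                for row in _ROWS
            }
        return pd.DataFrame(out).reindex(index=list(_ROWS))

    def case_share_percent(self, decimals: int = 1) -> float:
        """Suicidality encounters as a share of all encounters."""
        total = self.counts.loc["total", "all"]
        if total == 0:
            return 0.0
        return round_half_up(100.0 * self.counts.loc["total", "any_suicidality"] / total, decimals)


def summarize_cohort(
    encounters: pd.DataFrame,
    labels: Mapping[str, CaseLabel],
    codeset: CodeSet,
) -> CohortTable:
    """Encounter-level Table-1-style counts."""
    from .case_definition import classify_encounter

    counts = pd.DataFrame(0, index=list(_ROWS), columns=list(_COLS))
    for rec in encounters.itertuples(index=False):
        subtypes = classify_encounter(rec.icd10_codes, codeset)
        cols = ["all"]
        if subtypes:
            cols.append("any_suicidality")
            cols.extend(s for s in SUBTYPE_LABELS if s in subtypes)
        age_row = "age_12_18" if rec.age_at_visit >= ADOLESCENT_MIN_AGE else "age_6_11"
        rows = ["total", age_row]
        if rec.sex in ("male", "female"):
            rows.append(rec.sex)
        for col in cols:
            for row in rows:
                counts.loc[row, col] += 1
    table = CohortTable(counts)
    table.validate()
    return table


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-sided two-proportion z-test.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion; degenerate pooled proportions (0 or 1) raise.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 == 0 or n2 == 0:
        raise ValidationError("need 0 <= x <= n with n > 0 in both groups")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValidationError("degenerate pooled proportion; z-test undefined")
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return float(z), float(2.0 * norm.sf(abs(z)))


@dataclasses.dataclass(frozen=True)
class OddsRatioCI:
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValidationError("CI must bracket the odds ratio")


def odds_ratio_ci(a: int, b: int, c: int, d: int, conf_level: float = 0.95) -> OddsRatioCI:
    """OR = ad/bc with the Woolf (log) interval.

    A 0.5 continuity correction is applied to every cell (and flagged)
    when any cell is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("cell counts must be nonnegative")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (v + 0.5 for v in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    zcrit = norm.isf((1.0 - conf_level) / 2.0)
    return OddsRatioCI(
        odds_ratio=float(or_),
        ci_low=float(or_ * np.exp(-zcrit * se)),
        ci_high=float(or_ * np.exp(zcrit * se)),
        continuity_corrected=corrected,
    )


@dataclasses.dataclass
class EnrichmentReport:
    """Matched-comparator prevalence vs the comparator-pool reference."""

    prevalence_matched: float
    prevalence_reference: float
    n_matched: int
    n_reference: int
    z: float
    p_value: float
    odds_ratio: OddsRatioCI
    excluded_units: tuple[str, ...] = ()

    @property
    def enrichment_ratio(self) -> float:
        if self.prevalence_reference == 0:
            return float("inf")
        return self.prevalence_matched / self.prevalence_reference


def enrichment_report(
    matched_pairs,
    ground_truth: Mapping[str, bool],
    reference_patients: Iterable[str],
) -> EnrichmentReport:
    """Compare true-suicidality prevalence: matched comparators vs reference pool.

    ``ground_truth`` maps patient id to true status (synthetic latent
    labels or chart-review adjudication).  ``reference_patients`` is the
    comparator pool the matched group is drawn from; matched patients
    are excluded from the reference side of the 2x2 so the two groups
    are disjoint.  Matched patients missing from ``ground_truth`` are
    excluded and reported.
    """
    matched_patients: dict[str, None] = {}
    for _, comp_unit, _ in matched_pairs.pairs:
        matched_patients.setdefault(comp_unit[0])
    excluded = tuple(p for p in matched_patients if p not in ground_truth)
    if excluded:
        logger.warning("enrichment_report: %d matched patients lack truth labels", len(excluded))
    matched = [p for p in matched_patients if p in ground_truth]
    reference = [
        p for p in dict.fromkeys(reference_patients)
        if p in ground_truth and p not in matched_patients
    ]
    if not matched or not reference:
        raise ValidationError("both matched and reference groups must be nonempty")
    x1 = sum(bool(ground_truth[p]) for p in matched)
    x2 = sum(bool(ground_truth[p]) for p in reference)
    n1, n2 = len(matched), len(reference)
    z, p = two_proportion_z(x1, n1, x2, n2)
    or_ci = odds_ratio_ci(x1, n1 - x1, x2, n2 - x2)
    return EnrichmentReport(
        prevalence_matched=x1 / n1,
        prevalence_reference=x2 / n2,
        n_matched=n1,
        n_reference=n2,
        z=z,
        p_value=p,
        odds_ratio=or_ci,
        excluded_units=excluded,
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """One self-contained run: simulate -> label -> screen -> match -> evaluate."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    age_range: tuple[int, int] = (6, 18)
    required_note_type: str = "ED"
    strata: str = "default"  # "default" (marginal cells) or "grid" (full cross)
    min_patients: int = 20
    top_k: int = 20
    alpha: float = 0.05
    k_neighbors: int = 1
    caliper: Optional[float] = None
    regularization: str = "l2"
    lam: float = 1e-6

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PipelineConfig":
        kwargs = dict(payload)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig.from_dict(kwargs["sim"])
        if "age_range" in kwargs:
            kwargs["age_range"] = tuple(kwargs["age_range"])
        return cls(**kwargs)


@dataclasses.dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the reproducibility manifest."""

    dataset: object
    labels: dict
    cohort_table: CohortTable
    scan_results: dict
    significant_codes: dict
    dsm5_stats: pd.DataFrame
    matrix: object
    propensity: object
    pairs: object
    balance: object
    scores: dict
    enrichment: EnrichmentReport
    manifest: dict


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> PipelineResult:
    """Execute the full analysis on a synthetic cohort.

    Stages: simulate, select the study population, apply the case
    definition, screen comorbidities, pool DSM-5 categories, build the
    feature matrix, fit the propensity model, match, and evaluate
    enrichment against the generator's latent truth.  When ``out_dir``
    is given every intermediate artifact plus a JSON manifest (config
    hash, seed, declared-assumption knobs) is written for exact reruns.
    """
    stage = "simulate"
    try:
        dataset = generate_population(config.sim)
        stage = "select-population"
        study = select_study_population(
            dataset.encounters,
            age_range=config.age_range,
            date_range=config.sim.date_range,
            required_note_type=config.required_note_type,
        )
        stage = "define-cases"
        codeset = CodeSet.default()
        labels = label_patients(study, codeset)
        cohort_table = summarize_cohort(study, labels, codeset)
        stage = "comorbidity"
        profiles = patient_code_profiles(study)
        demographics = patient_demographics(study)
        strata = grid_strata() if config.strata == "grid" else default_strata()
        scan_results = run_scans(
            profiles,
            labels,
            codeset,
            demographics=demographics,
            strata=strata,
            min_patients=config.min_patients,
            top_k=config.top_k,
            alpha=config.alpha,
        )
        significant = significant_union(scan_results)
        mapping = Dsm5Mapping.default()
        dsm5_stats, _ = dsm5_category_stats(profiles, labels, mapping, codeset=codeset)
        stage = "featurize"
        spec = FeatureSpec(
            dsm5_categories=mapping.categories,
            significant_codes=tuple(significant),
            mapping=mapping,
        )
        matrix = assemble_matrix(study, labels, spec, codeset)
        stage = "match"
        propensity = fit_propensity(
            matrix, regularization=config.regularization, lam=config.lam
        )
        pairs = match_nearest(
            propensity, matrix.y, k=config.k_neighbors, caliper=config.caliper
        )
        balance = balance_report(matrix, pairs)
        scores = score_distribution(propensity, matrix.y, pairs=pairs)
        stage = "evaluate"
        truth = dict(
            zip(dataset.patients["patient_id"], dataset.patients["latent_suicidality"])
        )
        comparator_pool = matrix.y[matrix.y == 0].index.get_level_values(0).unique()
        enrichment = enrichment_report(pairs, truth, comparator_pool)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "package_version": __version__,
        "declared_assumptions": {
            "match_order": "descending logit",
            "k": config.k_neighbors,
            "caliper": config.caliper,
            "replacement": False,
            "rare_filter_on": "n_B",
            "cumulative_window": "inclusive of unit encounter",
        },
        "n_patients": int(len(dataset.patients)),
        "n_encounters": int(len(dataset.encounters)),
        "n_study_encounters": int(len(study)),
        "n_case_units": int((matrix.y == 1).sum()),
        "n_comparator_units": int((matrix.y == 0).sum()),
        "n_significant_codes": len(significant),
    }
    result = PipelineResult(
        dataset=dataset,
        labels=labels,
        cohort_table=cohort_table,
        scan_results=scan_results,
        significant_codes=significant,
        dsm5_stats=dsm5_stats,
        matrix=matrix,
        propensity=propensity,
        pairs=pairs,
        balance=balance,
        scores=scores,
        enrichment=enrichment,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_artifacts(result, out_dir)
    return result


def _write_artifacts(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_dataset(result.dataset, os.path.join(out_dir, "dataset"))
    _io.write_labels(result.labels, os.path.join(out_dir, "labels.csv"))
    result.cohort_table.counts.to_csv(os.path.join(out_dir, "cohort_counts.csv"))
    result.cohort_table.percentages().to_csv(os.path.join(out_dir, "cohort_percentages.csv"))
    stats_to_frame(result.scan_results).to_csv(
        os.path.join(out_dir, "comorbidity_stats.csv"), index=False
    )
    with open(os.path.join(out_dir, "significant_codes.json"), "w", encoding="utf-8") as fh:
        json.dump(
            {code: [str(s) for s in strata] for code, strata in result.significant_codes.items()},
            fh,
            indent=2,
        )
    result.dsm5_stats.to_csv(os.path.join(out_dir, "dsm5_stats.csv"))
    matrix_out = result.matrix.X.copy()
    matrix_out["label"] = result.matrix.y
    matrix_out.to_csv(os.path.join(out_dir, "matrix.csv"))
    pd.DataFrame(
        [
            {"case_patient": c[0], "case_encounter": c[1],
             "comparator_patient": m[0], "comparator_encounter": m[1], "distance": d}
            for c, m, d in result.pairs.pairs
        ]
    ).to_csv(os.path.join(out_dir, "pairs.csv"), index=False)
    result.balance.table.to_csv(os.path.join(out_dir, "balance.csv"))
    with open(os.path.join(out_dir, "scores.json"), "w", encoding="utf-8") as fh:
        json.dump(result.scores, fh, indent=2)
    enr = result.enrichment
    with open(os.path.join(out_dir, "enrichment.json"), "w", encoding="utf-8") as fh:
        json.dump(
            {
                "prevalence_matched": enr.prevalence_matched,
                "prevalence_reference": enr.prevalence_reference,
                "n_matched": enr.n_matched,
                "n_reference": enr.n_reference,
                "enrichment_ratio": enr.enrichment_ratio,
                "z": enr.z,
                "p_value": enr.p_value,
                "odds_ratio": enr.odds_ratio.odds_ratio,
                "or_ci": [enr.odds_ratio.ci_low, enr.odds_ratio.ci_high],
            },
            fh,
            indent=2,
        )
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
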