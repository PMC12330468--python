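# Methods

## The problem and the approach

ICD-10-based phenotyping of pediatric suicidality undercounts: coding
practice varies, stigma suppresses disclosure, and many truly suicidal
patients presenting to the ED carry only "adjacent" diagnoses —
depression, borderline personality, gender dysphoria, supposedly
accidental poisonings and lacerations.  The analysis here treats those
adjacent diagnoses as a signal.  Diagnosed cases define a comorbidity
profile; undiagnosed patients who share that profile are found by
propensity-score matching; and the enrichment of true suicidality in
the matched, undiagnosed group measures how much the code-based
definition misses.

## Case definition

A patient is a case when any encounter carries a code from the
suicidality codeset.  The three subtypes (ideation, self-harm, attempt)
grade severity and stratify the comorbidity screen.  Matching is exact
on normalized tokens (uppercase, dots removed); a pattern carries an
explicit trailing `*` for prefix matching.  Implicit prefix semantics
were rejected because the full self-harm family exceeds a thousand
codes and a silent prefix rule would inflate the phenotype
unpredictably.  The packaged codeset ships the printed subset
(ideation R45.851; personal-history self-harm R45.88, Z91.5, Z91.51,
Z91.52; attempt T14.91/XA/XD/XS) and accepts user extensions through
the codeset file; no claim is made to reproduce the full published
self-harm enumeration.  History-of codes count toward case status at
any encounter.  The study window is half-open `[start, end)` and the
age filter `[6, 18]` is inclusive on both ends — the sources state
boundaries without semantics, so a documented convention is adopted.

## Comorbidity screen

The unit of co-occurrence is the **patient** over the whole study
period, not the encounter.  For candidate code B (any observed code
outside the suicidality codeset), P(A|B) = n_AB / n_B over patients.
Codes with n_B < 20 carriers are dropped to damp rare-event noise
(`rare_filter_on="n_AB"` implements the alternative reading of the
filter on case-carriers).  The top 20 codes per stratum by P(A|B)
(ties: larger n_B, then code string — determinism) are selection-first,
then chi-square tested on the 2×2 patient table (Pearson, df 1, no
continuity correction).  The Bonferroni family size m is the total
number of tests actually performed in the run, recorded implicitly in
every adjusted p-value; the sources do not state m, and counting the
performed tests is the auditable choice.  Degenerate tables (a zero
margin, e.g. a stratum with no cases) yield chi2 = NaN, p = 1, never
significant.  Default strata are the marginal cells (overall, each age
group, each sex, each subtype — 8 scans); the full 2×2×4 cross is
available as `grid_strata()`.

The DSM-5 crosswalk pools ICD-10 F-chapter ranges into disorder
categories (ordered prefix list, first match wins, user-replaceable
JSON).  It is a pragmatic grouping for pooling sparse codes, not a
clinically validated mapping.

## Feature matrix and propensity model

Units: every case-defining encounter of a case patient (label 1) and
every encounter of a non-case patient (label 0); patients never
straddle groups.  Features are aggregated cumulatively per patient,
**inclusive** of the unit encounter — the diagnoses motivating a visit
are recorded at that visit; the exclusive variant is a flag.  Encounter
order is (date, encounter_id), a deterministic tie rule for same-day
visits.  Race is one-hot with "unknown" as its own level (EHR
missingness is informative) and a documented reference level dropped.
Suicidality codes are stripped before any feature computation; a test
verifies that removing them from the input changes no feature value.

The propensity model is logistic regression of the label on the
features.  Default fitting adds an L2 penalty λ/2·‖w‖², λ = 1e-6,
intercept unpenalized — one-hot EHR designs are separation-prone, and
this approximates the MLE to ~1e-3 while keeping the fit defined; exact
MLE (`regularization="none"`) is retained and raises on perfect
separation.  Constant columns are dropped with coefficient 0.

## Matching, balance, and enrichment

Greedy nearest-neighbor matching on the logit of the score: cases in
descending logit order, each taking its k (default 1) nearest unused
comparators by absolute logit difference, distance ties resolved toward
the smaller comparator unit id, without replacement, no caliper by
default (a caliper in logit units is available).  Greedy rather than
optimal matching mirrors common PSM-package behavior; k, caliper,
replacement, and ordering are undeclared in the sources, so the
defaults are surfaced in the run manifest as declared assumptions.

Balance: SMD = (mean_case − mean_comparator)/pooled SD per feature,
before (all units) and after (matched units); zero pooled SD with equal
means gives SMD 0, with unequal means ∞ (flagged).  Enrichment compares
true-suicidality prevalence among matched comparator patients against
the remaining comparator pool with a pooled two-proportion z-test and a
Woolf OR interval (0.5 continuity correction when a cell is zero,
flagged; critical value Φ⁻¹(0.975), which keeps the interval identical
to standard reference implementations).  The enrichment interface takes
a reference patient pool rather than a bare prevalence because the
z-test and OR need counts; ground truth is a patient→bool mapping —
synthetic latent labels by default, or a chart-review adjudication file.

## Synthetic cohort: what it emulates

`SimConfig` defaults describe a six-year pediatric ED extract:
20,000 patients (the scale at which the whole pipeline runs in seconds
and every planted parameter is estimable), ages 6–18 uniform, 48.3%
female, ~1.52 encounters per patient (1 + Poisson(0.52)), an ED note on
every encounter.  Per patient, in order: demographics; independent
comorbidity-code flags; a latent true-suicidality Bernoulli from a
logistic model over the flags plus fixed female (+0.8) and adolescent
(+2.1) log-odds terms (back-computed from the published case-mix so
cases skew female and adolescent); a documented indicator = latent AND
Bernoulli(0.5); code scatter across encounters.  Latent status lives
only in the ground-truth patients table.

The inverse problem — choose coefficients so that the population-level
P(latent | code_j) equals each target exactly — is solved by per-
coefficient Brent root finding with exact enumeration over the other
covariates' 2^m support, iterated to joint convergence (cap 200 sweeps,
plug-back residual verified to 1e-6; ≤18 covariates supported by
enumeration).  The intercept depends only on the fixed demographic
terms: P(latent | no flags) = 0.029, the published encounter-level case
share, used here as the no-comorbidity baseline.

Planted conditionals use the published category values (0.339, 0.361,
0.429, 0.442) for depressive, bipolar, gender-dysphoria, and
personality-disorder codes.  Their marginal prevalences (7–9%) are set
at the scale of the *common* psychiatric categories rather than the
rare tail the two highest conditionals actually occupy in clinic data:
with ~20,000 patients each planted code needs >1,000 carriers for its
conditional to be estimable to ±0.03, and identifiability was
prioritized over marginal realism.  Two consequences, stated plainly:
documented case prevalence in the synthetic cohort is ~3.8% of
encounters (above the published 2.9%, which enters as the baseline
parameter instead), and recovering a 43% conditional for a code this
common says nothing about estimating it for a 0.3%-prevalence category
in real data.  Unintentional-injury codes are emitted at 2% baseline
with a 5× rate ratio among latent cases, emulating miscoded self-harm;
background codes (URI, fever, head injury, …) are independent noise.

Other simplifications: comorbidity flags are mutually independent given
nothing; no longitudinal progression; no code-frequency realism beyond
the planted and background codes; encounter counts are Poisson because
the true dispersion is unreported (config-exposed).  Passing tests
therefore demonstrate that the *machinery* is correct and that the
matching mechanism concentrates true cases when the signal exists —
not that real EHR comorbidity structure carries this much signal.

## Null calibration and test scale

The null configuration sets every planted conditional equal to the
baseline and the injury rate ratio to 1, so no code is associated with
the latent status.  Family-wise error of the Bonferroni-corrected scan
is estimated over 200 seeded replicates at the default cohort size
(20,000 patients): at that size the rarest retained code has ~5
expected case-carriers, inside the chi-square approximation's validity
range, whereas much smaller replicates push expected cell counts below
1 and the Pearson statistic becomes anti-conservative in the deep tail
— a property of the test, not of the implementation.

## Numerical and degenerate-input choices

Brent brackets ±40 on the log-odds scale; solver tolerance 1e-13,
plug-back 1e-6.  Logistic convergence: lbfgs tol 1e-10 (penalized) or
Newton tol 1e-8 (MLE), iteration caps reported with a `converged` flag.
`logit` is defined only on the open interval (0, 1).  Empty strata
return empty results with a warning; a zero-patient simulation yields
valid header-only files; conditional probability with n_B = 0 raises
rather than silently returning 0.  All randomness flows from a single
`numpy` Generator seeded by `SimConfig.seed`; identical configs produce
byte-identical output files.
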