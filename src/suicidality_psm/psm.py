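"""Propensity-score estimation, logit-space nearest-neighbor matching, and
balance diagnostics.

The propensity score e(x) = P(case | x) is estimated by logistic
regression of the case/comparator label on the feature matrix.  Matching
operates on the logit ln(e/(1-e)): cases are processed in descending
logit order and each is paired greedily with its k nearest unused
comparators by |logit difference| (ties broken by comparator unit id),
optionally within a caliper, without replacement by default.  Covariate
balance is summarized by the standardized mean difference

    SMD = (mean_case - mean_comparator) / pooled SD,

computed before (all units) and after (matched units) matching;
|SMD| < 0.1 is the conventional balance yardstick.
"""

from __future__ import annotations

import bisect
import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .case_definition import ValidationError
from .features import FeatureMatrix

__all__ = [
    "SeparationError",
    "PropensityResult",
    "MatchedPairs",
    "BalanceReport",
    "logit",
    "fit_propensity",
    "match_nearest",
    "balance_report",
    "score_distribution",
]


class SeparationError(RuntimeError):
    """Perfect separation under unpenalized fitting; use l2 regularization."""


def logit(p):
    """ln(p / (1 - p)); strictly increasing; raises for p outside (0, 1)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValidationError("logit defined only on the open interval (0, 1)")
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclasses.dataclass
class PropensityResult:
    """Fitted scores/logits plus the model that produced them."""

    scores: pd.Series
    logits: pd.Series
    coefficients: pd.Series  # includes 'intercept'
    converged: bool
    n_iterations: int
    regularization: str
    dropped_features: tuple[str, ...] = ()


def fit_propensity(
    matrix: FeatureMatrix,
    regularization: str = "l2",
    lam: float = 1e-6,
    max_iter: int = 500,
) -> PropensityResult:
    """Fit the propensity model.

    ``regularization="none"`` is exact maximum likelihood (statsmodels
    Newton; perfect separation raises :class:`SeparationError`);
    ``"l2"`` adds a ridge penalty lam/2 * ||w||^2 on the slopes
    (intercept unpenalized), the default lam = 1e-6 approximating the
    MLE while stabilizing near-separation.  Constant feature columns
    carry no information and are dropped (coefficient 0) before fitting.
    Deterministic for fixed input and settings.
    """
    X, y = matrix.X, matrix.y
    if y.nunique() < 2:
        raise ValidationError("need at least one case and one comparator unit")
    constant = tuple(c for c in X.columns if X[c].nunique() <= 1)
    Xf = X.drop(columns=list(constant))
    if regularization == "none":
        design = sm.add_constant(Xf.to_numpy(float), has_constant="add")
        model = sm.Logit(y.to_numpy(float), design)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                fit = model.fit(method="newton", maxiter=max_iter, tol=1e-8, disp=False)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(
                "perfect separation under unpenalized logistic regression; "
                "refit with regularization='l2'"
            ) from exc
        params = np.asarray(fit.params, dtype=float)
        intercept, coefs = params[0], params[1:]
        converged = bool(fit.mle_retvals.get("converged", True))
        n_iter = int(fit.mle_retvals.get("iterations", 0))
    elif regularization == "l2":
        if lam <= 0:
            raise ValidationError("l2 regularization requires lam > 0")
        clf = LogisticRegression(
            C=1.0 / lam, solver="lbfgs", tol=1e-10, max_iter=max_iter
        )
        clf.fit(Xf.to_numpy(float), y.to_numpy())
        intercept = float(clf.intercept_[0])
        coefs = clf.coef_[0]
        n_iter = int(np.max(clf.n_iter_))
        converged = n_iter < max_iter
    else:
        raise ValidationError(f"regularization must be 'none' or 'l2', got {regularization!r}")

    coefficients = pd.Series(0.0, index=["intercept", *X.columns])
    coefficients["intercept"] = intercept
    coefficients[list(Xf.columns)] = coefs
    eta = intercept + X.to_numpy(float) @ coefficients[list(X.columns)].to_numpy()
    logits = pd.Series(eta, index=X.index, name="logit")
    scores = pd.Series(expit(eta), index=X.index, name="score")
    return PropensityResult(
        scores=scores,
        logits=logits,
        coefficients=coefficients,
        converged=converged,
        n_iterations=n_iter,
        regularization=regularization,
        dropped_features=constant,
    )


@dataclasses.dataclass
class MatchedPairs:
    """Greedy matching output: (case, comparator, |logit distance|) triples."""

    pairs: list[tuple[tuple, tuple, float]]
    unmatched_cases: tuple[tuple, ...]
    k: int
    caliper: Optional[float]
    replacement: bool

    def __post_init__(self) -> None:
        if not self.replacement:
            comps = [c for _, c, _ in self.pairs]
            if len(comps) != len(set(comps)):
                raise ValidationError("comparator reused in matching without replacement")
        if self.caliper is not None and any(d > self.caliper for _, _, d in self.pairs):
            raise ValidationError("pair distance exceeds caliper")

    @property
    def matched_cases(self) -> list[tuple]:
        seen: dict[tuple, None] = {}
        for case, _, _ in self.pairs:
            seen.setdefault(case)
        return list(seen)

    @property
    def matched_comparators(self) -> list[tuple]:
        return [c for _, c, _ in self.pairs]


def match_nearest(
    result: PropensityResult,
    labels: pd.Series,
    k: int = 1,
    caliper: Optional[float] = None,
    replacement: bool = False,
    seed: Optional[int] = None,
) -> MatchedPairs:
    """Greedy k-nearest-neighbor matching in logit space.

    Cases are processed in descending logit order (ties by unit id);
    each takes its k nearest unused comparators by |logit difference|,
    distance ties resolved toward the smaller comparator unit id.  With
    a caliper, neighbors beyond it are discarded and a case with no
    neighbor inside it is recorded unmatched.  Deterministic; the
    ``seed`` parameter is accepted for interface stability but unused
    because every tie-break is explicit.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if caliper is not None and caliper < 0:
        raise ValidationError("caliper must be nonnegative")
    logits = result.logits
    case_ids = sorted(
        (uid for uid in logits.index if labels.loc[uid] == 1),
        key=lambda u: (-logits.loc[u], u),
    )
    comp = sorted(
        ((float(logits.loc[uid]), uid) for uid in logits.index if labels.loc[uid] == 0),
    )
    comp_logits = [v for v, _ in comp]
    comp_ids = [u for _, u in comp]
    n = len(comp)
    alive = np.ones(n, dtype=bool)
    nxt = np.arange(1, n + 1)
    prv = np.arange(-1, n - 1)

    def kill(i: int) -> None:
        alive[i] = False
        left, right = prv[i], nxt[i]
        if left >= 0:
            nxt[left] = right
        if right < n:
            prv[right] = left

    pairs: list[tuple[tuple, tuple, float]] = []
    unmatched: list[tuple] = []
    for case in case_ids:
        target = float(logits.loc[case])
        pos = bisect.bisect_left(comp_logits, target)
        case_taken: set[int] = set()  # within-case exclusion when matching with replacement

        def usable(i: int) -> bool:
            return alive[i] and i not in case_taken

        taken = 0
        for _ in range(k):
            right = pos
            while right < n and not usable(right):
                right = nxt[right] if not alive[right] else right + 1
            left = pos - 1
            while left >= 0 and not usable(left):
                left = prv[left] if not alive[left] else left - 1
            d_left = target - comp_logits[left] if left >= 0 else np.inf
            d_right = comp_logits[right] - target if right < n else np.inf
            dist = min(d_left, d_right)
            if not np.isfinite(dist):
                break
            if caliper is not None and dist > caliper:
                break
            # Equal-distance candidates are contiguous runs of equal logits on
            # either side; the smallest comparator unit id among them wins.
            candidates = []
            i = left
            while i >= 0 and target - comp_logits[i] == dist:
                if usable(i):
                    candidates.append(i)
                i -= 1
            j = right
            while j < n and comp_logits[j] - target == dist:
                if usable(j):
                    candidates.append(j)
                j += 1
            choice = min(candidates, key=lambda t: comp_ids[t])
            pairs.append((case, comp_ids[choice], float(dist)))
            taken += 1
            case_taken.add(choice)
            if not replacement:
                kill(choice)
        if taken == 0:
            unmatched.append(case)
    return MatchedPairs(
        pairs=pairs,
        unmatched_cases=tuple(unmatched),
        k=k,
        caliper=caliper,
        replacement=replacement,
    )


@dataclasses.dataclass
class BalanceReport:
    """Per-feature SMD before/after matching plus summary magnitudes."""

    table: pd.DataFrame  # index feature, columns smd_before, smd_after
    max_abs_before: float
    max_abs_after: float
    mean_abs_before: float
    mean_abs_after: float


def _smd(case_vals: np.ndarray, comp_vals: np.ndarray) -> float:
    m1, m0 = case_vals.mean(), comp_vals.mean()
    v1 = case_vals.var(ddof=1) if len(case_vals) > 1 else 0.0
    v0 = comp_vals.var(ddof=1) if len(comp_vals) > 1 else 0.0
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0.0:
        return 0.0 if m1 == m0 else float("inf")
    return float((m1 - m0) / pooled)


def balance_report(matrix: FeatureMatrix, pairs: MatchedPairs) -> BalanceReport:
    """SMD per feature before (all units) and after (matched units) matching."""
    if not pairs.pairs:
        raise ValidationError("no matched pairs to report balance for")
    X, y = matrix.X, matrix.y
    case_all = X[y == 1]
    comp_all = X[y == 0]
    case_after = X.loc[pairs.matched_cases]
    comp_after = X.loc[pairs.matched_comparators]
    rows = {}
    for col in X.columns:
        rows[col] = {
            "smd_before": _smd(case_all[col].to_numpy(), comp_all[col].to_numpy()),
            "smd_after": _smd(case_after[col].to_numpy(), comp_after[col].to_numpy()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    finite = table.replace([np.inf, -np.inf], np.nan).abs()
    return BalanceReport(
        table=table,
        max_abs_before=float(table["smd_before"].abs().max()),
        max_abs_after=float(table["smd_after"].abs().max()),
        mean_abs_before=float(finite["smd_before"].mean()),
        mean_abs_after=float(finite["smd_after"].mean()),
    )


def score_distribution(
    result: PropensityResult,
    labels: pd.Series,
    pairs: Optional[MatchedPairs] = None,
    bin_width: float = 0.05,
    thresholds: tuple[float, float] = (0.5, 0.9),
) -> dict:
    """Binned score counts per group plus tail fractions.

    Reports, for cases and comparators (and matched comparators when
    ``pairs`` is given), histogram counts over [0, 1] and the fractions
    of units with score >= the upper threshold and < the lower one —
    the shape summaries used to judge whether matching moved the
    comparator distribution onto the cases'.
    """
    lo_thr, hi_thr = sorted(thresholds)
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 12)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    groups = {
        "cases": result.scores[labels == 1],
        "comparators": result.scores[labels == 0],
    }
    if pairs is not None:
        groups["matched_comparators"] = result.scores.loc[pairs.matched_comparators]
        groups["matched_cases"] = result.scores.loc[pairs.matched_cases]
    out: dict = {"bin_edges": edges.tolist(), "groups": {}}
    for name, scores in groups.items():
        vals = scores.to_numpy()
        counts, _ = np.histogram(vals, bins=edges)
        n = len(vals)
        out["groups"][name] = {
            "n": int(n),
            "counts": counts.tolist(),
            f"frac_ge_{hi_thr}": float((vals >= hi_thr).mean()) if n else float("nan"),
            f"frac_lt_{lo_thr}": float((vals < lo_thr).mean()) if n else float("nan"),
        }
    return out
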