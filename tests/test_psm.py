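"""Propensity fitting, logit-space matching, balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import greedy_match_oracle
from suicidality_psm.case_definition import ValidationError
from suicidality_psm.comorbidity import Dsm5Mapping
from suicidality_psm.features import FeatureMatrix, FeatureSpec
from suicidality_psm.psm import (
    MatchedPairs,
    PropensityResult,
    SeparationError,
    _smd,
    balance_report,
    fit_propensity,
    logit,
    match_nearest,
    score_distribution,
)


def make_matrix(X: np.ndarray, y: np.ndarray, names=None) -> FeatureMatrix:
    names = names or [f"f{i}" for i in range(X.shape[1])]
    index = pd.MultiIndex.from_tuples(
        [(f"p{'c' if lbl else 'n'}{i}", f"e{i}") for i, lbl in enumerate(y)],
        names=["patient_id", "encounter_id"],
    )
    spec = FeatureSpec(dsm5_categories=(), significant_codes=(), mapping=Dsm5Mapping.default())
    return FeatureMatrix(
        X=pd.DataFrame(X, index=index, columns=names, dtype=float),
        y=pd.Series(y, index=index, name="label", dtype="int8"),
        spec=spec,
    )


def result_from_logits(logits: dict) -> PropensityResult:
    index = pd.MultiIndex.from_tuples(list(logits), names=["patient_id", "encounter_id"])
    lg = pd.Series([logits[k] for k in logits], index=index, dtype=float)
    scores = 1 / (1 + np.exp(-lg))
    return PropensityResult(
        scores=scores, logits=lg, coefficients=pd.Series({"intercept": 0.0}),
        converged=True, n_iterations=1, regularization="none",
    )


class TestLogit:
    def test_half_is_zero(self):
        assert logit(0.5) == 0.0

    def test_known_value(self):
        assert logit(0.9) == pytest.approx(np.log(9.0), abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_symmetry(self, p):
        assert logit(1 - p) == pytest.approx(-logit(p), abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_domain(self, bad):
        with pytest.raises(ValidationError):
            logit(bad)


class TestFitPropensity:
    def test_intercept_only_scores_equal_case_fraction(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        fm = make_matrix(np.zeros((10, 2)), y)
        res = fit_propensity(fm, regularization="none")
        assert np.allclose(res.scores.to_numpy(), 0.2, atol=1e-8)
        assert res.dropped_features == ("f0", "f1")

    def test_saturated_single_binary_covariate(self):
        # Within each covariate level the fitted score must equal the
        # empirical case fraction (saturated logistic model).
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=float)[:, None]
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        fm = make_matrix(x, y)
        res = fit_propensity(fm, regularization="none")
        scores = res.scores.to_numpy()
        assert np.allclose(scores[x[:, 0] == 1], 0.75, atol=1e-6)
        assert np.allclose(scores[x[:, 0] == 0], 1 / 6, atol=1e-6)

    def test_l2_approximates_mle(self):
        rng = np.random.default_rng(3)
        X = rng.random((400, 3))
        eta = -1.0 + X @ np.array([1.0, -0.5, 0.25])
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(int)
        fm = make_matrix(X, y)
        mle = fit_propensity(fm, regularization="none")
        ridge = fit_propensity(fm, regularization="l2", lam=1e-6)
        assert np.allclose(
            mle.coefficients.to_numpy(), ridge.coefficients.to_numpy(), atol=1e-3
        )
        assert ridge.converged

    def test_score_logit_bijection(self):
        rng = np.random.default_rng(8)
        X = rng.random((100, 2))
        y = (rng.random(100) < 0.3).astype(int)
        res = fit_propensity(make_matrix(X, y))
        assert np.allclose(
            res.logits.to_numpy(),
            np.log(res.scores / (1 - res.scores)),
            atol=1e-12,
        )

    def test_perfect_separation_advises_l2(self):
        x = np.array([1, 1, 1, 0, 0, 0], dtype=float)[:, None]
        y = np.array([1, 1, 1, 0, 0, 0])
        fm = make_matrix(x, y)
        with pytest.raises(SeparationError, match="l2"):
            fit_propensity(fm, regularization="none")
        res = fit_propensity(fm, regularization="l2", lam=1e-2)
        assert res.converged

    def test_single_class_rejected(self):
        fm = make_matrix(np.random.default_rng(0).random((5, 1)), np.zeros(5, dtype=int))
        with pytest.raises(ValidationError):
            fit_propensity(fm)


class TestMatchNearest:
    def test_nearest_comparator_chosen(self):
        res = result_from_logits(
            {("c", "e0"): 0.0, ("n1", "e1"): -0.1, ("n2", "e2"): 0.5}
        )
        labels = pd.Series([1, 0, 0], index=res.logits.index)
        pairs = match_nearest(res, labels)
        assert pairs.pairs == [(("c", "e0"), ("n1", "e1"), pytest.approx(0.1))]

    def test_caliper_leaves_case_unmatched(self):
        res = result_from_logits({("c", "e0"): 0.0, ("n1", "e1"): 0.1})
        labels = pd.Series([1, 0], index=res.logits.index)
        pairs = match_nearest(res, labels, caliper=0.05)
        assert pairs.pairs == [] and pairs.unmatched_cases == ((("c", "e0")),)

    def test_k_two_takes_two_nearest(self):
        res = result_from_logits(
            {("c", "e0"): 0.0, ("n1", "e1"): 0.2, ("n2", "e2"): -0.3, ("n3", "e3"): 1.0}
        )
        labels = pd.Series([1, 0, 0, 0], index=res.logits.index)
        pairs = match_nearest(res, labels, k=2)
        assert [p[1] for p in pairs.pairs] == [("n1", "e1"), ("n2", "e2")]

    def test_without_replacement_is_injective(self):
        rng = np.random.default_rng(5)
        logits = {(f"c{i}", f"e{i}"): float(rng.normal()) for i in range(10)}
        logits.update({(f"n{i}", f"x{i}"): float(rng.normal()) for i in range(15)})
        res = result_from_logits(logits)
        labels = pd.Series(
            [1 if k[0].startswith("c") else 0 for k in res.logits.index],
            index=res.logits.index,
        )
        pairs = match_nearest(res, labels, k=1)
        comps = [c for _, c, _ in pairs.pairs]
        assert len(comps) == len(set(comps))

    def test_with_replacement_allows_reuse(self):
        res = result_from_logits(
            {("c1", "e1"): 0.0, ("c2", "e2"): 0.01, ("n", "x"): 0.0}
        )
        labels = pd.Series([1, 1, 0], index=res.logits.index)
        pairs = match_nearest(res, labels, replacement=True)
        assert [c for _, c, _ in pairs.pairs] == [("n", "x"), ("n", "x")]

    @pytest.mark.parametrize("k,caliper", [(1, None), (2, None), (1, 0.3), (3, 0.5)])
    def test_matches_bruteforce_oracle(self, k, caliper):
        rng = np.random.default_rng(1234 + k)
        for trial in range(30):
            n_case = int(rng.integers(1, 8))
            n_comp = int(rng.integers(1, 13))
            case_units = [
                ((f"c{i}", f"e{i}"), float(np.round(rng.normal(), 3)))
                for i in range(n_case)
            ]
            comp_units = [
                ((f"n{i}", f"x{i}"), float(np.round(rng.normal(), 3)))
                for i in range(n_comp)
            ]
            logits = dict(case_units) | dict(comp_units)
            res = result_from_logits(logits)
            labels = pd.Series(
                [1 if u[0].startswith("c") else 0 for u in res.logits.index],
                index=res.logits.index,
            )
            got = match_nearest(res, labels, k=k, caliper=caliper)
            want_pairs, want_unmatched = greedy_match_oracle(
                case_units, comp_units, k=k, caliper=caliper
            )
            assert [(c, m) for c, m, _ in got.pairs] == [(c, m) for c, m, _ in want_pairs]
            assert list(got.unmatched_cases) == want_unmatched
            for (_, _, d1), (_, _, d2) in zip(got.pairs, want_pairs):
                assert d1 == pytest.approx(d2, abs=1e-12)

    def test_invalid_parameters(self):
        res = result_from_logits({("c", "e"): 0.0, ("n", "x"): 0.1})
        labels = pd.Series([1, 0], index=res.logits.index)
        with pytest.raises(ValidationError):
            match_nearest(res, labels, k=0)
        with pytest.raises(ValidationError):
            match_nearest(res, labels, caliper=-1.0)


class TestBalance:
    def test_identical_groups_zero_smd(self):
        assert _smd(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])) == 0.0

    def test_known_smd(self):
        case = np.array([0.5, 1.0, 1.5])
        comp = np.array([-0.5, 0.0, 0.5])
        assert _smd(case, comp) == pytest.approx(2.0)

    def test_zero_pooled_sd(self):
        assert _smd(np.array([1.0, 1.0]), np.array([1.0, 1.0])) == 0.0
        assert _smd(np.array([1.0, 1.0]), np.array([0.0, 0.0])) == np.inf

    def test_report_shrinks_smd_for_matched_subset(self):
        # one binary feature fully driving case status; matching on it
        # must equalize the matched groups.
        X = np.array([[1.0]] * 5 + [[1.0]] * 6 + [[0.0]] * 12)
        y = np.array([1] * 5 + [0] * 18)
        fm = make_matrix(X, y)
        res = fit_propensity(fm, regularization="l2", lam=1e-4)
        pairs = match_nearest(res, fm.y)
        rep = balance_report(fm, pairs)
        assert rep.max_abs_after <= rep.max_abs_before
        assert rep.table.loc["f0", "smd_after"] == pytest.approx(0.0, abs=1e-12)


class TestScoreDistribution:
    def test_counts_conserved_and_thresholds(self):
        res = result_from_logits(
            {(f"c{i}", f"e{i}"): 3.0 for i in range(4)}
            | {(f"n{i}", f"x{i}"): -3.0 for i in range(6)}
        )
        labels = pd.Series(
            [1 if k[0].startswith("c") else 0 for k in res.logits.index],
            index=res.logits.index,
        )
        dist = score_distribution(res, labels)
        cases = dist["groups"]["cases"]
        comps = dist["groups"]["comparators"]
        assert sum(cases["counts"]) == cases["n"] == 4
        assert sum(comps["counts"]) == comps["n"] == 6
        assert cases["frac_ge_0.9"] == 1.0
        assert comps["frac_lt_0.5"] == 1.0
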