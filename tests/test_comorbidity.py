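"""Comorbidity screen: counts, tests, correction, DSM-5 pooling."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from conftest import make_encounters
from oracles import cooccurrence_tally_oracle
from suicidality_psm.case_definition import CaseLabel, ValidationError
from suicidality_psm.comorbidity import (
    DegenerateTableError,
    Dsm5Mapping,
    StratumSpec,
    bonferroni,
    chi_square_2x2,
    comorbidity_scan,
    conditional_probability,
    dsm5_category_stats,
    patient_code_profiles,
    run_scans,
    significant_union,
)


def case(date="2020-01-01"):
    return CaseLabel(True, frozenset({"ideation"}), pd.Timestamp(date).date())


def noncase():
    return CaseLabel(False, frozenset())


class TestProfiles:
    def test_union_across_encounters(self):
        enc = make_encounters(
            [
                ("p1", "e1", "2020-01-01", 10, "male", "white", ("F329",), ("ED",)),
                ("p1", "e2", "2020-02-01", 10, "male", "white", ("F329", "F419"), ("ED",)),
                ("p2", "e3", "2020-03-01", 11, "male", "white", (), ("ED",)),
            ]
        )
        profiles = patient_code_profiles(enc)
        assert profiles["p1"] == {"F329", "F419"}
        assert profiles["p2"] == frozenset()
        assert "p3" not in profiles

    def test_matches_bruteforce_union(self):
        rng = np.random.default_rng(5)
        pool = ["F329", "F419", "J069", "K529", "R509"]
        rows = []
        for i in range(5):
            for j in range(rng.integers(1, 4)):
                codes = tuple(rng.choice(pool, size=rng.integers(0, 4), replace=False))
                rows.append((f"p{i}", f"e{i}{j}", "2020-01-01", 9, "male", "white", codes, ("ED",)))
        enc = make_encounters(rows)
        profiles = patient_code_profiles(enc)
        for pid in enc["patient_id"].unique():
            expected = set().union(*enc.loc[enc["patient_id"] == pid, "icd10_codes"])
            assert profiles[pid] == expected


class TestConditionalProbability:
    @pytest.mark.parametrize("n_ab,n_b,expected", [(0, 10, 0.0), (20, 20, 1.0), (5, 20, 0.25)])
    def test_examples(self, n_ab, n_b, expected):
        assert conditional_probability(n_ab, n_b) == expected

    def test_zero_denominator_raises(self):
        with pytest.raises(ValidationError):
            conditional_probability(0, 0)


class TestChiSquare:
    def test_closed_form_example(self):
        chi2, _ = chi_square_2x2(10, 20, 30, 40)
        assert chi2 == pytest.approx(100 * (10 * 40 - 20 * 30) ** 2 / (30 * 70 * 40 * 60))
        assert chi2 == pytest.approx(0.7937, abs=1e-4)

    def test_independent_table(self):
        chi2, p = chi_square_2x2(10, 10, 10, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 200, size=4)
            chi2, p = chi_square_2x2(a, b, c, d)
            ref = chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-9, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            chi_square_2x2(0, 0, 5, 5)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], m=55) == [pytest.approx(0.55)]
        assert bonferroni([0.5], m=10) == [1.0]

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(0)
        ps = rng.random(50).tolist()
        adj = bonferroni(ps, m=80)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)
        # order of non-capped entries preserved
        order = np.argsort(ps)
        assert list(np.argsort(np.take(adj, order), kind="stable")) == sorted(
            range(len(ps))
        )

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni([0.1, 0.2], m=1)


class TestScan:
    def _toy(self):
        profiles = {
            "p1": frozenset({"F329"}),
            "p2": frozenset({"F329", "J069"}),
            "p3": frozenset({"F329"}),
            "p4": frozenset({"J069"}),
            "p5": frozenset({"K529"}),
            "p6": frozenset({"K529"}),
            "p7": frozenset({"K529"}),
            "p8": frozenset(),
        }
        labels = {p: case() for p in ("p1", "p2", "p5")}
        labels.update({p: noncase() for p in ("p3", "p4", "p6", "p7", "p8")})
        return profiles, labels

    def test_hand_counted_toy_corpus(self, codeset):
        profiles, labels = self._toy()
        stats = comorbidity_scan(
            profiles, labels, StratumSpec(), codeset, min_patients=1, top_k=None
        )
        by_code = {s.code: s for s in stats}
        f = by_code["F329"]
        assert (f.n_B, f.n_AB) == (3, 2)
        assert f.p_A_given_B == pytest.approx(2 / 3)
        assert f.p_B_given_A == pytest.approx(2 / 3)
        # table a=2 b=1 c=1 d=4 -> chi2 = 8*(8-1)^2/(3*5*3*5)
        assert f.chi2 == pytest.approx(8 * 49 / 225)
        assert [s.code for s in stats] == ["F329", "J069", "K529"]  # ranked by P(A|B)
        assert all(s.p_bonferroni == pytest.approx(min(1.0, 3 * s.p_value)) for s in stats)

    def test_bayes_consistency(self, codeset):
        profiles, labels = self._toy()
        n = len(profiles)
        n_a = sum(1 for v in labels.values() if v.is_case)
        stats = comorbidity_scan(
            profiles, labels, StratumSpec(), codeset, min_patients=1, top_k=None
        )
        for s in stats:
            lhs = Fraction(s.n_AB, s.n_B) * Fraction(s.n_B, n)
            rhs = Fraction(s.n_AB, n_a) * Fraction(n_a, n)
            assert lhs == rhs

    def test_zero_case_stratum(self, codeset):
        profiles, _ = self._toy()
        labels = {p: noncase() for p in profiles}
        stats = comorbidity_scan(
            profiles, labels, StratumSpec(), codeset, min_patients=1, top_k=None
        )
        assert stats and all(s.p_A_given_B == 0.0 for s in stats)
        assert not any(s.significant for s in stats)

    def test_min_patients_filter_and_top_k(self, codeset):
        profiles, labels = self._toy()
        stats = comorbidity_scan(
            profiles, labels, StratumSpec(), codeset, min_patients=3, top_k=1
        )
        assert [s.code for s in stats] == ["F329"]  # J069 filtered (n_B=2), top-1 keeps best

    def test_suicidality_codes_never_candidates(self, codeset):
        profiles = {"p1": frozenset({"R45851", "F329"}), "p2": frozenset({"F329"})}
        labels = {"p1": case(), "p2": noncase()}
        stats = comorbidity_scan(
            profiles, labels, StratumSpec(), codeset, min_patients=1, top_k=None
        )
        assert {s.code for s in stats} == {"F329"}

    def test_matches_bruteforce_tally(self, codeset):
        rng = np.random.default_rng(17)
        pool = ["F329", "F419", "J069", "K529", "R509", "F503"]
        profiles = {
            f"p{i}": frozenset(rng.choice(pool, size=rng.integers(0, 5), replace=False))
            for i in range(50)
        }
        labels = {
            pid: case() if rng.random() < 0.3 else noncase() for pid in profiles
        }
        case_ids = {p for p, l in labels.items() if l.is_case}
        oracle = cooccurrence_tally_oracle(profiles, case_ids)
        stats = comorbidity_scan(
            profiles, labels, StratumSpec(), codeset, min_patients=1, top_k=None
        )
        assert {s.code for s in stats} == set(oracle)
        for s in stats:
            assert (s.n_B, s.n_AB) == oracle[s.code]

    def test_encounter_order_invariance(self, codeset):
        rng = np.random.default_rng(23)
        pool = ["F329", "J069", "K529", "R45851"]
        rows = []
        for i in range(30):
            for j in range(rng.integers(1, 3)):
                codes = tuple(rng.choice(pool, size=rng.integers(0, 3), replace=False))
                rows.append(
                    (f"p{i}", f"e{i}{j}", "2020-01-01", 13, "female", "white", codes, ("ED",))
                )
        enc = make_encounters(rows)
        shuffled = enc.sample(frac=1.0, random_state=1)
        from suicidality_psm.case_definition import label_patients

        out1 = comorbidity_scan(
            patient_code_profiles(enc), label_patients(enc, codeset), StratumSpec(),
            codeset, min_patients=1, top_k=None,
        )
        out2 = comorbidity_scan(
            patient_code_profiles(shuffled), label_patients(shuffled, codeset), StratumSpec(),
            codeset, min_patients=1, top_k=None,
        )
        assert out1 == out2

    def test_stratum_restriction(self, codeset):
        profiles = {"p1": frozenset({"F329"}), "p2": frozenset({"F329"})}
        labels = {"p1": case(), "p2": noncase()}
        demo = {"p1": ("adolescents_12_18", "female"), "p2": ("children_6_11", "male")}
        stats = comorbidity_scan(
            profiles, labels, StratumSpec(sex="female"), codeset,
            demographics=demo, min_patients=1, top_k=None,
        )
        assert len(stats) == 1 and stats[0].n_B == 1 and stats[0].n_AB == 1


class TestSignificantUnion:
    def _corpus(self):
        # F329 perfectly associated with case status; J069 exactly independent.
        profiles = {}
        labels = {}
        for i in range(20):
            profiles[f"c{i}"] = frozenset({"F329", "J069"} if i < 10 else {"F329"})
            labels[f"c{i}"] = case()
        for i in range(20):
            profiles[f"n{i}"] = frozenset({"J069"} if i < 10 else set())
            labels[f"n{i}"] = noncase()
        return profiles, labels

    def test_union_keeps_associated_code_with_provenance(self, codeset):
        profiles, labels = self._corpus()
        strata = [StratumSpec(), StratumSpec(subtype="ideation")]
        results = run_scans(profiles, labels, codeset, strata=strata, min_patients=5,
                            top_k=None)
        union = significant_union(results)
        assert set(union) == {"F329"}
        assert union["F329"] == strata  # one entry, both strata as provenance

    def test_disjoint_strata_concatenate(self, codeset):
        profiles, labels = self._corpus()
        results = run_scans(profiles, labels, codeset, strata=[StratumSpec()],
                            min_patients=5, top_k=None)
        only = results[StratumSpec()]
        import dataclasses as _dc

        other = StratumSpec(subtype="self_harm")
        fake = {
            StratumSpec(): [s for s in only if s.significant],
            other: [_dc.replace(s, code="F999", stratum=other) for s in only if s.significant],
        }
        union = significant_union(fake)
        assert set(union) == {"F329", "F999"}


class TestDsm5:
    def test_single_covering_pattern(self):
        mapping = Dsm5Mapping(entries=(("F*", "mental"),))
        profiles = {"p1": frozenset({"F329"}), "p2": frozenset(), "p3": frozenset({"F419"})}
        labels = {"p1": case(), "p2": noncase(), "p3": noncase()}
        df, unmapped = dsm5_category_stats(profiles, labels, mapping)
        assert unmapped == 0
        assert df.loc["mental", "prevalence"] == pytest.approx(2 / 3)

    def test_category_held_only_by_cases(self):
        mapping = Dsm5Mapping(entries=(("F60*", "personality"),))
        profiles = {"p1": frozenset({"F603"}), "p2": frozenset({"J069"})}
        labels = {"p1": case(), "p2": noncase()}
        df, unmapped = dsm5_category_stats(profiles, labels, mapping)
        assert df.loc["personality", "p_suicidality_given_category"] == 1.0
        assert unmapped == 1  # J069

    def test_first_match_wins(self):
        mapping = Dsm5Mapping(entries=(("F64*", "gender_dysphoria"), ("F6*", "personality")))
        assert mapping.map_code("F648") == "gender_dysphoria"
        assert mapping.map_code("F603") == "personality"

    def test_default_mapping_covers_planted_codes(self):
        mapping = Dsm5Mapping.default()
        assert mapping.map_code("F329") == "depressive"
        assert mapping.map_code("F319") == "bipolar"
        assert mapping.map_code("F648") == "gender_dysphoria"
        assert mapping.map_code("F603") == "personality"
        assert mapping.map_code("J069") is None
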