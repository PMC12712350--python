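"""kNN/Gower imputation and univariate logistic odds-ratio screening."""

import dataclasses

import numpy as np
import pytest

from fqvigil.report_model import ReactionMention
from fqvigil.risk_factors import (
    ImputationError,
    ImputeConfig,
    knn_impute,
    logistic_univariate,
    risk_factor_screen,
    soc_outcome_flag,
)
from fqvigil.synthetic_reports import SimConfig, simulate


class TestKnnImpute:
    def test_unanimous_neighbourhood_imputes_donor_age(self, case_factory):
        donors = [
            case_factory(case_id=f"D{i}", age_years=40.0) for i in range(5)
        ]
        target = case_factory(case_id="T", age_years=None)
        out, report = knn_impute(donors + [target])
        assert out[-1].age_years == 40.0
        assert report["imputed_age"] == ["T"]

    def test_no_missing_values_is_a_no_op(self, case_factory):
        cases = [case_factory(case_id=f"C{i}") for i in range(6)]
        out, report = knn_impute(cases)
        assert out == cases
        assert report["imputed_age"] == [] and report["imputed_sex"] == []

    def test_observed_values_never_altered(self, case_factory):
        cases = [
            case_factory(case_id=f"D{i}", age_years=30.0 + i, sex="male")
            for i in range(8)
        ] + [case_factory(case_id="T", sex="unspecified", age_years=None)]
        out, _ = knn_impute(cases)
        for before, after in zip(cases[:-1], out[:-1]):
            assert before == after

    def test_too_few_donors_rejected(self, case_factory):
        cases = [
            case_factory(case_id="D0", age_years=40.0),
            case_factory(case_id="T", age_years=None),
        ]
        with pytest.raises(ImputationError):
            knn_impute(cases, ImputeConfig(k=5))

    def test_mode_tie_breaks_alphabetically(self, case_factory):
        # 2 female + 2 male nearest donors with k=4: "female" < "male"
        donors = [
            case_factory(case_id=f"D{i}",
                         sex="female" if i < 2 else "male",
                         age_years=40.0)
            for i in range(4)
        ]
        target = case_factory(case_id="T", sex="unspecified")
        out, _ = knn_impute(donors + [target], ImputeConfig(k=4))
        assert out[-1].sex == "female"

    def test_beats_marginal_median_imputation_under_mcar(self):
        # age strongly drug-linked so the feature signal is recoverable
        from fqvigil.synthetic_reports import default_demographics

        marginals = default_demographics()
        marginals["age_group_by_exposure"] = {
            "ciprofloxacin": {"0-17": 0.05, "18-34": 0.85,
                              "35-64": 0.08, "65+": 0.02},
            "levofloxacin": {"0-17": 0.02, "18-34": 0.08,
                             "35-64": 0.85, "65+": 0.05},
            "moxifloxacin": {"0-17": 0.01, "18-34": 0.04,
                             "35-64": 0.10, "65+": 0.85},
        }
        config = SimConfig(
            n_cases=5000,
            exposure_probs={"ciprofloxacin": 0.3, "levofloxacin": 0.3,
                            "moxifloxacin": 0.3, "background": 0.1},
            demographic_marginals=marginals,
            duplicate_fraction=0.0, psychotropic_rate=0.0,
            missing_rates={}, seed=23,
        )
        cases, _ = simulate(config)
        rng = np.random.default_rng(0)
        mask = rng.random(len(cases)) < 0.2
        truth_ages = {}
        holed = []
        for hide, case in zip(mask, cases):
            if hide and case.age_years is not None:
                truth_ages[case.case_id] = case.age_years
                holed.append(dataclasses.replace(case, age_years=None))
            else:
                holed.append(case)
        imputed, _ = knn_impute(holed)
        observed = [c.age_years for c in holed if c.age_years is not None]
        marginal = float(np.median(observed))
        knn_err = np.mean(
            [
                abs(c.age_years - truth_ages[c.case_id])
                for c in imputed
                if c.case_id in truth_ages
            ]
        )
        median_err = np.mean(
            [abs(marginal - v) for v in truth_ages.values()]
        )
        assert knn_err < median_err

    def test_deterministic_given_input(self, case_factory):
        cases = [
            case_factory(case_id=f"D{i}", age_years=float(20 + i))
            for i in range(10)
        ] + [case_factory(case_id="T", age_years=None)]
        out1, _ = knn_impute(cases, seed=1)
        out2, _ = knn_impute(cases, seed=99)
        assert out1 == out2



class TestLogisticUnivariate:
    def test_separation_is_flagged_not_fitted(self, case_factory):
        # every male has the event, no female does → perfect separation
        cases = [
            case_factory(case_id=f"M{i}", sex="male",
                         reactions=[ReactionMention("anxiety")])
            for i in range(10)
        ] + [
            case_factory(case_id=f"F{i}", sex="female",
                         reactions=[ReactionMention("tendonitis")])
            for i in range(10)
        ]
        results = logistic_univariate(
            cases, "sex", lambda c: "anxiety" in c.pts()
        )
        flagged = [r for r in results if "separation" in r.flags]
        assert flagged and all(r.or_estimate is None for r in flagged)

    def test_reference_row_has_unit_or(self, case_factory):
        cases = [
            case_factory(case_id=f"C{i}", sex="male" if i % 2 else "female",
                         reactions=[ReactionMention(
                             "anxiety" if i % 3 else "tendonitis")])
            for i in range(60)
        ]
        results = logistic_univariate(
            cases, "sex", lambda c: "anxiety" in c.pts()
        )
        ref = next(r for r in results if r.is_reference)
        assert ref.level == "male" and ref.or_estimate == 1.0
        assert ref.ci_low is None

    def test_null_simulation_ci_covers_one(self):
        covers = total = 0
        rng = np.random.default_rng(31)
        for _ in range(60):
            config = SimConfig(
                n_cases=3000,
                exposure_probs={"ciprofloxacin": 0.5, "background": 0.5},
                baseline_event_odds={"anxiety": 0.05,
                                     "drug ineffective": 0.04},
                planted_or={},
                duplicate_fraction=0.0, psychotropic_rate=0.0,
                missing_rates={}, seed=int(rng.integers(0, 2**31 - 1)),
            )
            cases, _ = simulate(config)
            results = logistic_univariate(
                cases, "sex", lambda c: "anxiety" in c.pts(),
            )
            for r in results:
                if r.ci_low is not None:
                    covers += r.ci_low <= 1.0 <= r.ci_high
                    total += 1
        assert covers / total > 0.88


class TestRiskFactorScreen:
    def test_planted_age_effect_recovered(self, dictionary):
        from fqvigil.experiments import age_or_recovery

        fitted = age_or_recovery(2.5, n_cases=50000, seed=41)
        assert 2.0 <= fitted <= 3.0

    def test_one_bh_family_across_predictors(self, dictionary):
        config = SimConfig(n_cases=4000, seed=6)
        cases, _ = simulate(config)
        from fqvigil.preprocess import preprocess

        retained, _ = preprocess(cases)
        imputed, _ = knn_impute(retained)
        results = risk_factor_screen(
            imputed, soc_outcome_flag(dictionary, "psychiatric disorders")
        )
        from fqvigil.tto_analysis import bh_adjust

        raw = [r.p_value for r in results if r.p_value is not None]
        adj = [r.p_adjusted for r in results if r.p_value is not None]
        assert adj == pytest.approx(bh_adjust(raw))
        refs = [r for r in results if r.is_reference]
        assert {r.predictor for r in refs} == {
            "exposure", "therapy", "sex", "age_group", "severity",
        }

    def test_null_screen_fdr_controlled(self, dictionary):
        significant = total = 0
        rng = np.random.default_rng(51)
        for _ in range(40):
            config = SimConfig(
                n_cases=2500,
                exposure_probs={
                    "ciprofloxacin": 0.3, "levofloxacin": 0.2,
                    "background": 0.5,
                },
                baseline_event_odds={"anxiety": 0.05,
                                     "drug ineffective": 0.04},
                planted_or={},
                duplicate_fraction=0.0, psychotropic_rate=0.0,
                missing_rates={}, seed=int(rng.integers(0, 2**31 - 1)),
            )
            cases, _ = simulate(config)
            results = risk_factor_screen(
                cases,
                soc_outcome_flag(dictionary, "psychiatric disorders"),
                predictors=("exposure", "sex", "age_group"),
            )
            for r in results:
                if r.p_adjusted is not None:
                    significant += r.p_adjusted < 0.05
                    total += 1
        assert significant / total <= 0.10
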