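"""Score engines, rate tables, DEALE conversion, and range enumeration."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afchoice.risk_engine import (
    Outcome,
    TreatmentOption,
    annual_stroke_rate,
    baseline_bleed_rate,
    chads2_score,
    enumerate_ranges,
    hemorrhages_score,
    horizon_risk,
    risk_estimate,
    round_pct,
    treated_bleed_rate,
    treated_stroke_rate,
    warfarin_bleed_rate,
)
from helpers import RELEVANT_FLAGS, build_profile


class TestScores:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(age=60), 0),
            (dict(age=60, prior_stroke_tia=True), 2),
            (dict(age=74, chf=True, hypertension=True, diabetes=True), 3),
            (dict(age=75), 1),  # age threshold is inclusive
            (
                dict(age=80, chf=True, hypertension=True, diabetes=True,
                     prior_stroke_tia=True),
                6,
            ),
        ],
    )
    def test_chads2(self, kwargs, expected):
        assert chads2_score(build_profile(**kwargs)) == expected

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(age=60), 0),
            (dict(age=60, prior_major_bleed=True), 2),
            (dict(age=75), 0),  # "older age" threshold is strict
            (dict(age=76), 1),
            (
                dict(
                    age=80,
                    hepatic_or_renal_disease=True, ethanol_abuse=True,
                    malignancy=True, reduced_platelets=True,
                    hypertension=True, uncontrolled_hypertension=True,
                    anemia=True, genetic_factors=True, fall_risk=True,
                    prior_stroke_tia=True, prior_major_bleed=True,
                ),
                12,
            ),
        ],
    )
    def test_hemorrhages(self, kwargs, expected):
        assert hemorrhages_score(build_profile(**kwargs)) == expected

    def test_chads2_age_criterion_differs_from_hemorrhages(self):
        p75 = build_profile(age=75)
        assert chads2_score(p75) == 1
        assert hemorrhages_score(p75) == 0


class TestRateTables:
    def test_stroke_rates_strictly_increasing(self):
        rates = [annual_stroke_rate(s) for s in range(7)]
        assert rates == [0.019, 0.028, 0.040, 0.059, 0.085, 0.125, 0.182]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_warfarin_bleed_rates_increase_then_cap(self):
        rates = [warfarin_bleed_rate(s) for s in range(13)]
        assert rates[:6] == [0.019, 0.025, 0.053, 0.084, 0.104, 0.123]
        assert all(a < b for a, b in zip(rates[:6], rates[1:6]))
        assert set(rates[5:]) == {0.123}

    @pytest.mark.parametrize("score", [-1, 7])
    def test_stroke_score_out_of_range(self, score):
        with pytest.raises(ValueError):
            annual_stroke_rate(score)

    @pytest.mark.parametrize("score", [-1, 13])
    def test_bleed_score_out_of_range(self, score):
        with pytest.raises(ValueError):
            warfarin_bleed_rate(score)

    @pytest.mark.parametrize(
        "age, prior_bleed, expected",
        [
            (50, False, 0.0012),
            (59, False, 0.0012),
            (60, False, 0.005),   # band lower bounds inclusive
            (69, True, 0.015),
            (70, False, 0.012),
            (79, True, 0.030),
            (80, False, 0.025),
            (85, True, 0.060),
        ],
    )
    def test_baseline_bleed_stratification(self, age, prior_bleed, expected):
        p = build_profile(age=age, prior_major_bleed=prior_bleed)
        assert baseline_bleed_rate(p) == expected

    def test_baseline_monotone_in_age_and_prior_bleed(self):
        for prior in (False, True):
            rates = [
                baseline_bleed_rate(build_profile(age=a, prior_major_bleed=prior))
                for a in (50, 65, 75, 85)
            ]
            assert all(a < b for a, b in zip(rates, rates[1:]))
        for a in (50, 65, 75, 85):
            assert baseline_bleed_rate(
                build_profile(age=a, prior_major_bleed=True)
            ) > baseline_bleed_rate(build_profile(age=a, prior_major_bleed=False))


class TestTreatmentModifiers:
    def test_aspirin_stroke_reduction(self):
        assert treated_stroke_rate(0.10, TreatmentOption.ASPIRIN) == pytest.approx(0.079)

    def test_warfarin_stroke_reduction(self):
        assert treated_stroke_rate(0.10, TreatmentOption.WARFARIN) == pytest.approx(0.033)

    def test_combination_adds_no_stroke_benefit_over_warfarin(self):
        assert treated_stroke_rate(
            0.10, TreatmentOption.ASPIRIN_PLUS_WARFARIN
        ) == treated_stroke_rate(0.10, TreatmentOption.WARFARIN)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            treated_stroke_rate(-0.1, TreatmentOption.NONE)

    def test_bleed_pathways(self):
        p = build_profile(age=50)
        assert treated_bleed_rate(p, TreatmentOption.NONE) == 0.0012
        assert treated_bleed_rate(p, TreatmentOption.ASPIRIN) == pytest.approx(0.0024)
        assert treated_bleed_rate(p, TreatmentOption.WARFARIN) == 0.019
        assert treated_bleed_rate(
            p, TreatmentOption.ASPIRIN_PLUS_WARFARIN
        ) == pytest.approx(0.038)


class TestHorizonConversion:
    @pytest.mark.parametrize(
        "rate, years, expected",
        [
            (0.0, 5, 0.0),
            (0.182, 5, 0.59748),
            (0.019, 5, 0.09063),
        ],
    )
    def test_closed_form(self, rate, years, expected):
        assert horizon_risk(rate, years) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("rate, years", [(-0.1, 5), (0.1, 0), (0.1, -1)])
    def test_invalid_inputs(self, rate, years):
        with pytest.raises(ValueError):
            horizon_risk(rate, years)

    @settings(derandomize=True, max_examples=200)
    @given(
        r1=st.floats(1e-6, 0.5), dr=st.floats(1e-6, 0.5),
        t1=st.floats(0.1, 20), dt=st.floats(1e-3, 20),
    )
    def test_monotone_in_rate_and_years(self, r1, dr, t1, dt):
        # strict monotonicity, tested above float-resolution noise
        assert horizon_risk(r1, t1) < horizon_risk(r1 + dr, t1)
        assert horizon_risk(r1, t1) < horizon_risk(r1, t1 + dt)
        assert 0.0 <= horizon_risk(r1, t1) < 1.0

    @settings(derandomize=True, max_examples=200)
    @given(rt=st.floats(1e-6, 0.02), years=st.floats(0.5, 10))
    def test_small_rate_limit_matches_linear_approximation(self, rt, years):
        rate = rt / years
        assert horizon_risk(rate, years) / rt == pytest.approx(1.0, rel=0.01)


class TestRoundPct:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.0906, 9), (0.455, 46), (0.5975, 60), (0.125, 13), (0.004, 0), (0.005, 1)],
    )
    def test_half_away_from_zero(self, p, expected):
        assert round_pct(p) == expected

    @pytest.mark.parametrize("p", [-0.01, 1.0, 1.5])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            round_pct(p)


class TestRiskEstimate:
    def test_range_minimum_profile_on_warfarin(self):
        est = risk_estimate(build_profile(age=60), TreatmentOption.WARFARIN)
        assert est.stroke_risk_pct == 3
        assert est.bleed_risk_pct == 9

    def test_range_maximum_profile_untreated(self):
        p = build_profile(
            age=80, chf=True, hypertension=True, diabetes=True,
            prior_stroke_tia=True, prior_major_bleed=True,
            hepatic_or_renal_disease=True, ethanol_abuse=True,
        )
        assert chads2_score(p) == 6 and hemorrhages_score(p) >= 5
        assert risk_estimate(p, TreatmentOption.NONE).stroke_risk_pct == 60

    def test_vanishing_horizon_sends_risks_to_zero(self):
        est = risk_estimate(build_profile(age=85), TreatmentOption.NONE, years=1e-9)
        assert est.stroke_risk_pct == 0 and est.bleed_risk_pct == 0

    def test_composition_consistency(self, fixture_profiles):
        """Percent fields always equal round_pct(horizon_risk(.)) from parts."""
        for p in fixture_profiles[:100]:
            for opt in TreatmentOption:
                est = risk_estimate(p, opt)
                base = annual_stroke_rate(chads2_score(p))
                assert est.stroke_rate_annual == treated_stroke_rate(base, opt)
                assert est.bleed_rate_annual == treated_bleed_rate(p, opt)
                assert est.stroke_risk_pct == round_pct(
                    horizon_risk(est.stroke_rate_annual, est.years)
                )
                assert est.bleed_risk_pct == round_pct(
                    horizon_risk(est.bleed_rate_annual, est.years)
                )

    def test_stroke_risk_ordering_across_options(self, fixture_profiles):
        """Warfarin < aspirin < none on the raw rate scale for every profile."""
        for p in fixture_profiles[:100]:
            none = risk_estimate(p, TreatmentOption.NONE)
            asp = risk_estimate(p, TreatmentOption.ASPIRIN)
            war = risk_estimate(p, TreatmentOption.WARFARIN)
            assert war.stroke_rate_annual < asp.stroke_rate_annual < none.stroke_rate_annual
            assert war.stroke_risk_pct <= asp.stroke_risk_pct <= none.stroke_risk_pct


AGE_GRID = (40, 59, 60, 69, 70, 74, 75, 76, 79, 80, 95)


def exhaustive_range_oracle(years=5.0):
    """Independent brute force over every flag combination and a full age grid.

    Walks all 2^13 combinations of the rate-relevant flags times the age
    grid (covering both sides of every threshold), sends each real profile
    through ``risk_estimate``, and records the extreme percents — no rate
    table is consulted directly.
    """
    lo = {(o, w): 101 for o in TreatmentOption for w in Outcome}
    hi = {(o, w): -1 for o in TreatmentOption for w in Outcome}
    for bits in itertools.product((False, True), repeat=len(RELEVANT_FLAGS)):
        flags = dict(zip(RELEVANT_FLAGS, bits))
        for age in AGE_GRID:
            profile = build_profile(age=age, **flags)
            for opt in TreatmentOption:
                est = risk_estimate(profile, opt, years)
                for outcome, pct in (
                    (Outcome.STROKE, est.stroke_risk_pct),
                    (Outcome.MAJOR_BLEED, est.bleed_risk_pct),
                ):
                    key = (opt, outcome)
                    lo[key] = min(lo[key], pct)
                    hi[key] = max(hi[key], pct)
    return {k: (lo[k], hi[k]) for k in lo}


def test_enumerate_ranges_matches_exhaustive_oracle():
    oracle = exhaustive_range_oracle()
    for opt in TreatmentOption:
        for outcome in Outcome:
            assert enumerate_ranges(opt, outcome) == oracle[(opt, outcome)], (
                opt, outcome,
            )


def test_enumerate_ranges_shrink_with_shorter_horizon():
    for opt in TreatmentOption:
        for outcome in Outcome:
            lo5, hi5 = enumerate_ranges(opt, outcome, years=5)
            lo1, hi1 = enumerate_ranges(opt, outcome, years=1)
            assert lo1 <= lo5 and hi1 < hi5
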