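"""Risk score engines, rate tables, and multi-year risk conversion.

Pipeline: a patient profile is scored (CHADS₂ for stroke, HEMORR₂HAGES for
major bleeding on warfarin, an age × prior-bleed stratification for baseline
bleeding), each score maps to an annual event rate from an embedded table,
treatment modifies the rate multiplicatively (aspirin reduces stroke rate by
21%, warfarin by 67%; aspirin doubles bleeding rate), and the constant annual
rate r is converted to a t-year cumulative risk with the declining exponential
approximation of life expectancy (DEALE), ``1 - exp(-r t)``, with t = 5 years
by default.  Displayed risks are integer percentages, rounded half away from
zero.

All numeric constants live in ``data/rate_tables.json`` shipped with the
package, so they can be audited without reading code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Literal

from .patient_model import PatientProfile

__all__ = [
    "TreatmentOption",
    "Outcome",
    "RiskEstimate",
    "TABLES",
    "chads2_score",
    "hemorrhages_score",
    "annual_stroke_rate",
    "warfarin_bleed_rate",
    "baseline_bleed_rate",
    "treated_stroke_rate",
    "treated_bleed_rate",
    "horizon_risk",
    "round_pct",
    "risk_estimate",
    "enumerate_ranges",
]


class TreatmentOption(str, Enum):
    """Antithrombotic strategy under consideration."""

    NONE = "none"
    ASPIRIN = "aspirin"
    WARFARIN = "warfarin"
    ASPIRIN_PLUS_WARFARIN = "aspirin_plus_warfarin"


class Outcome(str, Enum):
    """Event whose risk is being communicated."""

    STROKE = "stroke"
    MAJOR_BLEED = "major_bleed"


def _load_tables() -> dict:
    with resources.files("afchoice.data").joinpath("rate_tables.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


#: Embedded rate tables and relative-risk constants (events per person-year).
TABLES = _load_tables()

_STROKE_RATES: list[float] = TABLES["stroke_rate_by_chads2"]
_WARFARIN_BLEED_RATES: list[float] = TABLES["warfarin_bleed_rate_by_hemorrhages"]
_WARFARIN_BLEED_CAP: int = TABLES["warfarin_bleed_score_cap"]
_BASELINE = TABLES["baseline_bleed_rate"]
ASPIRIN_STROKE_RRR: float = TABLES["aspirin_stroke_rrr"]
WARFARIN_STROKE_RRR: float = TABLES["warfarin_stroke_rrr"]
ASPIRIN_BLEED_RR: float = TABLES["aspirin_bleed_rr"]
DEFAULT_HORIZON_YEARS: float = TABLES["default_horizon_years"]

CHADS2_MAX = 6
HEMORRHAGES_MAX = 12

#: Stroke-rate multiplier for each option relative to no treatment.  Adding
#: aspirin to warfarin is assumed to confer no additional stroke reduction.
STROKE_RATE_MULTIPLIER: dict[TreatmentOption, float] = {
    TreatmentOption.NONE: 1.0,
    TreatmentOption.ASPIRIN: 1.0 - ASPIRIN_STROKE_RRR,
    TreatmentOption.WARFARIN: 1.0 - WARFARIN_STROKE_RRR,
    TreatmentOption.ASPIRIN_PLUS_WARFARIN: 1.0 - WARFARIN_STROKE_RRR,
}


def chads2_score(profile: PatientProfile) -> int:
    """CHADS₂ stroke-risk score, 0-6.

    One point each for congestive heart failure, hypertension, age >= 75 and
    diabetes; two points for prior stroke or TIA.
    """
    return (
        int(profile.chf)
        + int(profile.hypertension)
        + int(profile.age >= 75)
        + int(profile.diabetes)
        + 2 * int(profile.prior_stroke_tia)
    )


def hemorrhages_score(profile: PatientProfile) -> int:
    """HEMORR₂HAGES bleeding-risk score, 0-12.

    One point each for hepatic or renal disease, ethanol abuse, malignancy,
    age > 75, reduced platelet count or function, uncontrolled hypertension,
    anemia, genetic factors, excessive fall risk and prior stroke; two points
    for a prior major bleed (the rebleeding factor that gives the acronym its
    subscript 2).
    """
    return (
        int(profile.hepatic_or_renal_disease)
        + int(profile.ethanol_abuse)
        + int(profile.malignancy)
        + int(profile.age > 75)
        + int(profile.reduced_platelets)
        + int(profile.uncontrolled_hypertension)
        + int(profile.anemia)
        + int(profile.genetic_factors)
        + int(profile.fall_risk)
        + int(profile.prior_stroke_tia)
        + 2 * int(profile.prior_major_bleed)
    )


def annual_stroke_rate(score: int) -> float:
    """Annual stroke rate (events/person-year) for a CHADS₂ score."""
    if not 0 <= score <= CHADS2_MAX:
        raise ValueError(f"CHADS2 score must be in [0, {CHADS2_MAX}], got {score}")
    return _STROKE_RATES[score]


def warfarin_bleed_rate(score: int) -> float:
    """Annual major-bleed rate on warfarin for a HEMORR₂HAGES score.

    Scores of 5 and above share the top rate band.
    """
    if not 0 <= score <= HEMORRHAGES_MAX:
        raise ValueError(
            f"HEMORR2HAGES score must be in [0, {HEMORRHAGES_MAX}], got {score}"
        )
    return _WARFARIN_BLEED_RATES[min(score, _WARFARIN_BLEED_CAP)]


def _age_band_index(age: int) -> int:
    bounds = _BASELINE["age_band_lower_bounds"]
    idx = 0
    for i, lower in enumerate(bounds):
        if age >= lower:
            idx = i
    return idx


def baseline_bleed_rate(profile: PatientProfile) -> float:
    """Annual major-bleed rate off anticoagulation.

    Stratified by age band (<60, 60-69, 70-79, >=80; lower bounds inclusive)
    and by history of major bleeding, monotone in both.
    """
    key = "prior_bleed" if profile.prior_major_bleed else "no_prior_bleed"
    return _BASELINE[key][_age_band_index(profile.age)]


def treated_stroke_rate(base: float, option: TreatmentOption) -> float:
    """Annual stroke rate after applying the option's relative risk reduction."""
    if base < 0:
        raise ValueError(f"rate must be >= 0, got {base}")
    return base * STROKE_RATE_MULTIPLIER[TreatmentOption(option)]


def treated_bleed_rate(profile: PatientProfile, option: TreatmentOption) -> float:
    """Annual major-bleed rate under the given option.

    Off warfarin the baseline stratification applies (doubled on aspirin);
    on warfarin the HEMORR₂HAGES table applies, doubled again when aspirin is
    added on top.
    """
    option = TreatmentOption(option)
    if option is TreatmentOption.NONE:
        return baseline_bleed_rate(profile)
    if option is TreatmentOption.ASPIRIN:
        return baseline_bleed_rate(profile) * ASPIRIN_BLEED_RR
    rate = warfarin_bleed_rate(hemorrhages_score(profile))
    if option is TreatmentOption.ASPIRIN_PLUS_WARFARIN:
        rate *= ASPIRIN_BLEED_RR
    return rate


def horizon_risk(rate: float, years: float) -> float:
    """Cumulative event probability over a horizon: ``1 - exp(-rate * years)``.

    The constant-rate (DEALE) conversion from an annual rate to a multi-year
    risk; for small ``rate * years`` it approaches the linear approximation
    ``rate * years``.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if years <= 0:
        raise ValueError(f"years must be > 0, got {years}")
    return 1.0 - math.exp(-rate * years)


def round_pct(p: float) -> int:
    """Probability to integer percent, rounding half away from zero."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    return int(math.floor(100.0 * p + 0.5))


@dataclass(frozen=True)
class RiskEstimate:
    """Per-option annual rates and horizon risks for one patient."""

    option: TreatmentOption
    years: float
    stroke_rate_annual: float
    bleed_rate_annual: float
    stroke_risk_pct: int
    bleed_risk_pct: int

    def risk_pct(self, outcome: Outcome) -> int:
        outcome = Outcome(outcome)
        return (
            self.stroke_risk_pct
            if outcome is Outcome.STROKE
            else self.bleed_risk_pct
        )


def risk_estimate(
    profile: PatientProfile,
    option: TreatmentOption,
    years: float = DEFAULT_HORIZON_YEARS,
) -> RiskEstimate:
    """Full score → rate → treatment → horizon → percent composition."""
    option = TreatmentOption(option)
    stroke_rate = treated_stroke_rate(annual_stroke_rate(chads2_score(profile)), option)
    bleed_rate = treated_bleed_rate(profile, option)
    return RiskEstimate(
        option=option,
        years=years,
        stroke_rate_annual=stroke_rate,
        bleed_rate_annual=bleed_rate,
        stroke_risk_pct=round_pct(horizon_risk(stroke_rate, years)),
        bleed_risk_pct=round_pct(horizon_risk(bleed_rate, years)),
    )


def _attainable_rates(option: TreatmentOption, outcome: Outcome) -> list[float]:
    """All annual rates reachable over the discrete input space."""
    if outcome is Outcome.STROKE:
        mult = STROKE_RATE_MULTIPLIER[option]
        return [r * mult for r in _STROKE_RATES]
    if option in (TreatmentOption.NONE, TreatmentOption.ASPIRIN):
        mult = 1.0 if option is TreatmentOption.NONE else ASPIRIN_BLEED_RR
        cells = _BASELINE["no_prior_bleed"] + _BASELINE["prior_bleed"]
        return [r * mult for r in cells]
    mult = 1.0 if option is TreatmentOption.WARFARIN else ASPIRIN_BLEED_RR
    return [r * mult for r in _WARFARIN_BLEED_RATES]


def enumerate_ranges(
    option: TreatmentOption,
    outcome: Outcome | Literal["stroke", "major_bleed"],
    years: float = DEFAULT_HORIZON_YEARS,
) -> tuple[int, int]:
    """Attainable (min, max) rounded horizon-risk percents for an option.

    Brute force over the full discrete input space: every CHADS₂ score level
    for stroke, every HEMORR₂HAGES rate band or baseline age × prior-bleed
    cell for bleeding.
    """
    option = TreatmentOption(option)
    outcome = Outcome(outcome)
    pcts = [
        round_pct(horizon_risk(r, years)) for r in _attainable_rates(option, outcome)
    ]
    return min(pcts), max(pcts)
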