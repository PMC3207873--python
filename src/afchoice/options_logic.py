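"""Treatment-menu logic, practical issues, and sequelae content.

Which options are put in front of a patient depends on coexisting coronary
artery disease: without it the menu is no treatment / aspirin / warfarin;
with it, aspirin is kept on board per local practice norms, so the menu pairs
the current regimen with its alternative and never offers "no treatment".
"""

from __future__ import annotations

from dataclasses import dataclass

from .patient_model import CurrentMedication, PatientProfile
from .risk_engine import Outcome, TreatmentOption

__all__ = [
    "OptionMenu",
    "SequelaeDistribution",
    "OptionContextError",
    "available_options",
    "practical_issues",
    "sequelae",
    "OPTION_LABELS",
]

#: Human-readable option names used on every screen.
OPTION_LABELS: dict[TreatmentOption, str] = {
    TreatmentOption.NONE: "no treatment",
    TreatmentOption.ASPIRIN: "aspirin",
    TreatmentOption.WARFARIN: "warfarin",
    TreatmentOption.ASPIRIN_PLUS_WARFARIN: "aspirin plus warfarin",
}


class OptionContextError(ValueError):
    """The profile describes a treatment context with no defined menu."""


@dataclass(frozen=True)
class OptionMenu:
    options: tuple[TreatmentOption, ...]
    context_note: str

    def __post_init__(self) -> None:
        if not self.options:
            raise ValueError("option menu must be non-empty")
        if len(set(self.options)) != len(self.options):
            raise ValueError("option menu must not contain duplicates")


@dataclass(frozen=True)
class SequelaeDistribution:
    """How outcomes of an event divide among recovery, disability and death."""

    outcome: Outcome
    recover: float
    disabled: float
    die: float

    def __post_init__(self) -> None:
        if self.recover + self.disabled + self.die != 1.0:
            raise ValueError("sequelae fractions must sum to 1.0")


def available_options(profile: PatientProfile) -> OptionMenu:
    """Menu of treatment options for this patient's context.

    Raises :class:`OptionContextError` for a patient with coronary artery
    disease on no antithrombotic: that context has no defined presentation
    (local practice keeps such patients on aspirin).
    """
    if not profile.cad:
        return OptionMenu(
            options=(
                TreatmentOption.NONE,
                TreatmentOption.ASPIRIN,
                TreatmentOption.WARFARIN,
            ),
            context_note="No coronary artery disease: no treatment, aspirin "
            "alone, and warfarin alone are all available.",
        )
    if profile.current_medication is CurrentMedication.ASPIRIN:
        return OptionMenu(
            options=(TreatmentOption.ASPIRIN, TreatmentOption.ASPIRIN_PLUS_WARFARIN),
            context_note="Coronary artery disease, currently on aspirin: "
            "aspirin alone or aspirin plus warfarin.",
        )
    if profile.current_medication is CurrentMedication.WARFARIN:
        return OptionMenu(
            options=(TreatmentOption.ASPIRIN, TreatmentOption.WARFARIN),
            context_note="Coronary artery disease, currently on warfarin: "
            "aspirin alone or warfarin alone.",
        )
    raise OptionContextError(
        "no option menu is defined for coronary artery disease with no "
        "current antithrombotic medication"
    )


_NO_WARFARIN_ISSUES = [
    "no need for regular blood tests",
    "no restriction of activities or diet",
]
_WARFARIN_ISSUES = [
    "monthly blood tests",
    "avoid activities that can cause serious injury",
    "watch the amount of green, leafy vegetables in the diet",
]


def practical_issues(option: TreatmentOption) -> list[str]:
    """Day-to-day burdens of an option; warfarin's constraints dominate any
    regimen that contains it."""
    option = TreatmentOption(option)
    if option in (TreatmentOption.WARFARIN, TreatmentOption.ASPIRIN_PLUS_WARFARIN):
        return list(_WARFARIN_ISSUES)
    return list(_NO_WARFARIN_ISSUES)


def sequelae(outcome: Outcome) -> SequelaeDistribution:
    """Outcome distribution after a stroke or a major bleed.

    Strokes: about half recover, a quarter are disabled, a quarter die.
    Major bleeds: about three-quarters recover and a small number are
    disabled or die; the residual quarter is split evenly here, and rendered
    text says "a small number" rather than quoting these numerals.
    """
    outcome = Outcome(outcome)
    if outcome is Outcome.STROKE:
        return SequelaeDistribution(outcome, recover=0.50, disabled=0.25, die=0.25)
    return SequelaeDistribution(outcome, recover=0.75, disabled=0.125, die=0.125)
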