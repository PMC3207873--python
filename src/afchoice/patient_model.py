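"""Patient record model, parsing/validation, and synthetic fixture generation.

The patient profile is the single data-entry record the risk engine consumes:
the five CHADS₂ stroke-risk factors, the eleven HEMORR₂HAGES bleeding-risk
factors (several overlap), coronary-artery-disease status, and the patient's
current antithrombotic medication.  Age is recorded once and each score
applies its own threshold to it (CHADS₂ counts age >= 75, HEMORR₂HAGES
counts age > 75).
"""

from __future__ import annotations

import json
import random
import warnings
from enum import Enum
from typing import Any, Iterable, Mapping

import pydantic
from pydantic import ConfigDict, Field

__all__ = [
    "CurrentMedication",
    "PatientProfile",
    "ProfileError",
    "MissingFieldError",
    "ProfileValidationError",
    "ProfileWarning",
    "parse_profile",
    "generate_fixtures",
    "profile_json_schema",
]

AGE_MIN = 18
AGE_MAX = 120

#: Boolean risk-factor fields, in data-entry order.
FLAG_FIELDS: tuple[str, ...] = (
    "chf",
    "hypertension",
    "diabetes",
    "prior_stroke_tia",
    "hepatic_or_renal_disease",
    "ethanol_abuse",
    "malignancy",
    "reduced_platelets",
    "prior_major_bleed",
    "uncontrolled_hypertension",
    "anemia",
    "genetic_factors",
    "fall_risk",
    "cad",
)


class CurrentMedication(str, Enum):
    """Antithrombotic the patient is taking at the time of the encounter."""

    NONE = "none"
    ASPIRIN = "aspirin"
    WARFARIN = "warfarin"


class ProfileError(ValueError):
    """Base class for patient-record parsing and validation failures."""


class MissingFieldError(ProfileError):
    """A required field was absent from the input record."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing required field: {field!r}")


class ProfileValidationError(ProfileError):
    """A field was present but its value is not acceptable."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid value for {field!r}: {message}")


class ProfileWarning(UserWarning):
    """Non-fatal inconsistency in a patient record."""


class PatientProfile(pydantic.BaseModel):
    """Validated patient data-entry record.

    All fields are required; a record with a missing flag is rejected rather
    than defaulted, so that an unticked box can never be confused with an
    unasked question.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    age: int = Field(ge=AGE_MIN, le=AGE_MAX, description="Age in whole years")
    chf: bool = Field(description="Congestive heart failure")
    hypertension: bool = Field(description="History of hypertension")
    diabetes: bool
    prior_stroke_tia: bool = Field(description="Prior stroke or TIA")
    hepatic_or_renal_disease: bool
    ethanol_abuse: bool
    malignancy: bool
    reduced_platelets: bool = Field(
        description="Reduced platelet count or function"
    )
    prior_major_bleed: bool = Field(description="Prior major bleed (rebleeding risk)")
    uncontrolled_hypertension: bool
    anemia: bool
    genetic_factors: bool
    fall_risk: bool = Field(description="Excessive fall risk")
    cad: bool = Field(description="Coronary artery disease")
    current_medication: CurrentMedication

    @pydantic.model_validator(mode="after")
    def _warn_inconsistent_hypertension(self) -> "PatientProfile":
        if self.uncontrolled_hypertension and not self.hypertension:
            warnings.warn(
                "uncontrolled_hypertension is set without hypertension; "
                "the record is accepted but may be inconsistent",
                ProfileWarning,
                stacklevel=2,
            )
        return self

    def to_record(self) -> dict[str, Any]:
        """Plain-JSON mapping that round-trips through :func:`parse_profile`."""
        rec = self.model_dump()
        rec["current_medication"] = self.current_medication.value
        return rec


def parse_profile(record: Mapping[str, Any]) -> PatientProfile:
    """Validate a flat key/value mapping into a :class:`PatientProfile`.

    Raises
    ------
    MissingFieldError
        if a required field is absent.
    ProfileValidationError
        if a value is out of range, of the wrong type, or if the record
        contains a field name that is not part of the profile.
    """
    if not isinstance(record, Mapping):
        raise ProfileValidationError("<record>", "expected a mapping of field values")
    try:
        return PatientProfile.model_validate(dict(record))
    except pydantic.ValidationError as exc:
        err = exc.errors()[0]
        field = str(err["loc"][0]) if err["loc"] else "<record>"
        if err["type"] == "missing":
            raise MissingFieldError(field) from exc
        if err["type"] == "extra_forbidden":
            accepted = ", ".join(PatientProfile.model_fields)
            raise ProfileValidationError(
                field, f"unknown field; accepted fields are: {accepted}"
            ) from exc
        raise ProfileValidationError(field, err["msg"]) from exc


def load_profile(path: str) -> PatientProfile:
    """Read and validate a single patient profile from a JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return parse_profile(data)


def generate_fixtures(n: int, seed: int) -> list[PatientProfile]:
    """Generate ``n`` synthetic patient profiles spanning the risk-factor space.

    Every risk-factor flag is drawn independently with probability 0.5 and age
    uniformly on [40, 95], so all CHADS₂ and HEMORR₂HAGES score levels are
    reachable and (for n in the thousands) essentially certain to occur.
    Current medication is drawn uniformly from the options compatible with the
    drawn coronary-artery-disease status, so every fixture supports a
    presentable option menu.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = random.Random(seed)
    out: list[PatientProfile] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ProfileWarning)
        for _ in range(n):
            rec: dict[str, Any] = {name: rng.random() < 0.5 for name in FLAG_FIELDS}
            rec["age"] = rng.randint(40, 95)
            if rec["cad"]:
                rec["current_medication"] = rng.choice(
                    [CurrentMedication.ASPIRIN, CurrentMedication.WARFARIN]
                ).value
            else:
                rec["current_medication"] = rng.choice(list(CurrentMedication)).value
            out.append(PatientProfile.model_validate(rec))
    return out


def profiles_to_json(profiles: Iterable[PatientProfile]) -> str:
    """Serialize profiles as a JSON array of plain records."""
    return json.dumps([p.to_record() for p in profiles], indent=2)


def profile_json_schema() -> dict[str, Any]:
    """JSON Schema for the patient-profile file format."""
    return PatientProfile.model_json_schema()
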