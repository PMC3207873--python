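"""Shared test helpers: profile construction without validation warnings."""

from __future__ import annotations

import warnings

from afchoice.patient_model import (
    FLAG_FIELDS,
    PatientProfile,
    ProfileWarning,
    parse_profile,
)

RELEVANT_FLAGS = tuple(f for f in FLAG_FIELDS if f != "cad")


def build_profile(
    age: int = 60, current_medication: str = "none", **flags: bool
) -> PatientProfile:
    """A valid profile with all flags false unless overridden."""
    rec: dict = {f: False for f in FLAG_FIELDS}
    unknown = set(flags) - set(FLAG_FIELDS)
    if unknown:
        raise TypeError(f"unknown flags: {unknown}")
    rec.update(flags)
    rec["age"] = age
    rec["current_medication"] = current_medication
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ProfileWarning)
        return parse_profile(rec)
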