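"""Rendering: icon-array pictographs, option screens, and the decision report.

Risks are communicated as 100-person icon arrays (one filled icon per percent
of absolute risk over the horizon), shown one option at a time and then all
options side by side, framed by the facilitator's education script and closed
with a worksheet and a physician prompt.  All script passages live in an
editable text-asset file (``data/script_text.json``) so locale variants can be
swapped without touching code.

Rendering is deterministic: a fixed profile yields byte-identical text, SVG
and HTML output, which keeps snapshot tests honest.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .options_logic import (
    OPTION_LABELS,
    OptionMenu,
    available_options,
    practical_issues,
    sequelae,
)
from .patient_model import PatientProfile
from .risk_engine import (
    DEFAULT_HORIZON_YEARS,
    Outcome,
    RiskEstimate,
    TreatmentOption,
    risk_estimate,
)

__all__ = [
    "IconArray",
    "OptionScreen",
    "DecisionReport",
    "build_icon_array",
    "render_icon_array",
    "build_report",
    "render_report",
    "script_text",
]

ICON_DENOMINATOR = 100
GRID_SIDE = 10

OUTCOME_COLORS = {Outcome.STROKE: "#c0392b", Outcome.MAJOR_BLEED: "#e67e22"}
UNAFFECTED_COLOR = "#cfcfcf"

OUTCOME_LABELS = {Outcome.STROKE: "stroke", Outcome.MAJOR_BLEED: "major bleed"}

AFFECTED_GLYPH = "●"  # ●
UNAFFECTED_GLYPH = "○"  # ○


@lru_cache(maxsize=1)
def script_text() -> dict[str, str]:
    """The facilitator script passages shipped with the package."""
    with resources.files("afchoice.data").joinpath("script_text.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


@dataclass(frozen=True)
class IconArray:
    """A 100-icon pictograph: ``affected`` of 100 people have the outcome."""

    affected: int
    outcome: Outcome
    option: TreatmentOption
    denominator: int = ICON_DENOMINATOR

    def __post_init__(self) -> None:
        if not 0 <= self.affected <= self.denominator:
            raise ValueError(
                f"affected must be in [0, {self.denominator}], got {self.affected}"
            )


def build_icon_array(estimate: RiskEstimate, outcome: Outcome) -> IconArray:
    """Icon array whose filled count is the estimate's rounded percent."""
    outcome = Outcome(outcome)
    return IconArray(
        affected=estimate.risk_pct(outcome),
        outcome=outcome,
        option=estimate.option,
    )


def _render_text_grid(array: IconArray) -> str:
    rows = []
    for r in range(GRID_SIDE):
        start = r * GRID_SIDE
        row = "".join(
            AFFECTED_GLYPH if start + c < array.affected else UNAFFECTED_GLYPH
            for c in range(GRID_SIDE)
        )
        rows.append(row)
    return "\n".join(rows)


def _render_svg_grid(array: IconArray) -> str:
    # 16px cells with 12px circles; filled icons run left-to-right,
    # top-to-bottom, matching the text rendering.
    cell, radius, pad = 16, 6, 8
    side = GRID_SIDE * cell
    color = OUTCOME_COLORS[array.outcome]
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{side}" height="{side}" viewBox="0 0 {side} {side}" '
        f'role="img" aria-label="{array.affected} of {array.denominator} '
        f'affected by {OUTCOME_LABELS[array.outcome]}">'
    ]
    for i in range(array.denominator):
        r, c = divmod(i, GRID_SIDE)
        fill = color if i < array.affected else UNAFFECTED_COLOR
        parts.append(
            f'<circle cx="{c * cell + pad}" cy="{r * cell + pad}" '
            f'r="{radius}" fill="{fill}"/>'
        )
    parts.append("</svg>")
    return "".join(parts)


def render_icon_array(array: IconArray, format: str = "text") -> str:
    """Render a pictograph as a text grid or an SVG 1.1 document."""
    if format == "text":
        return _render_text_grid(array)
    if format == "svg":
        return _render_svg_grid(array)
    raise ValueError(f"unknown format {format!r}; expected 'text' or 'svg'")


@dataclass(frozen=True)
class OptionScreen:
    """One treatment option's outcome screen: risks, pictographs, burdens."""

    estimate: RiskEstimate
    stroke_array: IconArray
    bleed_array: IconArray
    issues: tuple[str, ...]


@dataclass(frozen=True)
class DecisionReport:
    """The ordered presentation bundle for one patient encounter."""

    profile: PatientProfile
    menu: OptionMenu
    years: float
    education: tuple[str, ...]
    option_screens: tuple[OptionScreen, ...]
    combined_screen: tuple[RiskEstimate, ...]
    values_script: tuple[str, ...]
    worksheet_prompt: str
    worksheet_slots: int
    physician_prompt: str
    sequelae_text: tuple[str, ...] = field(default=())


def build_report(
    profile: PatientProfile, years: float = DEFAULT_HORIZON_YEARS
) -> DecisionReport:
    """Assemble the decision report for a patient, in presentation order."""
    menu = available_options(profile)
    text = script_text()
    screens = []
    estimates = []
    for option in menu.options:
        est = risk_estimate(profile, option, years)
        estimates.append(est)
        screens.append(
            OptionScreen(
                estimate=est,
                stroke_array=build_icon_array(est, Outcome.STROKE),
                bleed_array=build_icon_array(est, Outcome.MAJOR_BLEED),
                issues=tuple(practical_issues(option)),
            )
        )
    return DecisionReport(
        profile=profile,
        menu=menu,
        years=years,
        education=(
            text["communication_opening"],
            text["education_afib"],
            text["education_heart_brain"],
        ),
        option_screens=tuple(screens),
        combined_screen=tuple(estimates),
        values_script=(
            text["no_perfect_medication"],
            text["think_one_at_a_time"],
            text["talk_to_doctor"],
            text["talking_helps"],
        ),
        worksheet_prompt=text["worksheet_prompt"],
        worksheet_slots=5,
        physician_prompt=text["physician_prompt"],
        sequelae_text=(text["sequelae_stroke"], text["sequelae_bleed"]),
    )


def _fmt_years(years: float) -> str:
    return f"{years:g}-year"


def _report_text(report: DecisionReport) -> str:
    lines: list[str] = []
    horizon = _fmt_years(report.years)
    lines.append("UNDERSTANDING YOUR ATRIAL FIBRILLATION TREATMENT CHOICES")
    lines.append("=" * 56)
    lines.append("")
    for passage in report.education:
        lines.append(passage)
        lines.append("")
    lines.append(f"Your context: {report.menu.context_note}")
    lines.append("")
    for screen in report.option_screens:
        label = OPTION_LABELS[screen.estimate.option]
        lines.append(f"OPTION: {label.upper()}")
        lines.append("-" * (8 + len(label)))
        lines.append(
            f"Out of 100 people like you, over {report.years:g} years, "
            f"{screen.estimate.stroke_risk_pct} would have a stroke:"
        )
        lines.append(render_icon_array(screen.stroke_array, "text"))
        lines.append(
            f"Out of 100 people like you, over {report.years:g} years, "
            f"{screen.estimate.bleed_risk_pct} would have a major bleed:"
        )
        lines.append(render_icon_array(screen.bleed_array, "text"))
        lines.append("What this option means day to day:")
        for issue in screen.issues:
            lines.append(f"  - {issue}")
        lines.append("")
    for passage in report.sequelae_text:
        lines.append(passage)
        lines.append("")
    lines.append(f"ALL OPTIONS TOGETHER ({horizon} risks per 100 people)")
    lines.append(f"{'option':<24}{'strokes':>10}{'major bleeds':>15}")
    for est in report.combined_screen:
        lines.append(
            f"{OPTION_LABELS[est.option]:<24}"
            f"{est.stroke_risk_pct:>10}{est.bleed_risk_pct:>15}"
        )
    lines.append("")
    for passage in report.values_script:
        lines.append(passage)
        lines.append("")
    lines.append("YOUR WORKSHEET")
    lines.append(report.worksheet_prompt)
    for i in range(report.worksheet_slots):
        lines.append(f"  {i + 1}. " + "_" * 48)
    lines.append("")
    lines.append("FOR YOUR DOCTOR")
    lines.append(report.physician_prompt)
    return "\n".join(lines) + "\n"


def _report_html(report: DecisionReport) -> str:
    esc = html.escape
    parts: list[str] = []
    parts.append(
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>Atrial fibrillation treatment choices</title>"
        "<style>body{font-family:sans-serif;max-width:52em;margin:2em auto}"
        "table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:4px 10px}.slot{border-bottom:1px solid #333;height:1.6em}"
        "</style></head><body>"
    )
    parts.append("<h1>Understanding your atrial fibrillation treatment choices</h1>")
    for passage in report.education:
        parts.append(f"<p>{esc(passage)}</p>")
    parts.append(f"<p><em>{esc(report.menu.context_note)}</em></p>")
    for screen in report.option_screens:
        label = OPTION_LABELS[screen.estimate.option]
        parts.append(f"<h2>Option: {esc(label)}</h2>")
        parts.append(
            f"<p>Out of 100 people like you, over {report.years:g} years, "
            f"<strong>{screen.estimate.stroke_risk_pct}</strong> would have "
            "a stroke:</p>"
        )
        parts.append(render_icon_array(screen.stroke_array, "svg"))
        parts.append(
            f"<p>Out of 100 people like you, over {report.years:g} years, "
            f"<strong>{screen.estimate.bleed_risk_pct}</strong> would have "
            "a major bleed:</p>"
        )
        parts.append(render_icon_array(screen.bleed_array, "svg"))
        parts.append("<p>What this option means day to day:</p><ul>")
        for issue in screen.issues:
            parts.append(f"<li>{esc(issue)}</li>")
        parts.append("</ul>")
    for passage in report.sequelae_text:
        parts.append(f"<p>{esc(passage)}</p>")
    parts.append(
        f"<h2>All options together ({report.years:g}-year risks per "
        "100 people)</h2><table><tr><th>option</th><th>strokes</th>"
        "<th>major bleeds</th></tr>"
    )
    for est in report.combined_screen:
        parts.append(
            f"<tr><td>{esc(OPTION_LABELS[est.option])}</td>"
            f"<td>{est.stroke_risk_pct}</td><td>{est.bleed_risk_pct}</td></tr>"
        )
    parts.append("</table>")
    for passage in report.values_script:
        parts.append(f"<p>{esc(passage)}</p>")
    parts.append(f"<h2>Your worksheet</h2><p>{esc(report.worksheet_prompt)}</p>")
    for _ in range(report.worksheet_slots):
        parts.append("<div class='slot'></div>")
    parts.append(f"<h2>For your doctor</h2><p>{esc(report.physician_prompt)}</p>")
    parts.append("</body></html>")
    return "".join(parts)


def render_report(
    profile: PatientProfile,
    years: float = DEFAULT_HORIZON_YEARS,
    format: str = "text",
) -> str:
    """Render the full decision report for a patient as text or HTML."""
    report = build_report(profile, years)
    if format == "text":
        return _report_text(report)
    if format == "html":
        return _report_html(report)
    raise ValueError(f"unknown format {format!r}; expected 'text' or 'html'")
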