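# Methods

## Risk model

The engine treats each outcome (ischemic stroke, major bleed) as a
constant-rate process. A patient's comorbidities select an annual event rate
from a lookup table; treatment scales that rate multiplicatively; the scaled
rate is converted to a cumulative horizon risk.

**Stroke pathway.** CHADS₂ is an additive score: 1 point each for congestive
heart failure, history of hypertension, age ≥ 75 years, and diabetes, and
2 points for prior stroke or TIA (range 0–6). Each score maps to an annual
stroke rate, in events per person-year:

| CHADS₂ | 0 | 1 | 2 | 3 | 4 | 5 | 6 |
|---|---|---|---|---|---|---|---|
| rate | 0.019 | 0.028 | 0.040 | 0.059 | 0.085 | 0.125 | 0.182 |

Aspirin multiplies the stroke rate by 0.79 (a 21% relative risk reduction),
warfarin by 0.33 (67%). Aspirin added to warfarin is assumed to confer no
additional stroke reduction, so the combination uses the warfarin multiplier.
The warfarin multiplier is exactly 1 − 0.67 = 0.33, not 1/3: the published
reduction is stated as a percentage.

**Bleeding pathway.** On warfarin (alone or combined), HEMORR₂HAGES applies:
1 point each for hepatic or renal disease, ethanol abuse, malignancy,
age > 75, reduced platelet count or function, uncontrolled hypertension,
anemia, genetic factors, excessive fall risk, and prior stroke; 2 points for
a prior major bleed (the rebleeding factor that gives the acronym its
subscript 2). Annual major-bleed rates are 0.019 / 0.025 / 0.053 / 0.084 /
0.104 for scores 0–4 and 0.123 for every score ≥ 5 (the top band is a cap:
the source cohort could not discriminate further).

Off warfarin, baseline bleeding risk is stratified by age band and bleeding
history (events per person-year):

| age band | no prior bleed | prior major bleed |
|---|---|---|
| < 60 | 0.0012 | 0.010 |
| 60–69 | 0.005 | 0.015 |
| 70–79 | 0.012 | 0.030 |
| ≥ 80 | 0.025 | 0.060 |

Band lower bounds are inclusive (exactly 60 falls in 60–69). The published
description of baseline bleeding risk gives only the attainable 5-year
envelope (1–26% untreated, 1–45% on aspirin), not the underlying table; the
table above is this package's calibration — the corner cells are fixed by
inverting the horizon conversion at the published envelope endpoints, and
interior cells are monotone interpolations in age and bleeding history. The
envelope endpoints are therefore faithful; individual interior cells are a
modeling choice and should not be quoted as published values.

Aspirin carries a bleeding relative risk of 2, applied multiplicatively to
the baseline rate. For aspirin + warfarin, where no published bleeding model
exists, the same relative risk of 2 is applied to the warfarin rate — the
same multiplicative convention used everywhere else. The resulting
combination bleeding envelope (17–71% at 5 years) is a consequence of this
choice, not a published figure.

**Horizon conversion.** A constant annual rate r becomes a t-year risk via
the declining exponential approximation of life expectancy (DEALE),
P = 1 − exp(−r·t). The default horizon is 5 years — long enough that risks
are not undervalued as negligible — and is a parameter everywhere. For small
r·t this approaches the linear approximation r·t (within 1% for r·t ≤ 0.02),
which the test suite checks.

**Display rounding.** Probabilities are kept at full precision internally and
rounded half away from zero to integer percent only for display; the rounded
percent is also the filled-icon count of the 100-person pictograph, so a
screen can never show a number that disagrees with its pictograph. This
convention reproduces every published envelope endpoint; whether the original
implementation rounded identically is unknowable from the published ranges
alone.

## Age thresholds

A single age field feeds both scores with deliberately different thresholds:
CHADS₂ counts age ≥ 75, HEMORR₂HAGES counts age > 75, as their respective
derivations define them. At exactly 75 a patient scores the CHADS₂ age point
but not the HEMORR₂HAGES one. Prior stroke/TIA is one shared input flag
scoring in both systems.

## Option menus

Patients without coronary artery disease choose among no treatment, aspirin,
and warfarin. With coronary artery disease, local practice keeps aspirin on
board: a patient on aspirin chooses between aspirin alone and aspirin +
warfarin; a patient on warfarin chooses between aspirin alone and warfarin
alone. A CAD patient on no antithrombotic has no defined presentation
context and is rejected explicitly rather than silently assigned a menu.
Menu ordering follows the order the contexts are described in.

## Sequelae

Stroke outcomes are presented as one-half recover, one-quarter disabled,
one-quarter die. For major bleeds the published description is
three-quarters recover and "a small number" disabled or die; the residual
quarter is split evenly (0.125/0.125) for internal bookkeeping, but rendered
text deliberately says "a small number" and never prints those numerals,
since the even split is a convention, not data.

## Synthetic patient generator

`generate_fixtures(n, seed)` draws every risk-factor flag independently with
probability 0.5 and age uniformly on [40, 95], so all score levels and both
sides of every age threshold occur; for n in the thousands every extreme
profile (CHADS₂ 0 and 6, HEMORR₂HAGES ≥ 5) appears with near certainty.
Current medication is drawn uniformly from the options compatible with the
drawn CAD flag (a CAD patient is never generated on no medication), so every
fixture can be rendered end to end. The generator emulates coverage of the
discrete input space, not epidemiology: real comorbidities are correlated
(hypertension and diabetes travel together; flag prevalence is not 50%), so
passing tests demonstrate correctness of the arithmetic over the whole input
space, not calibration against any real cohort.

## Numerical and degenerate-input choices

- Scores are small integers and rates exact table constants; the only
  floating-point step is `1 - exp(-r t)`, stable throughout the domain.
- Rounding is half away from zero via `floor(100p + 0.5)` (valid since
  probabilities are non-negative), avoiding banker's-rounding surprises at
  exact halves such as 0.455 → 46.
- Zero rate gives exactly 0% at any horizon; as the horizon → 0⁺ all risks
  → 0%. A negative rate or non-positive horizon is an argument error.
- Age is validated to [18, 120]. An uncontrolled-hypertension flag without
  the hypertension flag is accepted with a warning (the records are
  logically inconsistent but the score, which counts only the uncontrolled
  flag, is still well defined).
- Range enumeration brute-forces the discrete rate space (7 stroke levels,
  6 bleed bands, 8 baseline cells); a test cross-checks it against an
  exhaustive sweep of all 2¹³ flag combinations × an 11-point age grid
  (~90 000 profiles) pushed through the per-patient estimator.

## Rendering

Icon arrays use denominator 100 — the natural reading of integer-percent
pictographs — filled left-to-right, top-to-bottom, stroke icons in red and
bleed icons in orange. Text, SVG and HTML output are byte-deterministic for
a fixed profile, which makes snapshot testing meaningful. The facilitator
script passages (education, sequelae, value clarification, worksheet prompt,
physician prompt) are shipped as an editable JSON text asset so locale
variants can be swapped without code changes; sequelae are rendered as text,
not as a third pictograph.

## Known limitations

- Warfarin bleeding risk is treated as constant over the horizon, though it
  likely declines after the first months of therapy.
- No competing-risk mortality adjustment: a 5-year event risk ignores death
  from other causes, overstating risk for the very old.
- Intracranial and extracranial bleeds are pooled into one "major bleed"
  outcome despite very different sequelae.
- The score derivations come from older, largely Medicare-age cohorts;
  validity in younger patients is not established.
- Aspirin's bleeding relative risk is applied uniformly, with no interaction
  with individual bleeding risk factors, and drug–drug interactions (e.g.
  NSAIDs with warfarin) are out of scope.
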