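# afchoice

Individualized treatment decision support for non-valvular atrial
fibrillation (NVAF).

NVAF raises stroke risk; anticoagulation lowers it at the price of a higher
bleeding risk, and both risks vary widely with a patient's comorbidities —
enough that the benefit-to-harm balance can reverse between patients.
`afchoice` computes per-patient 5-year stroke and major-bleeding risks for
four strategies (no treatment, aspirin, warfarin, aspirin + warfarin) and
renders them as a patient decision aid: 100-person icon-array pictographs
shown option by option and then side by side, sequelae descriptions,
practical-issue summaries, a question worksheet, and a physician prompt. It
is intended for builders of decision aids and for anyone auditing the
arithmetic behind one.

## The model

For a patient with comorbidity flags and age *a*:

- **Stroke.** The CHADS₂ score (1 point each for congestive heart failure,
  hypertension, age ≥ 75, diabetes; 2 for prior stroke/TIA) maps to an annual
  stroke rate *r* from an embedded table
  (1.9/2.8/4.0/5.9/8.5/12.5/18.2 per 100 person-years for scores 0–6).
  Treatment scales the rate by a relative risk reduction: aspirin ×0.79,
  warfarin ×0.33; adding aspirin to warfarin confers no extra stroke benefit.
- **Bleeding.** On warfarin, the HEMORR₂HAGES score (1 point each for
  hepatic/renal disease, ethanol abuse, malignancy, age > 75, reduced
  platelets, uncontrolled hypertension, anemia, genetic factors, fall risk,
  prior stroke; 2 for prior major bleed) maps to an annual bleed rate
  (1.9/2.5/5.3/8.4/10.4 per 100 person-years for 0–4, 12.3 for ≥ 5). Off
  warfarin, a baseline table stratified by age band and bleeding history
  applies (0.12–6.0 per 100 person-years); aspirin doubles the bleeding rate
  (relative risk 2).
- **Horizon.** A constant annual rate *r* becomes a *t*-year risk via the
  declining exponential approximation of life expectancy (DEALE):
  *P* = 1 − e^(−*r·t*), with *t* = 5 years by default. Displayed risks are
  integer percentages (rounded half away from zero), which also fix the
  filled-icon counts of the pictographs.

Which options are shown depends on coronary artery disease (CAD): without
CAD the menu is no treatment / aspirin / warfarin; with CAD, aspirin stays on
board, so the menu pairs the current regimen with its alternative and never
offers "no treatment".

All rate tables and relative-risk constants ship as
`src/afchoice/data/rate_tables.json` for audit.

## Worked example

A 78-year-old with hypertension and diabetes, no CAD, on no antithrombotic
(CHADS₂ = 3, HEMORR₂HAGES = 1):

```sh
afchoice calc --profile patient.json --json
```

```json
{
  "horizon_years": 5.0,
  "context": "No coronary artery disease: no treatment, aspirin alone, and warfarin alone are all available.",
  "estimates": [
    {"option": "none",     "stroke_risk_pct": 26, "bleed_risk_pct": 6},
    {"option": "aspirin",  "stroke_risk_pct": 21, "bleed_risk_pct": 11},
    {"option": "warfarin", "stroke_risk_pct": 9,  "bleed_risk_pct": 12}
  ]
}
```

Read: out of 100 people like this patient, over 5 years, 26 would have a
stroke untreated versus 9 on warfarin, while major bleeds rise from 6 to 12.
`afchoice calc --profile patient.json` renders the same numbers as the full
report (icon arrays, sequelae, worksheet, physician prompt); `--format html`
produces a self-contained page with inline SVG pictographs.

`afchoice ranges` prints the attainable envelope over all comorbidity
combinations:

```
option                  outcome         min%  max%
no treatment            stroke             9    60
aspirin                 stroke             7    51
warfarin                stroke             3    26
warfarin                bleed              9    46
aspirin                 bleed              1    45
no treatment            bleed              1    26
```

`afchoice fixtures --n 100 --seed 1 --out fixtures.json` writes synthetic
patient profiles spanning the full risk-factor space.

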