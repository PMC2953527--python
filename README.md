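# ondansetron-cea

Decision-analytic cost-effectiveness model of routinely giving a single oral
dose of ondansetron — on top of oral rehydration therapy (ORT) — to children
who present to a North American emergency department (ED) with acute
gastroenteritis, vomiting and dehydration.

The package is for health economists, ED clinicians and guideline writers
who want to evaluate, audit or perturb the model: every input (event
probabilities per arm, unit costs per country, population constants, utility
weights) is an editable YAML document, every analysis is a library function
with a matching CLI command, and all randomness is seeded.

## The model

A two-strategy decision tree compares *treat all* against *standard care*
over one ED episode (horizon < 1 year, no discounting).  After the decision
node, chance nodes fire in order

```
vomit → IV rehydration | vomit status → admission | IV
      → ED revisit (discharged only) → admission at revisit
```

plus, in the treated arm, a cost-only "vomited the first dose" redose
branch.  For strategy *s* with terminal paths *j*, expected cost per patient
is the exact rollback

```
E[C_s] = Σ_j  p_j · c_j ,      net savings = E[C_control] − E[C_ondansetron]
```

with payoffs accrued per path (ED visit + physician fee per encounter, IV
insertion, hospitalization + inpatient fee per admission, dose price; the
societal perspective adds lost wages under an 8/16/24-hour rule, food/ORS,
travel and diapers).  QALY weights are 0.93 (moderate, outpatient) and 0.90
(severe, hospitalized).  The same tree is run as a Monte Carlo
microsimulation — parameters drawn from normal/gamma distributions truncated
to valid support, one simulated patient per trial, one trial per eligible
child — and through one-way/tornado sensitivity sweeps, closed-form
break-even dose pricing, and national-scale extrapolation for the US
(172,549 eligible children/year) and Canada (23,981).  Modeling conventions
and their rationale are documented in `docs/methods.md`.

## Worked example

```bash
ondansetron-cea evaluate --scenario us_2006
```

prints (manifest block omitted):

```json
{
  "country": "US",
  "currency": "USD",
  "perspective": "health_care",
  "arms": {
    "ondansetron": {
      "expected_cost_per_patient": 1341.110621315,
      "expected_qaly_per_patient": 0.9280500438000001
    },
    "control": {
      "expected_cost_per_patient": 1664.28342076,
      "expected_qaly_per_patient": 0.9268124172000001
    }
  },
  "net_savings_per_patient": 323.172799445,
  "net_savings_total_population": 55763143.37143531
}
```

Treating every eligible child costs the US health-care payer $1,341 per
patient versus $1,664 under standard care — the drug pays for itself by
averting IV insertions, admissions and revisit admissions, saving
$323/patient and ≈$55.8 million/year nationally, while also *gaining*
quality-adjusted life time (0.92805 vs 0.92681 QALYs/patient-year): a
dominant strategy.  The Canadian break-even price,

```bash
ondansetron-cea breakeven --scenario canada_2006
```

```json
{
  "country": "Canada",
  "currency": "CAD",
  "perspective": "health_care",
  "break_even_price_per_dose": 57.02649573809529,
  "current_price_per_dose": 12.86
}
```

shows the dose could cost 4.4× its CDN$12.86 reimbursement price before the
savings vanish.  Other commands: `simulate` (seeded microsimulation),
`sensitivity` / `tornado`, `qaly`, `population` (prevented IV insertions
and hospitalizations), `make-scenario` (random synthetic inputs) and
`run-all` (full CSV/JSON report bundle for both countries).  Equivalent
library calls live in `ondansetron_cea` (`net_savings`, `simulate`,
`break_even_price`, `tornado`, `prevented_events`, ...).

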