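# Methods

## The model

`ondansetron_cea` implements a two-strategy decision-analytic model of a
single clinical encounter: a child presents to a North American emergency
department (ED) with acute gastroenteritis, vomiting and mild-to-moderate
dehydration, and either receives one oral dose of ondansetron on top of oral
rehydration therapy (ORT) or receives ORT alone.  The time horizon is under
one year, so costs are not discounted and no multi-cycle (Markov) structure
is used.

After the treatment decision, chance nodes fire in this order:

1. **Vomiting continues** in the ED (probability `p_vomit`, arm-specific).
2. **Intravenous (IV) rehydration**, conditional on vomiting status
   (`p_iv_given_vomit` / `p_iv_given_no_vomit`).
3. **Hospital admission**, conditional on IV (`p_admit_given_iv`).
   Admission without IV does not occur at the index visit.
4. **Repeat ED visit**, for patients discharged home (`p_revisit`; see
   the revisit convention below).  Admitted patients do not revisit.
5. **Admission at the repeat visit**, conditional on revisiting
   (`p_admit_at_revisit`, arm-specific).
6. In the treated arm only, an independent **redose** branch (`p_redose`):
   the child vomits the first dose and a second is dispensed.  This is a
   cost-only event; it does not alter the efficacy probabilities, since the
   trials that produced the estimates re-administered the dose.

Terminal payoffs, health-care payer perspective: every ED encounter accrues
the adjusted ED-visit cost plus the ED physician fee; IV branches add the
IV-insertion fee; each admission (index or revisit) adds hospitalization
plus the inpatient physician fee; the treated arm adds the dose price
(doubled on the redose branch).  The revisit encounter carries no
IV-insertion fee and no second drug dose — the inputs provide no revisit-IV
probability, so the minimal structure consistent with the
revisit → admission chain is used.

Societal perspective adds, per patient: caregiver lost wages at the hourly
wage times lost work hours — 8 h for an outpatient visit without IV, 16 h
with IV but no admission, 24 h per admission, applied per ED episode (a
revisit adds 8 h if discharged again, 24 h if admitted) — plus special
food/oral rehydration solution, travel, and extra diapers, the last 33%
higher in the treated arm to reflect ondansetron's transient increase in
diarrhea.

Expected values are exact probability-weighted sums over the enumerated
terminal paths (28 treated / 14 control paths at the reference estimates;
zero-probability branches are pruned).  Net savings are defined as expected
cost(control) − expected cost(ondansetron); positive values favor treating.

### The ED-cost adjustment

The US administrative ED-visit cost mean includes IV rehydration for an
estimated 25% of visits.  Because the tree bills IV insertion explicitly,
the embedded average IV cost is removed once from the per-visit ED cost:
`ed_visit − 0.25 × iv_insertion` (704 − 0.25 × 194 = 655.50 US$), floored at
zero.  The adjusted value is used at every ED encounter.  The Canadian ED
cost is micro-costed without an embedded IV component, so its fraction is 0.

### The revisit-rate convention (a deliberate modeling choice)

The source estimates give arm-specific repeat-visit proportions (12%
treated / 10% control) whose difference was not statistically significant,
and the published population-scale outputs are mutually consistent only
with a treatment-independent revisit rate: prevented hospitalizations per
year (7,220 US; 1,003 Canada) imply a between-arm difference in total
admission probability of ≈0.0418 in both countries, which this model
reproduces (0.0413, within 1.5%) when both arms revisit at the
standard-care rate, but misses by >20% when each arm uses its own printed
rate.  Clinically, a single ED dose of a short-half-life antiemetic has no
plausible mechanism for changing post-discharge revisit behavior days
later.  The package therefore defaults to `revisit_rate="standard_care"`
(both arms revisit at the control-arm estimate, while admission severity at
the revisit stays arm-specific); `revisit_rate="arm"` switches every
function to fully arm-specific revisit rates for sensitivity of the
conclusion to this choice.  Under the default, headline US health-care
savings are $323/patient; under `"arm"` they fall to $242/patient, because
the treated arm's higher printed revisit-admission parameters
(12% × 44% vs 10% × 29%) then charge it ≈$195/patient of extra revisit
hospitalization.  Either way the treat-all strategy dominates.

Note the published revisit quantities are internally inconsistent — the
QALY totals imply an admission-probability difference of ≈0.051, the
hospitalization-cost sensitivity span implies ≈0.047, and the prevented
counts ≈0.0418 — so no convention reproduces all of them; the prevented
counts (printed to the unit for both countries) were taken as the
identifying observable.

### QALYs

Utility weights are annual: 0.93 for moderate gastroenteritis (any
outpatient course, with or without IV — assigning the IV-no-admit state the
moderate weight biases *against* the drug) and 0.90 for severe
(hospitalized at either visit).  The per-dose QALY gain is therefore
0.03 × the reduction in total admission probability, ≈0.00124 QALYs per
dose at the reference estimates.

## Uncertainty analysis

**One-way sweeps / tornado.**  Each parameter is fixed at the bounds of its
sensitivity range (95% CI for probabilities where the meta-analysis
provided one; ±25% for unit costs; 75–125% of the point estimate as the
fallback) with everything else at point estimates; the tornado sorts sweeps
by savings span, widest first, ties broken alphabetically, with an optional
filter dropping variables whose span is below a fraction (e.g. 1%) of the
base-case expected cost.  Expected cost is affine in every unit cost, so
cost-sweep extremes provably occur at the bounds.

**Break-even price.**  The treated arm's expected cost is affine in the
dose price with slope 1 + `p_redose`, so the zero-savings price is closed
form: (savings at price 0)/(1 + `p_redose`); a Brent root-bracketing solver
provides an independent numerical check to 1e−6.

**Microsimulation.**  Each trial draws one parameter set from the stated
distributions — normal for most parameters, gamma (moment-matched shape and
scale) for revisit admission, sd = (high − low)/(2 × 1.96) throughout — and
walks one simulated patient through the tree with a Bernoulli draw per
chance node.  The distribution family for costs is not dictated by the
sources; truncated normal was chosen, with truncation (probabilities to
[0, 1], costs to [0, ∞)) done by rejection rather than clipping so the mean
is not distorted by mass piling at the bounds.  Because expected cost is
multilinear in the parameters and draws are independent, the simulation
mean converges to the deterministic expectation; this is asserted at 10⁶
trials within 3 standard errors.  The default trial count is the eligible
population of the scenario's country (172,549 US; 23,981 Canada).
Randomness uses named numpy `SeedSequence` substreams, one per
(arm, parameter/chance node) in a fixed order: a fixed seed reproduces
results bit-for-bit, the two arms are independent, and growing `n_trials`
leaves earlier trials' draws in place except where rejection resampling
intervenes (rare, since all ranges sit well inside their supports).
Reported per-arm intervals are 2.5–97.5 percentiles of trial costs; the net
savings interval is a normal-approximation 95% CI of the mean difference.
No variance-reduction techniques are used.

## Population scaling

Eligible children per year = floor(annual gastroenteritis ED visits ×
eligibility fraction): 1,725,493 × 10% = 172,549 (US), 239,813 × 10% =
23,981 (Canada).  Prevented IV insertions use the index-visit IV
probability difference (law of total probability over vomiting status:
0.2652 control vs 0.0955 treated).  The headline prevented-hospitalization
count nets index and revisit admissions; the index-only count is reported
alongside because the published counting convention is not recoverable.
Totals are per-patient values times the eligible count.

## Synthetic scenarios

`generate_scenario` emulates the *structure* of the real inputs —
probabilities per chance node in [0, 1] with CI-style ranges, strictly
positive costs with ±25% ranges, a multiplicative treatment effect — so
that normalization, oracle-equivalence, symmetry and monotonicity
properties can be tested across hundreds of seeded random scenarios.  It
does not emulate correlations between parameters (none are modeled, as in
the original analysis) or any real-world covariance between costs and
probabilities, so passing those tests validates the arithmetic of the
machinery, not the clinical realism of any particular random scenario.

## Numerical conventions and limitations

- All currency arithmetic is at full floating precision; rounding to cents
  (or to whole events) happens only at report time.
- Canadian results are in 2006 CDN$; the 0.88 USD/CAD rate is shipped for
  cross-currency comparison but no result is silently converted.
- Two Canadian dose prices circulate in the sources (12.86 in the costing
  table, 13.09 as a provincial reimbursement average); the default Canadian
  scenario uses 12.86 and `canada_2006_provincial_price` ships the variant.
- The gamma family for a probability-valued parameter is unusual; it is
  retained as specified for revisit admission, moment-matched and rejected
  above 1 (a practically measure-zero event at these means).
- Eligibility (10%) is a conservative national assumption; the model's
  totals scale linearly in it.
- The model is an ED-encounter model for children with dehydration and
  recent vomiting in high-income settings; nothing here supports
  extrapolation to non-dehydrated children, repeat dosing, office settings,
  or developing-country ORT programs.
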