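# Methods

## Model structure

A cohort of AMI survivors is tracked over annual cycles through thirteen
mutually exclusive states:

| kind | states |
|---|---|
| acute tunnels (1 cycle) | Non-fatal MI, Non-fatal MI 2+, Non-fatal stroke, Non-fatal stroke 2+ |
| post-event | Post-MI, Post-stroke |
| composites | Post-MI + Post-stroke; acute MI (2+) over Post-stroke; acute stroke (2+) over Post-MI |
| absorbing | CV death, Non-CV death |

Routing: a new MI or stroke always passes through the corresponding acute
tunnel; the tunnel chosen depends on the person's history (first event vs
2+, with or without the other event's post history). Deeper histories
collapse onto the 2+ variants. Acute states never self-transition: a
same-type recurrence struck while already inside that event's 2+ tunnel
cannot be distinguished from the ongoing acute year, so its mass advances
with the tunnel (memory is unchanged). Revascularization is an expected
procedure count per cycle with a per-procedure cost, not a state. The set
of acute-over-post composites is a package choice (the underlying diagram
does not enumerate them) and is isolated in `build_state_space` for easy
reconfiguration.

Competing risks within a cycle: each annual rate converts independently to
a probability (`1 - exp(-r/100)`); death takes its mass first, and if
death plus events exceeds 1 the event probabilities are rescaled
proportionally — the standard cohort-model convention. Residual mass
advances tunnels to their post states and keeps post states in place. Every
row of every matrix is validated to sum to 1 within 1e-12.

## Mortality

The sources state only that cardiovascular mortality "varies with age";
the package composes mortality as follows:

* cycle 0 uses the cohort's published death rates (CV 2.2/100 pt-yr for the
  registry cohort; non-CV = all-cause 3.1 minus CV when an all-cause rate
  is published, otherwise the life table's non-CV value);
* cycles ≥ 1 take non-CV mortality directly from the life table at
  attained age and scale the cohort's CV hazard by the life table's CV age
  gradient, anchored to 1.0 at the starting age.

This keeps the cohort's excess cardiovascular risk while letting both
components rise with age. The treatment's CV-death effect multiplies the
CV hazard every cycle (rate ratio 0.86 per mmol/l in the surrogate engine).

**Endpoint-engine CV death.** No combined cardiovascular-death hazard
ratio is published for the endpoint engine; the packaged default is a
deliberately conservative 1.0, exposed as the parameter
`constant/Cardiovascular death hazard ratio (endpoint engine)`. This is
the main reason packaged endpoint-engine ICERs are high relative to
surrogate-engine ones — the endpoint arm gains QALYs only through avoided
non-fatal events. Users with a defensible estimate should override it.

History multipliers (`adjustment/Prior MI|stroke hazard multiplier`)
scale all event hazards of states carrying that history and stack
multiplicatively across two histories; the published values live in a
supplement, so the defaults are 1.0.

## Rewards

Costs and utilities accrue on the average of start- and end-of-cycle
occupancy (half-cycle correction), including cycle 0; cycle-t rewards are
discounted by `1/(1+d)**t` (annual-start convention; both choices are
config switches where the convention is genuinely open, e.g.
`drug_half_cycle`). Acute tunnels carry the year-1 event costs/utilities,
post states the beyond-1y rows. Combined states take the minimum utility
and the maximum cost of their components, except that the explicitly
published "Stroke + Post MI" cost rows override the max rule for that
composite. The published "MI 2+/Stroke 2+ (beyond 1y)" utilities have no
separate post-2+ states in this topology; they are loaded and sampled but
unused by the default mapping. Terminal CV-death costs are charged on the
transition inflow (an event count, not a state membership, hence no
half-cycle averaging), attributed by the decedent's event history with the
max rule for dual histories. The healthcare perspective counts direct
costs; the private payer adds the published indirect rows (acute-cycle
caregiver wage loss, ongoing informal care after stroke). Death states
accrue nothing. The injection-site adverse event (2.1% within 26 months,
annualized under a constant hazard) applies a −0.0003 utility decrement to
the treated arm.

## Synthetic inputs

The packaged parameter table reproduces the published key-input table
verbatim (values, ranges, distribution families). What the generators
emulate, and what they do not:

* **Life table** (`gen_life_table`): Gompertz all-cause hazard, calibrated
  near age 61 to the registry cohort's 3.1/100 pt-yr all-cause rate, with
  a CV fraction rising 0.30 → 0.50 over ages 40–90; seeded ±2% jitter.
  It is smooth and nationally unanchored — real census tables have sex
  structure and cohort effects the generator ignores.
* **Population profiles** (`gen_population`): starting ages 61 (registry,
  BERSON trial) and 69 (insurance database), effect engines and LDL-C
  reductions as published (66% of baseline for the database cohorts;
  1.88/1.69 mmol/l for BERSON). Baseline event rates for the database and
  BERSON cohorts are unpublished and stand in as the registry / trial rate
  blocks, flagged `synthetic_rates`; database baseline LDL-C values (2.8
  and 2.2 mmol/l) are representative stand-ins.
* **Hospital-tier multipliers**: synthetic factors (0.60–1.45 on direct
  event costs) spanning roughly the reported 2.4× county-to-apex cost
  span.

Consequently the packaged base-case ICERs demonstrate engine behaviour and
orderings (regimen ordering, horizon/discount/price monotonicities), not
the original report's table values — passing tests say the machinery is
right, not that any specific published ICER is recovered.

## Sensitivity analyses

* **One-way DSA**: efficacy/utility/baseline-rate parameters vary over
  their 95% CIs, costs over ±25%, discount rate over 0–8%; output is the
  tornado table sorted by |spread| (ties by name, deterministic).
* **PSA**: independent draws per parameter; lognormal fitted by matching
  the median to the point value and sigma to the log-width of the 95%
  interval; gamma and beta by moment matching with
  sd = (high − low)/3.92; negative beta rows (disutilities) sampled on the
  magnitude and negated; fixed/unranged rows stay at the point value.
  Default 10,000 replications; a seed fixes the full draw sequence
  (sorted-key order). CEAC grid: 0 to 3× WTP in 101 steps, always
  containing the WTP.
* **Scenarios**: one-at-a-time sweeps of horizon (5–35 y), starting age,
  discount rate (3/5/6%), statin annual cost (118.86 / 2855 / 5470.28 CNY)
  and hospital tier, for both regimens and perspectives.

## Numerical and verification choices

* Conversions are constant-hazard throughout (rates ↔ probabilities,
  26-month → annual adverse-event probability). `rate_to_prob` clamps
  strictly below 1 so absorbing-row arithmetic stays well-posed.
* Classification at the WTP boundaries is inclusive on the cost-effective
  side (ICER = 1× or 3× GDP per capita ⇒ cost-effective).
* Dominance is reported as a flag, never as a signed ICER; a zero
  incremental effect yields an "undefined" flag rather than infinity.
* The cohort engine is verified against an individual-level simulation of
  100,000 patients over the same per-cycle matrices. The comparison holds
  every cycle-state occupancy within Monte Carlo error at the 99.73%
  (3-standard-error) confidence level applied *familywise*: with ~340
  simultaneous comparisons a raw per-cell 3-SE band is exceeded by chance
  alone in most runs, so the per-cell critical value is
  Bonferroni-adjusted (~4.3 SE) to keep the whole-trace test at the
  intended confidence. The simulation is seeded for reproducibility.
* Test and acceptance problem sizes (1,000 randomized conservation
  configurations, 1,000–2,000 PSA replications, 100,000 simulated
  patients) were chosen to give tight Monte Carlo error at desk scale; the
  production default for PSA remains 10,000 replications.

## Known limitations

* No treatment discontinuation, adherence, or statin-intensity modelling;
  the treated arm pays drug costs until death or horizon end.
* One-year cycles; no sub-annual event timing beyond the half-cycle
  correction.
* Post-event states do not distinguish recurrence count (only the acute
  2+ tunnels and composites carry that memory).
* PSA draws are independent across parameters; no correlation structure
  is published.
* No EVPI/EVPPI, budget impact, or CPI re-inflation (costs are taken as
  2022 CNY).
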