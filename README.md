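# evocea

A Markov cohort state-transition model for the cost-effectiveness of adding
evolocumab (a PCSK9 inhibitor) to statin therapy in survivors of acute
myocardial infarction (AMI) in China, evaluated from the healthcare and the
private-payer perspective.

## Who this is for

Health-economics modellers and methodologists who want a tested, scriptable
implementation of a secondary-prevention cost-effectiveness model — in
particular one that exposes **both** common ways of modelling the treatment
effect of an LDL-C-lowering drug, so their impact on the incremental
cost-effectiveness ratio (ICER) can be compared on identical baselines.

## The model

The cohort enters in the *Post-MI* state and moves through annual cycles
between mutually exclusive health states: acute tunnel states for a
non-fatal MI or stroke (first event and 2+ recurrence variants, occupied
exactly one year), post-event maintenance states, composite states that
preserve the memory of both an MI and a stroke history, and two absorbing
death states (cardiovascular vs other causes). Coronary revascularization
(RV) is a costed procedure, not a health state.

Baseline event rates \(r_0\) (per 100 patient-years) become treated rates
via one of two engines:

* **endpoint engine** — \(r_{tx} = r_0 \cdot \mathrm{HR}\), with separate
  first-year and later-year hazard ratios from trial endpoints;
* **surrogate engine** — \(r_{tx} = r_0 \cdot \mathrm{RR}^{\Delta LDL}\),
  where RR is the rate ratio per 1 mmol/l of LDL-C reduction and
  \(\Delta LDL\) the absolute reduction achieved.

Rates convert to probabilities under a constant hazard,
\(p = 1 - e^{-r/100}\). Non-cardiovascular mortality comes from an
age-indexed life table (all-cause minus cardiovascular). Costs (2022 CNY)
and utilities accrue with a half-cycle correction and are discounted at 5%
per year over a 25-year horizon. The ICER \(\Delta C / \Delta E\) is judged
against a willingness-to-pay threshold of 3× GDP per capita
(CNY 257,094 ≈ US$38,224); one-way (tornado), probabilistic
(CEAC / cost-effectiveness plane) and scenario analyses are built in.

The published cohort baselines and national life tables are not
redistributable, so the packaged workspace uses the published parameter
table plus clearly flagged synthetic stand-ins (see `docs/methods.md`);
headline ICERs therefore reproduce the model's *behaviour*, not the
original report's table values.

## Worked example

```sh
evocea generate -w ws --seed 1
evocea basecase -w ws -o res --population SuValue_100 \
       --perspective healthcare --regimen Q2W_140
evocea psa -w ws -o res_psa --population SuValue_100 --draws 1000 --seed 7
evocea compare-engines -w ws -o cmp --population FOURIER
```

prints

```
ICER (SuValue_100, Q2W_140, healthcare): 106445.03 CNY/QALY [cost_effective]
P(cost-effective at WTP 257094): 1.0000 (0 failed draws)
ICER endpoint/surrogate ratio: 5.588
```

Reading the output: for the insurance-database cohort (LDL-C ≥ 100 mg/dl,
surrogate engine, 66% LDL-C reduction), adding evolocumab 140 mg every two
weeks costs about CNY 106,445 per quality-adjusted life-year gained —
between 1× and 3× GDP per capita, hence *cost-effective*; essentially all
of 1,000 probabilistic replications fall below the threshold. The engine
comparison runs the same trial baseline through both effect engines: the
endpoint-based ICER is several-fold higher here because the packaged
endpoint engine carries no cardiovascular-mortality benefit (no combined
CV-death hazard ratio is published; the default of 1.0 is deliberately
conservative and configurable — see `docs/methods.md`).

Each command writes full-precision CSV results and a `manifest.json`
(input digests, seed, version) to its output directory. The same
functionality is available as a library:

```python
from evocea import gen_default_parameters, gen_life_table, gen_population, run_cea

params = gen_default_parameters()
result = run_cea(params, gen_population("PEACE"), gen_life_table(seed=1))
print(result.icer, result.classification)
```

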