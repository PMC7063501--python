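# t1crc-cea

A Markov cohort cost-effectiveness model for treatment of T1 (submucosa-
confined) colorectal cancer, stratified by tumor-biomarker prognostic class.
It compares three curative strategies for 65-year-old patients —

* **ET** — endoscopic therapy (mucosal resection / submucosal dissection),
* **LC** — laparoscopic colectomy,
* **OC** — open colectomy,

across six prognostic classes defined by *APC* (one vs two truncating hits),
*KRAS*, *TP53*, and *BRAFV600E* (MSI-H), each with its own monthly
cancer-specific mortality in the recurrent-cancer state. The package is aimed
at health-economics and outcomes researchers who want a transparent,
fully-testable re-implementation of this decision model with every input
exposed in a config file.

## The model

A monthly-cycle cohort model follows patients from age 65 until death or age
100 (420 cycles). States: a one-month post-procedure tunnel (carrying the 0–1
month utility and the 30-day procedural mortality), long-term post-procedure
survival under colonoscopic surveillance, an absorbing recurrent-cancer state,
and three death states (cancer, other-cause, procedural). ET and LC carry an
intra-procedural conversion pathway (1.5% and 19%) to emergency open
colectomy, modeled as a parallel tunnel/long-term/recurrence chain with its
own costs and utilities. Background mortality comes from a period life table;
class-specific cancer mortality applies in the recurrent state only.

Outcomes per (class, strategy): undiscounted life-years,
quality-adjusted life-years `QALY = Σ_t occupancy(t)·u(state)·d(t)/12`, and
cost (procedure, conversion increment, complication readmissions, monthly
surveillance and recurrence treatment), with monthly discounting
`d(t) = (1+r)^(−t/12)`. The analysis layer adds dominance/extended-dominance
ICER ranking, net monetary benefit `NMB = QALY·WTP − cost`, one-way
sensitivity analysis with tornado ranking and threshold (preference-flip)
search, and probabilistic sensitivity analysis with cost-effectiveness
acceptability curves (10,000 joint draws run in one vectorized pass).

A note on discounting: the published base-case table this model reproduces
discounts costs at 3%/yr but leaves QALYs undiscounted; the engine exposes
separate QALY/cost discount rates, and
`t1crc_cea.cea.PUBLISHED_TABLE_DISCOUNTING` selects that accounting
(see `docs/methods.md`).

All external inputs ship synthetically: a Gompertz life table calibrated to a
19.4-year life expectancy at 65, survival-curve calibration targets, and an
individual-level microsimulation twin used to validate the cohort engine.

## Worked example

```python
from t1crc_cea import base_case, default_life_table, default_parameter_set
from t1crc_cea.cea import PUBLISHED_TABLE_DISCOUNTING

params = default_parameter_set()           # packaged published inputs, 2019 USD
lt = default_life_table()                  # synthetic 2015-like period life table
print(base_case(params, lt, **PUBLISHED_TABLE_DISCOUNTING))
```

which prints (excerpt; `python examples/01_base_case.py` for the full run):

```
 class strategy  life_years  qalys      cost
class4       ET       17.55  16.42 42,063.92
class4       LC       18.14  16.67 65,390.26
class4       OC       18.18  16.44 68,682.96
...
class4  preferred: LC  (ICER(LC vs ET) = $94,104/QALY)
msi_h   preferred: ET  (LC dominated)
```

For class 4 (the most aggressive profile), ET is cheapest, OC yields the most
unadjusted life-years, LC the most QALYs; the incremental ratio of LC over ET
— about $94,000 per extra QALY on the synthetic life table — is what the
$100,000/QALY willingness-to-pay verdict turns on. For the indolent classes
ET simply dominates (more QALYs, lower cost).

Other entry points, one script per capability, live in `examples/`:
tornado/threshold analysis, PSA with acceptability curves, hazard-ratio
calibration, and microsimulation validation. `t1crc_cea.reporting` writes all
results as deterministic CSVs with a JSON run manifest.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from the packaged inputs — the 18-cell base case,
per-class ICER ranking at $100,000/QALY, a seeded calibration round trip, and
a 10,000-draw PSA for classes 0 and 4 — printing each result as it goes and
writing the results JSON at the end.
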