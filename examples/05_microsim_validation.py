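"""Validate the cohort engine against its individual-level Monte Carlo twin.

The microsimulation walks 100,000 individual patients through the identical
states, monthly probabilities, and payoff rules as the cohort model, so the
cohort outputs must equal the microsimulation means up to Monte Carlo error.
"""

from t1crc_cea import ClassId, Strategy, default_life_table, default_parameter_set, microsimulate, run_strategy

params = default_parameter_set()
lt = default_life_table()
strategy, cls = Strategy.LC, ClassId.class4

cohort = run_strategy(strategy, cls, params, lt)
micro = microsimulate(strategy, cls, params, lt, n=100_000, seed=20)

print(f"{strategy.value} / {cls.value} (n = {micro.n_individuals:,} individuals)")
for field, got, se, want in (
    ("life-years", micro.life_years, micro.life_years_se, cohort.life_years),
    ("QALYs", micro.qalys, micro.qalys_se, cohort.qalys),
    ("cost $", micro.cost, micro.cost_se, cohort.cost),
):
    z = (got - want) / se
    print(f"  {field:11s} microsim {got:12,.3f} +/- {se:,.3f}   "
          f"cohort {want:12,.3f}   z = {z:+.2f}")

print(
    "\nReading: |z| values within ~3 confirm the cohort model computes the "
    "exact expectation of the individual-level process."
)
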