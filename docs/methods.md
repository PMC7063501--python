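# Methods

This note records the model as implemented: its structure, the conventions
chosen where the source material was silent or ambiguous, what the synthetic
inputs do and do not emulate, and the known limitations. Nothing here states a
result the test suite or `scripts/acceptance.py` does not itself compute.

## Cohort model

**Population and horizon.** 65-year-old patients with T1N0-2M0 colorectal
cancer, one of six biomarker classes (by *APC*/*KRAS*/*TP53* genotype, or
*BRAFV600E*/MSI-H). Monthly cycles from the index procedure until death or age
100, i.e. a fixed 420-cycle horizon; survivors at age 100 are censored alive
and accrual stops.

**States.** Per strategy run: `tunnel_elective` and `tunnel_emergency`
(first post-procedure month), `post_elective` / `post_emergency` (long-term
surveillance), `recurrent_elective` / `recurrent_emergency` (absorbing until
death), and three absorbing death states (`dead_crc`, `dead_other`,
`dead_procedural`). Recurrence states are tagged by pathway so recurrence
cost and utility can be varied separately for the elective treatment and for
emergency open colectomy — required to reproduce the published one-way
analyses, which move "recurrence cost after ET" and "after LC" independently.

**Transitions.** Conversion to emergency open colectomy (ET 1.5%, LC 19%, OC
none) happens only at cycle 0. During cycle 1 the tunnels face 30-day
procedural mortality (ET 0.01%, LC 0.5%, OC and emergency OC 1%) and one month
of background mortality; the tunnel is exited on the next transition.
Competing risks within a cycle resolve in a fixed documented order —
procedural/cancer death → background death → recurrence → tunnel exit — with
each later risk conditioned on surviving the earlier ones, so transition rows
sum to one by construction. Monthly recurrence probabilities are
treatment-specific (ET 0.0012, LC 0.0007, OC and emergency 0.0006);
class-specific monthly cancer mortality (0.0012–0.0119) applies only in the
recurrent states, all other alive states face background mortality alone.
Recurrence is absorbing: there is no return to surveillance.

**Background mortality.** A period life table supplies annual death
probabilities; the monthly probability at attained age `x` is
`1 − (1 − q_x)^(1/12)` (constant hazard within each year of age). Attained age
advances every 12 cycles.

**Payoffs.** State membership is counted at cycle end; no half-cycle
correction (the bias this trades away is bounded by 1/24 year). Cycle 0
accrues no occupancy reward and the pre-procedure utility (0.88) is never
accrued — the procedure happens at time zero. Utilities: first-month values
0.82/0.81/0.79 (ET/LC/OC), 0.74 after emergency conversion; long-term values
0.95/0.93/0.91 and 0.91; recurrence 0.75. Costs: the elective procedure at
cycle 0 (ET $980, LC $37,778, OC $44,837 in 2019 USD) plus, for the converted
fraction, the published *net* emergency increments ($43,857 after ET, $7,059
after LC — exactly topping up to the OC price); expected complication
readmission costs at cycle 1 (ET: delayed bleeding $7,493; LC/OC/emergency:
the mean of delayed bleeding and bowel obstruction, $6,582) applied to
patients alive in a tunnel; $28/month surveillance in all alive non-recurrent
states (the 1-year-then-triennial colonoscopy schedule amortized, following
the per-month unit of the source inputs); $3,872/month recurrence treatment.
Discounting is monthly, `(1+r)^(−t/12)`.

**Discounting and the published table.** The published methods state 3%/yr
discounting of both costs and QALYs, but the published base-case table cannot
have discounted QALYs: its class-4 ET row pairs 17.31 undiscounted life-years
with 16.24 QALYs, while 3%-discounted life-years over that horizon are ≈ 13
and QALYs are bounded above by them. Empirically this model matches the
published costs only when costs are discounted at 3%/yr and matches the
published QALYs only when QALYs are undiscounted. The engine therefore
exposes independent `qaly_discount_rate` / `cost_discount_rate` arguments; the
config default is 0.03 for both (the stated method), and
`PUBLISHED_TABLE_DISCOUNTING` (cost 3%, QALY 0%) is the documented accounting
used wherever published numbers are reproduced.

**Structural switch.** `complications_route_to_emergency` (off by default)
implements the alternative reading of the model schematic in which ET/LC
complications also route to emergency open colectomy instead of being priced
as readmission cost events; the default treats conversion as the emergency
route and complications as cost-only events, which is what the published cost
structure implies.

## Calibration pipeline

Published class-level survival covers all cancer stages; the model needs
stage-1 monthly cause-specific mortality. Under proportional hazards with a
constant monthly baseline hazard `h0`, the all-stage class curve is a
stage-mixture of exponentials `S(t) = Σ_s w_s exp(−h0·HRc·HRs·t)` (class HRs
1.94/1.00/1.11/1.48/2.48; stage HRs 1/2.11/7.99/52.2). `h0` is fit to a target
survival curve by bounded 1-D least squares on the survival scale (robust as
S→0; a log-scale variant would up-weight the tail), and the stage-1 monthly
probability per class is `1 − exp(−h0·HRc)`. Boundary fits (e.g. a flat
target) are flagged, not trusted. MSI-H sits outside the ladder (no published
HR) and keeps its direct input rate. The stage mix is not published and is a
config input with a synthetic default. Note the published per-class rates are
not mutually proportional to the class HRs (class4/class1 = 9.9 vs HR 2.48),
so this pipeline reproduces the stated *procedure*; the packaged rates are
treated as authoritative inputs and never overwritten.

## Sensitivity analyses

**One-way / tornado.** Each non-setting parameter with a non-degenerate range
is moved to its low and high bounds; the ICER of the pair under study is
recorded and parameters are ranked by swing (unbounded swings — dominance or
preference flips at a bound — rank first; ties break on name). Threshold
search brackets sign changes of the NMB difference on a 64-point grid and
refines each by Brent root finding, equivalent to |ICER − WTP| → 0 while the
incremental QALY keeps its sign; non-monotone responses therefore yield every
crossing, not just one.

**PSA.** Parameters are sampled jointly but independently: uniform on
[low, high]; beta and gamma by moment matching with mean = base and
sd = (high − low)/(2·1.96), i.e. the printed range read as a 95% interval
(most ranges are symmetric ±25%), with draws truncated to [low, high]
(clipping; creates small point masses at the bounds). Infeasible beta moments
fall back to uniform with a logged warning. Inputs printed without a range
(class 1–3 and MSI-H mortality) and analysis settings are held fixed; the
starting-age range (55–75) is stored but only sampled on request. All three
strategies share each draw's parameter vector, the full cohort recursion runs
vectorized across draws, and the CEAC reports the fraction of draws in which
each strategy attains maximal NMB (ties to the earliest strategy in ET, LC,
OC order). Everything is reproducible from the seed.

## Synthetic inputs and what green tests establish

**Life table.** `q(age) = 1 − exp(−a·e^(b·age))` (Gompertz), b = 0.09 (a
typical adult log-hazard slope), `a` solved so life expectancy at 65 equals
19.4 years — the combined-sex value of the 2015 US period life table this
stands in for — and the table closed at age 110. It reproduces the *level* of
old-age mortality, not the exact age profile of the real table: on this table
all 18 base-case life-year cells sit ~+1.5% above the published values, and
quantities driven by strategy *differences* (the class-4 incremental QALY,
hence its ICER and the LC-cost flip point) deviate by ~10%. A real CDC-format
table (age, qx CSV) slots in without code change and is the right choice for
strict reproduction.

**Calibration targets.** Model-family curves with multiplicative lognormal
noise, re-monotonized by cumulative minimum — they validate recovery of a
known baseline hazard (1e-8 relative noiseless; within 5% under 1% noise in
≥9/10 seeds), not the shape of real Kaplan-Meier data.

**Microsimulation oracle.** A first-order Monte Carlo twin that walks
individuals through the identical event cascade and accrual rules, so the
cohort model's outputs are the exact expectations of its trajectories;
agreement within Monte Carlo error (checked at n = 200,000 on all 18 cells)
validates the cohort bookkeeping, and cannot detect an error shared by both
(mitigated by the closed-form and property tests).

## Numerical conventions

ICERs are reported to the nearest dollar; dominance decisions use unrounded
values. Extended dominance is applied iteratively until frontier ICERs
strictly increase. Exact cost-and-QALY ties keep the first strategy in
enumeration order and are flagged. Transition rows are validated to 1e-12,
trace conservation to 1e-10. The calibration bracket is [1e-8, 0.5]/month with
`xatol` 1e-14; fits within 1e-6 of the bracket ends are flagged as boundary
solutions. Probabilities entering any transition are range-checked and raise a
model error rather than being renormalized silently.

## Limitations

No adjuvant therapy, retreatment after failed initial therapy, or
indirect/productivity costs; recurrence rates vary by treatment but not by
biomarker class (no data); parameter correlations in the PSA are not modeled
(none published); the published PSA distribution parameters are unknown, so
published acceptability percentages are reproducible only qualitatively; and
the synthetic life table bounds how closely the published absolute values can
be matched (see above).
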