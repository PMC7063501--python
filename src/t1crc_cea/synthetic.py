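"""Synthetic stand-ins for every external input, plus a microsimulation oracle.

Nothing the analysis needs is downloaded: this module generates

* parametric (Gompertz) period life tables with realistic age-increasing
  mortality, standing in for the national 2015 period life table;
* noisy survival-curve calibration targets standing in for published
  Kaplan-Meier curves;
* an individual-level (first-order Monte Carlo) microsimulation that walks the
  exact event cascade of the cohort engine, used to validate the cohort
  expectations.

All artifacts are deterministic given their spec and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from . import engine
from .calibration import HazardRatios, StageMix, SurvivalCurve, stage_weighted_survival
from .engine import S, Strategy
from .life_tables import LifeTable
from .parameters import ClassId, ParameterSet

__all__ = [
    "GompertzSpec",
    "MicrosimEstimate",
    "make_life_table",
    "life_expectancy",
    "default_gompertz_spec",
    "default_life_table",
    "make_target_curve",
    "microsimulate",
]


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz mortality law: annual hazard ``a * exp(b * age)``.

    ``q_annual(age) = 1 - exp(-a * exp(b * age))``, capped so the terminal age
    closes the table with q = 1.
    """

    a: float            # baseline annual hazard at age 0
    b: float            # log-hazard slope per year of age
    cap_age: int = 110

    def __post_init__(self):
        if self.a <= 0 or self.b < 0:
            raise ValueError("need a > 0 and b >= 0")


@dataclass(frozen=True)
class MicrosimEstimate:
    """Monte Carlo means and standard errors for one (strategy, class) cell."""

    strategy: Strategy
    class_id: ClassId
    life_years: float
    life_years_se: float
    qalys: float
    qalys_se: float
    cost: float
    cost_se: float
    n_individuals: int
    seed: int


def make_life_table(spec: GompertzSpec) -> LifeTable:
    """Deterministic life table from a Gompertz spec, ages 0..cap_age."""
    ages = np.arange(spec.cap_age + 1)
    hazard = spec.a * np.exp(spec.b * ages)
    q = 1.0 - np.exp(-hazard)
    if np.any(q[: max(spec.cap_age - 20, 1)] > 0.999):
        warnings.warn("Gompertz spec implies near-certain annual death well "
                      "before the cap age; check a and b", stacklevel=2)
    q[-1] = 1.0  # close out the table at the terminal age
    return LifeTable(ages, q, provenance=f"synthetic Gompertz a={spec.a:g} b={spec.b:g}")


def life_expectancy(lt: LifeTable, from_age: int) -> float:
    """Remaining life expectancy at an exact age, by monthly compounding.

    Months lived are counted at month end (matching the cohort engine's
    end-of-cycle accrual), i.e. ``E = (1/12) * sum_t S(t)`` over monthly
    survival from ``from_age`` to the end of the table.
    """
    months = (lt.max_age - from_age + 1) * 12
    surv = 1.0
    total = 0.0
    for t in range(1, months + 1):
        age = from_age + (t - 1) // 12
        surv *= 1.0 - lt.monthly_q(age)
        total += surv
    return total / 12.0


@lru_cache(maxsize=None)
def default_gompertz_spec(
    target_le_at_65: float = 19.4, b: float = 0.09, cap_age: int = 110
) -> GompertzSpec:
    """The canonical synthetic life table spec.

    Calibrated (once, by root finding on ``a``) so remaining life expectancy at
    age 65 equals 19.4 years — the combined-sex value of the 2015 US period
    life table this generator emulates — with a typical adult log-hazard slope
    b = 0.09.
    """

    def gap(a: float) -> float:
        lt = make_life_table(GompertzSpec(a=a, b=b, cap_age=cap_age))
        return life_expectancy(lt, 65) - target_le_at_65

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # bracket endpoints probe extreme specs
        a = brentq(gap, 1e-7, 5e-3, xtol=1e-12)
    return GompertzSpec(a=a, b=b, cap_age=cap_age)


def default_life_table() -> LifeTable:
    return make_life_table(default_gompertz_spec())


def make_target_curve(
    h0: float,
    hrs: HazardRatios,
    cls: ClassId,
    mix: StageMix,
    noise_sd: float,
    seed: int,
    horizon_months: int = 120,
) -> SurvivalCurve:
    """A calibration target: the model-family curve with multiplicative noise.

    Lognormal noise is applied pointwise (t >= 1), then the curve is
    re-monotonized by cumulative minimum and clipped to (0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    base = stage_weighted_survival(h0, hrs, cls, mix, horizon_months)
    s = base.survival.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s[1:] = s[1:] * np.exp(rng.normal(0.0, noise_sd, size=s.size - 1))
    s = np.minimum.accumulate(np.clip(s, 1e-12, 1.0))
    s[0] = 1.0
    return SurvivalCurve(base.times, s)


def microsimulate(
    strategy: Strategy,
    cls: ClassId,
    params: ParameterSet,
    lt: LifeTable,
    n: int,
    seed: int,
    discount_rate: float | None = None,
    qaly_discount_rate: float | None = None,
    cost_discount_rate: float | None = None,
) -> MicrosimEstimate:
    """First-order Monte Carlo twin of the cohort engine.

    Each of ``n`` individuals walks the same states with the same monthly
    probabilities and the same within-cycle event order (procedural/CRC death,
    then background death, then recurrence, then tunnel exit), and accrues the
    same end-of-month rewards, so the cohort model's outputs are the exact
    expectations of these trajectories.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    v = params.values()
    r = float(v["discount_rate_annual"]) if discount_rate is None else float(discount_rate)
    r_q = r if qaly_discount_rate is None else float(qaly_discount_rate)
    r_c = r if cost_discount_rate is None else float(cost_discount_rate)
    sv = engine._strategy_values(strategy, v)
    s = strategy.value
    start_age = int(v["start_age_years"])
    horizon = engine.horizon_months(params)
    disc = (1.0 + r_q) ** (-np.arange(horizon + 1) / 12.0)
    disc_c = disc if r_c == r_q else (1.0 + r_c) ** (-np.arange(horizon + 1) / 12.0)

    rng = np.random.default_rng(seed)

    TUN_E, POST_E = S["tunnel_elective"], S["post_elective"]
    TUN_M, POST_M = S["tunnel_emergency"], S["post_emergency"]
    REC_E, REC_M = S["recurrent_elective"], S["recurrent_emergency"]
    DEAD_CRC, DEAD_OTH, DEAD_PROC = S["dead_crc"], S["dead_other"], S["dead_procedural"]

    p_crc = v[params.biomarker_class(cls).mortality_param]
    utilities, monthly_costs = engine._payoff_vectors(strategy, v)
    u = np.asarray(utilities, dtype=float)
    cm = np.asarray(monthly_costs, dtype=float)

    converted = rng.random(n) < sv["conv"]  # conv already folds in routed complications
    state = np.where(converted, TUN_M, TUN_E).astype(np.int8)
    charge_elective_compl = not (sv["route_complications"] and strategy.has_emergency_pathway)

    ly = np.zeros(n)
    qaly = np.zeros(n)
    cost = np.full(n, float(v[f"cost_{s}"]))
    if strategy.has_emergency_pathway:
        cost += converted * float(v[f"cost_emergency_after_{s}"])

    cc_bleed, cc_obstr = float(v["cost_compl_bleeding"]), float(v["cost_compl_obstruction"])
    cc_elective = cc_bleed if strategy is Strategy.ET else 0.5 * (cc_bleed + cc_obstr)
    cc_emergency = 0.5 * (cc_bleed + cc_obstr)

    for t in range(1, horizon + 1):
        p_bg = lt.monthly_q(start_age + (t - 1) // 12)
        u1 = rng.random(n)
        u2 = rng.random(n)
        u3 = rng.random(n)

        if t == 1:
            in_e, in_m = state == TUN_E, state == TUN_M
            die_proc = (in_e & (u1 < sv["p30_elective"])) | (in_m & (u1 < sv["p30_emergency"]))
            state[die_proc] = DEAD_PROC
            alive_tun = (state == TUN_E) | (state == TUN_M)
            die_bg = alive_tun & (u2 < p_bg)
            state[die_bg] = DEAD_OTH
            # Complication readmission for those alive in a tunnel at month end.
            compl_e = (state == TUN_E) & (u3 < v[f"p_compl_{s}"]) & charge_elective_compl
            compl_m = (state == TUN_M) & (u3 < v["p_compl_OC"])
            cost += (compl_e * cc_elective + compl_m * cc_emergency) * disc_c[1]
        else:
            in_rec = (state == REC_E) | (state == REC_M)
            die_crc = in_rec & (u1 < p_crc)
            state[die_crc] = DEAD_CRC
            alive = state < DEAD_CRC
            die_bg = alive & (u2 < p_bg)
            state[die_bg] = DEAD_OTH
            # Recurrence, then tunnel exit to the long-term state.
            for tun, post, rec, p_rec in (
                (TUN_E, POST_E, REC_E, sv["p_recur_elective"]),
                (TUN_M, POST_M, REC_M, sv["p_recur_emergency"]),
                (POST_E, POST_E, REC_E, sv["p_recur_elective"]),
                (POST_M, POST_M, REC_M, sv["p_recur_emergency"]),
            ):
                here = state == tun
                recur = here & (u3 < p_rec)
                state[recur] = rec
                if tun != post:
                    state[here & ~recur] = post

        alive = state < DEAD_CRC
        ly += alive
        qaly += u[state] * disc[t]
        cost += cm[state] * disc_c[t]

    ly /= 12.0
    qaly /= 12.0

    def mean_se(x: np.ndarray) -> tuple[float, float]:
        m = float(np.mean(x))
        se = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        return m, se

    ly_m, ly_se = mean_se(ly)
    q_m, q_se = mean_se(qaly)
    c_m, c_se = mean_se(cost)
    return MicrosimEstimate(strategy, cls, ly_m, ly_se, q_m, q_se, c_m, c_se, n, seed)
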