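"""Markov cohort engine: monthly transition matrices, cohort traces, and payoffs.

The model follows a cohort of 65-year-old patients with T1 colorectal cancer
from the index procedure until death or age 100 (420 monthly cycles). Health
states:

* ``tunnel_elective`` / ``tunnel_emergency`` — first post-procedure month
  (tunnel states carrying the 0–1 month utility and 30-day mortality);
* ``post_elective`` / ``post_emergency`` — long-term post-procedure survival
  under colonoscopic surveillance;
* ``recurrent_elective`` / ``recurrent_emergency`` — recurrent cancer, absorbing
  until death, tagged by the pathway that produced it so recurrence cost and
  utility can differ between the elective treatment and emergency colectomy;
* ``dead_crc`` / ``dead_other`` / ``dead_procedural`` — absorbing death states.

Competing risks within a cycle resolve in the documented order
procedural/CRC death -> background death -> recurrence -> tunnel exit, with
each later risk conditioned on surviving the earlier ones, so rows sum to one
by construction.

Class-specific CRC mortality applies only in the recurrent-cancer states; every
other alive state faces background (life-table) mortality alone, plus the
one-time 30-day procedural mortality in the first cycle.

All probability inputs may be scalars or equal-length 1-D arrays; the engine
broadcasts, which is how the probabilistic sensitivity analysis runs thousands
of parameter draws in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .life_tables import LifeTable
from .parameters import ClassId, ParameterSet, Strategy

__all__ = [
    "STATES",
    "ALIVE_STATES",
    "ModelError",
    "CohortTrace",
    "CEAResult",
    "initial_allocation",
    "build_transition_matrix",
    "run_cohort",
    "accumulate",
    "run_strategy",
    "horizon_months",
]

STATES = (
    "tunnel_elective",
    "post_elective",
    "tunnel_emergency",
    "post_emergency",
    "recurrent_elective",
    "recurrent_emergency",
    "dead_crc",
    "dead_other",
    "dead_procedural",
)
S = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)
ALIVE_STATES = tuple(range(6))
_DEAD = (S["dead_crc"], S["dead_other"], S["dead_procedural"])


class ModelError(ValueError):
    """Inconsistent inputs detected while building transitions."""


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy; row 0 is the initial procedure allocation."""

    occupancy: np.ndarray  # (horizon+1, n_states) or (B, horizon+1, n_states)
    strategy: Strategy
    class_id: ClassId

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[-2] - 1

    def alive(self) -> np.ndarray:
        return self.occupancy[..., list(ALIVE_STATES)].sum(axis=-1)


@dataclass(frozen=True)
class CEAResult:
    """Payoffs for one (strategy, class) run.

    ``life_years`` is undiscounted; ``qalys`` and ``cost`` are discounted at the
    configured annual rate (3%/yr by default, applied monthly).
    """

    strategy: Strategy
    class_id: ClassId
    life_years: float
    qalys: float
    cost: float


def horizon_months(params: ParameterSet) -> int:
    return int(round((params.value("max_age_years") - params.value("start_age_years")) * 12))


def _strategy_values(strategy: Strategy, v: Mapping[str, Union[float, np.ndarray]]):
    """Resolve the per-strategy parameter names the transitions need."""
    s = strategy.value
    conv = v[f"p_convert_{s}"] if strategy.has_emergency_pathway else 0.0
    # Alternative structural reading (off by default): procedural complications
    # of ET/LC also route to emergency open colectomy instead of being priced
    # as readmission cost events.
    route = bool(np.any(np.asarray(v.get("complications_route_to_emergency", 0)) > 0))
    if route and strategy.has_emergency_pathway:
        conv = conv + (1 - np.asarray(conv, dtype=float)) * np.asarray(
            v[f"p_compl_{s}"], dtype=float
        )
    return {
        "conv": conv,
        "route_complications": route,
        "p30_elective": v[f"p_mort30_{s}"],
        "p30_emergency": v["p_mort30_OC"],
        "p_recur_elective": v[f"p_recur_{s}"],
        # Emergency colectomy patients behave like elective open colectomy.
        "p_recur_emergency": v["p_recur_OC"],
    }


def initial_allocation(
    strategy: Strategy, params: ParameterSet, values: Mapping[str, float] | None = None
) -> np.ndarray:
    """Cycle-0 cohort split between the elective and emergency tunnels.

    The converted fraction (intra-procedural conversion to emergency open
    colectomy) starts in the emergency tunnel; conversion only happens at the
    index procedure. 30-day procedural deaths are applied during cycle 1, not
    here.
    """
    v = values if values is not None else params.values()
    sv = _strategy_values(strategy, v)
    conv = np.asarray(sv["conv"], dtype=float)
    x0 = np.zeros(np.broadcast(conv).shape + (N_STATES,))
    x0[..., S["tunnel_elective"]] = 1.0 - conv
    x0[..., S["tunnel_emergency"]] = conv
    return x0 if x0.ndim > 1 else x0.reshape(N_STATES)


def _check_prob(name: str, p) -> None:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ModelError(f"{name} outside [0, 1]: inconsistent inputs")


def build_transition_matrix(
    strategy: Strategy,
    cls: ClassId,
    cycle_index: int,
    params: ParameterSet,
    lt: LifeTable,
    values: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Row-stochastic transition matrix for the step into ``cycle_index``.

    ``cycle_index`` counts from 1; the matrix moves occupancy from cycle
    ``cycle_index - 1`` to ``cycle_index``. The attained age during that month
    is ``start_age + (cycle_index - 1) // 12`` years.
    """
    if cycle_index < 1:
        raise ModelError("cycle_index counts from 1")
    v = values if values is not None else params.values()
    sv = _strategy_values(strategy, v)
    start_age = int(v["start_age_years"])
    age = start_age + (cycle_index - 1) // 12
    if age > int(v["max_age_years"]):
        raise ModelError(f"attained age {age} beyond the model's maximum age")
    p_bg = lt.monthly_q(age)
    p_crc = v[params.biomarker_class(cls).mortality_param]
    for nm, p in (("p_bg", p_bg), ("p_crc", p_crc),
                  ("p30_elective", sv["p30_elective"]), ("p30_emergency", sv["p30_emergency"]),
                  ("p_recur_elective", sv["p_recur_elective"]),
                  ("p_recur_emergency", sv["p_recur_emergency"])):
        _check_prob(nm, p)

    m = np.zeros((N_STATES, N_STATES))
    for d in _DEAD:
        m[d, d] = 1.0

    def tunnel_row(i_tun, i_post, i_rec, p30, p_rec):
        if cycle_index == 1:
            # 30-day window: procedural death, then background death; survivors
            # stay in the tunnel so the first post-procedure month is counted.
            m[i_tun, S["dead_procedural"]] = p30
            m[i_tun, S["dead_other"]] = (1 - p30) * p_bg
            m[i_tun, i_tun] = (1 - p30) * (1 - p_bg)
        else:
            # Tunnel exit: background death -> recurrence -> long-term state.
            m[i_tun, S["dead_other"]] = p_bg
            m[i_tun, i_rec] = (1 - p_bg) * p_rec
            m[i_tun, i_post] = (1 - p_bg) * (1 - p_rec)

    tunnel_row(S["tunnel_elective"], S["post_elective"], S["recurrent_elective"],
               sv["p30_elective"], sv["p_recur_elective"])
    tunnel_row(S["tunnel_emergency"], S["post_emergency"], S["recurrent_emergency"],
               sv["p30_emergency"], sv["p_recur_emergency"])

    for i_post, i_rec, p_rec in (
        (S["post_elective"], S["recurrent_elective"], sv["p_recur_elective"]),
        (S["post_emergency"], S["recurrent_emergency"], sv["p_recur_emergency"]),
    ):
        m[i_post, S["dead_other"]] = p_bg
        m[i_post, i_rec] = (1 - p_bg) * p_rec
        m[i_post, i_post] = (1 - p_bg) * (1 - p_rec)

    for i_rec in (S["recurrent_elective"], S["recurrent_emergency"]):
        m[i_rec, S["dead_crc"]] = p_crc
        m[i_rec, S["dead_other"]] = (1 - p_crc) * p_bg
        m[i_rec, i_rec] = (1 - p_crc) * (1 - p_bg)

    rowsum = m.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-12):
        raise ModelError("transition rows do not sum to 1")
    return m


def run_cohort(
    strategy: Strategy,
    cls: ClassId,
    params: ParameterSet,
    lt: LifeTable,
    horizon: int | None = None,
    values: Mapping[str, Union[float, np.ndarray]] | None = None,
) -> CohortTrace:
    """Propagate the cohort over monthly cycles and return the full trace.

    With scalar parameter values this multiplies explicit transition matrices.
    With array-valued parameters (shape ``(B,)``) it runs all B parameter draws
    simultaneously with the identical update equations; the two paths agree to
    machine precision.
    """
    v = values if values is not None else params.values()
    if horizon is None:
        start = v["start_age_years"]
        horizon = int(round((float(np.min(np.asarray(v["max_age_years"])))
                             - float(np.max(np.asarray(start)))) * 12))
    batched = any(np.ndim(val) > 0 for val in v.values())
    if not batched:
        x = initial_allocation(strategy, params, v)
        occ = np.empty((horizon + 1, N_STATES))
        occ[0] = x
        for t in range(1, horizon + 1):
            mtx = build_transition_matrix(strategy, cls, t, params, lt, v)
            occ[t] = occ[t - 1] @ mtx
        return CohortTrace(occ, strategy, cls)
    return _run_cohort_batch(strategy, cls, params, lt, horizon, v)


def _run_cohort_batch(strategy, cls, params, lt, horizon, v) -> CohortTrace:
    sv = _strategy_values(strategy, v)
    # Broadcast every needed value to a common batch shape.
    conv = np.asarray(sv["conv"], dtype=float)
    p30e = np.asarray(sv["p30_elective"], dtype=float)
    p30m = np.asarray(sv["p30_emergency"], dtype=float)
    pre = np.asarray(sv["p_recur_elective"], dtype=float)
    prm = np.asarray(sv["p_recur_emergency"], dtype=float)
    p_crc = np.asarray(v[params.biomarker_class(cls).mortality_param], dtype=float)
    shape = np.broadcast(conv, p30e, p30m, pre, prm, p_crc).shape or (1,)
    conv, p30e, p30m, pre, prm, p_crc = (
        np.broadcast_to(a, shape).astype(float) for a in (conv, p30e, p30m, pre, prm, p_crc)
    )
    for nm, p in (("conversion", conv), ("p30", p30e), ("p30_em", p30m),
                  ("recurrence", pre), ("recurrence_em", prm), ("crc mortality", p_crc)):
        _check_prob(nm, p)

    start_age = int(np.asarray(v["start_age_years"]).flat[0])
    occ = np.zeros(shape + (horizon + 1, N_STATES))
    occ[..., 0, S["tunnel_elective"]] = 1.0 - conv
    occ[..., 0, S["tunnel_emergency"]] = conv

    for t in range(1, horizon + 1):
        p_bg = lt.monthly_q(start_age + (t - 1) // 12)
        x = occ[..., t - 1, :]
        y = occ[..., t, :]
        tun_e, tun_m = x[..., S["tunnel_elective"]], x[..., S["tunnel_emergency"]]
        post_e, post_m = x[..., S["post_elective"]], x[..., S["post_emergency"]]
        rec_e, rec_m = x[..., S["recurrent_elective"]], x[..., S["recurrent_emergency"]]

        if t == 1:
            y[..., S["tunnel_elective"]] = tun_e * (1 - p30e) * (1 - p_bg)
            y[..., S["tunnel_emergency"]] = tun_m * (1 - p30m) * (1 - p_bg)
            y[..., S["dead_procedural"]] = x[..., S["dead_procedural"]] + tun_e * p30e + tun_m * p30m
            dead_other_new = (tun_e * (1 - p30e) + tun_m * (1 - p30m)) * p_bg
            y[..., S["post_elective"]] = post_e
            y[..., S["post_emergency"]] = post_m
            y[..., S["recurrent_elective"]] = rec_e
            y[..., S["recurrent_emergency"]] = rec_m
            y[..., S["dead_crc"]] = x[..., S["dead_crc"]]
        else:
            surv_e = tun_e * (1 - p_bg)
            surv_m = tun_m * (1 - p_bg)
            y[..., S["tunnel_elective"]] = 0.0
            y[..., S["tunnel_emergency"]] = 0.0
            y[..., S["post_elective"]] = (post_e * (1 - p_bg) + surv_e) * (1 - pre)
            y[..., S["post_emergency"]] = (post_m * (1 - p_bg) + surv_m) * (1 - prm)
            y[..., S["recurrent_elective"]] = (
                rec_e * (1 - p_crc) * (1 - p_bg) + (post_e * (1 - p_bg) + surv_e) * pre
            )
            y[..., S["recurrent_emergency"]] = (
                rec_m * (1 - p_crc) * (1 - p_bg) + (post_m * (1 - p_bg) + surv_m) * prm
            )
            y[..., S["dead_crc"]] = x[..., S["dead_crc"]] + (rec_e + rec_m) * p_crc
            dead_other_new = (tun_e + tun_m + post_e + post_m) * p_bg + (
                rec_e + rec_m
            ) * (1 - p_crc) * p_bg
            y[..., S["dead_procedural"]] = x[..., S["dead_procedural"]]
        y[..., S["dead_other"]] = x[..., S["dead_other"]] + dead_other_new

    return CohortTrace(occ, strategy, cls)


def _payoff_vectors(strategy: Strategy, v: Mapping[str, Union[float, np.ndarray]]):
    s = strategy.value
    utilities = [
        v[f"u_{s}_m1"], v[f"u_{s}_post"],
        v["u_emergency_m1"], v["u_emergency_post"],
        v[f"u_recur_{s}"], v["u_recur_OC"],
        0.0, 0.0, 0.0,
    ]
    c_surv = v["cost_surveillance_monthly"]
    monthly_costs = [
        c_surv, c_surv, c_surv, c_surv,
        v[f"cost_recur_treatment_{s}"], v["cost_recur_treatment_OC"],
        0.0, 0.0, 0.0,
    ]
    return utilities, monthly_costs


def accumulate(
    trace: CohortTrace,
    strategy: Strategy,
    cls: ClassId,
    params: ParameterSet,
    values: Mapping[str, Union[float, np.ndarray]] | None = None,
    discount_rate: float | None = None,
    qaly_discount_rate: float | None = None,
    cost_discount_rate: float | None = None,
) -> CEAResult:
    """Fold a cohort trace into life-years, discounted QALYs, and discounted cost.

    State membership is counted at cycle end (no half-cycle correction); cycle 0
    accrues no occupancy reward. One-time costs: procedure (plus the net
    emergency-colectomy increment for the converted fraction) at cycle 0, and
    expected complication-readmission costs at cycle 1 for patients alive in a
    tunnel state. Monthly costs: surveillance in non-recurrent alive states,
    recurrence treatment in the recurrent states. Discounting is monthly at
    ``(1 + r) ** (-t / 12)`` with t in months; QALYs and costs can be
    discounted at different rates (the published base-case tables discount
    costs at 3%/yr but leave QALYs undiscounted — see docs/methods.md).
    """
    if strategy is not trace.strategy or cls is not trace.class_id:
        raise ModelError("trace does not match the requested strategy/class")
    v = values if values is not None else params.values()
    sv = _strategy_values(strategy, v)
    r_default = float(v["discount_rate_annual"]) if discount_rate is None else float(discount_rate)
    r_q = r_default if qaly_discount_rate is None else float(qaly_discount_rate)
    r_c = r_default if cost_discount_rate is None else float(cost_discount_rate)

    occ = trace.occupancy
    H = trace.n_cycles
    t = np.arange(H + 1)
    disc = (1.0 + r_q) ** (-t / 12.0)
    disc_c = disc if r_c == r_q else (1.0 + r_c) ** (-t / 12.0)

    alive = trace.alive()
    life_years = (alive[..., 1:].sum(axis=-1)) / 12.0

    utilities, monthly_costs = _payoff_vectors(strategy, v)
    u = np.stack([np.broadcast_to(np.asarray(x, float), occ.shape[:-2] or ())
                  for x in utilities], axis=-1)
    cm = np.stack([np.broadcast_to(np.asarray(x, float), occ.shape[:-2] or ())
                   for x in monthly_costs], axis=-1)

    qaly_by_cycle = (occ * u[..., None, :]).sum(axis=-1)
    qalys = (qaly_by_cycle[..., 1:] * disc[1:]).sum(axis=-1) / 12.0

    cost_by_cycle = (occ * cm[..., None, :]).sum(axis=-1)
    cost = (cost_by_cycle[..., 1:] * disc_c[1:]).sum(axis=-1)

    s = strategy.value
    proc = np.asarray(v[f"cost_{s}"], dtype=float)
    conv = np.asarray(sv["conv"], dtype=float)
    if strategy.has_emergency_pathway:
        proc = proc + conv * np.asarray(v[f"cost_emergency_after_{s}"], dtype=float)
    cost = cost + proc

    cc_bleed = np.asarray(v["cost_compl_bleeding"], dtype=float)
    cc_obstr = np.asarray(v["cost_compl_obstruction"], dtype=float)
    cc_elective = cc_bleed if strategy is Strategy.ET else 0.5 * (cc_bleed + cc_obstr)
    cc_emergency = 0.5 * (cc_bleed + cc_obstr)
    # When complications route to the emergency pathway, the elective-side
    # readmission charge is replaced by the emergency procedure itself.
    elective_chargeable = 0.0 if (
        sv["route_complications"] and strategy.has_emergency_pathway
    ) else 1.0
    compl = (
        occ[..., 1, S["tunnel_elective"]] * np.asarray(v[f"p_compl_{s}"], float)
        * cc_elective * elective_chargeable
        + occ[..., 1, S["tunnel_emergency"]] * np.asarray(v["p_compl_OC"], float) * cc_emergency
    )
    cost = cost + compl * disc_c[1]

    if np.ndim(life_years) == 0:
        return CEAResult(strategy, cls, float(life_years), float(qalys), float(cost))
    return CEAResult(strategy, cls, life_years, qalys, cost)


def run_strategy(
    strategy: Strategy,
    cls: ClassId,
    params: ParameterSet,
    lt: LifeTable,
    values: Mapping[str, Union[float, np.ndarray]] | None = None,
    discount_rate: float | None = None,
    qaly_discount_rate: float | None = None,
    cost_discount_rate: float | None = None,
) -> CEAResult:
    """Convenience wrapper: run the cohort and accumulate payoffs in one call."""
    v = values if values is not None else params.values()
    trace = run_cohort(strategy, cls, params, lt, values=v)
    return accumulate(trace, strategy, cls, params, values=v,
                      discount_rate=discount_rate,
                      qaly_discount_rate=qaly_discount_rate,
                      cost_discount_rate=cost_discount_rate)
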