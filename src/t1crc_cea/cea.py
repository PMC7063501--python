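"""Cost-effectiveness analysis layer.

Base-case comparison of the three strategies per biomarker class, dominance and
ICER ranking on the efficiency frontier, net monetary benefit, one-way
(deterministic) sensitivity analysis with tornado ranking and threshold search,
and probabilistic sensitivity analysis with cost-effectiveness acceptability
curves.

Conventions: strategies are ordered by ascending cost; strictly dominated
options (more costly, no more effective) and extendedly dominated options
(ICER above that of a more effective alternative) are excluded before ICERs
are reported. The preferred strategy at a willingness-to-pay (WTP) threshold is
the most effective frontier option whose ICER does not exceed WTP — identical,
draw by draw, to picking the argmax of net monetary benefit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .engine import CEAResult, run_strategy, run_cohort, accumulate
from .life_tables import LifeTable
from .parameters import ClassId, Parameter, ParameterSet, Strategy

__all__ = [
    "ICERRow",
    "ICERTable",
    "OneWayResult",
    "PSAResult",
    "PUBLISHED_TABLE_DISCOUNTING",
    "base_case",
    "rank_and_icer",
    "nmb",
    "one_way",
    "tornado",
    "sample_parameter",
    "sample_parameter_set",
    "run_psa",
]

logger = logging.getLogger(__name__)

_STRATEGY_ORDER = (Strategy.ET, Strategy.LC, Strategy.OC)

# The published base-case tables discount costs at 3%/yr but (demonstrably, see
# docs/methods.md) leave QALYs and life-years undiscounted; passing this mapping
# as keyword arguments reproduces that accounting.
PUBLISHED_TABLE_DISCOUNTING = {"qaly_discount_rate": 0.0, "cost_discount_rate": 0.03}


# ---------------------------------------------------------------------------
# Base case
# ---------------------------------------------------------------------------

def base_case(
    params: ParameterSet,
    lt: LifeTable,
    classes: Sequence[ClassId] | None = None,
    strategies: Sequence[Strategy] | None = None,
    discount_rate: float | None = None,
    qaly_discount_rate: float | None = None,
    cost_discount_rate: float | None = None,
) -> pd.DataFrame:
    """Deterministic run of every (class, strategy) cell.

    Returns a DataFrame with columns ``class, strategy, life_years, qalys,
    cost`` (18 rows for the full model).
    """
    classes = list(classes) if classes is not None else list(ClassId)
    strategies = list(strategies) if strategies is not None else list(_STRATEGY_ORDER)
    rows = []
    for cls in classes:
        for strat in strategies:
            res = run_strategy(strat, cls, params, lt, discount_rate=discount_rate,
                               qaly_discount_rate=qaly_discount_rate,
                               cost_discount_rate=cost_discount_rate)
            rows.append(
                {"class": cls.value, "strategy": strat.value,
                 "life_years": res.life_years, "qalys": res.qalys, "cost": res.cost}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dominance / ICER ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICERRow:
    strategy: Strategy
    cost: float
    qalys: float
    status: str                 # on_frontier | dominated | extended_dominated
    icer: float | None          # vs previous frontier strategy; None for cheapest


@dataclass(frozen=True)
class ICERTable:
    class_id: ClassId | None
    rows: tuple[ICERRow, ...]   # ascending cost
    wtp: float
    preferred: Strategy
    tie_flagged: bool = False

    def frontier(self) -> list[ICERRow]:
        return [r for r in self.rows if r.status == "on_frontier"]

    def icer_of(self, strategy: Strategy) -> float | None:
        for r in self.rows:
            if r.strategy is strategy:
                return r.icer
        raise KeyError(strategy)


def nmb(result: CEAResult, wtp: float) -> float:
    """Net monetary benefit, QALYs * WTP - cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return result.qalys * wtp - result.cost


def rank_and_icer(
    results: Iterable[CEAResult], wtp: float, class_id: ClassId | None = None
) -> ICERTable:
    """Dominance analysis and incremental ratios for one class.

    Strategies are sorted by ascending cost (ties broken by the fixed
    enumeration order ET, LC, OC). Strictly dominated options are removed, then
    extended dominance is applied until frontier ICERs increase strictly.
    Dominance is decided on unrounded values; an exact cost+QALY tie keeps the
    first strategy in enumeration order and flags the tie.
    """
    res = list(results)
    if len(res) < 2:
        raise ValueError("need at least two strategies to rank")
    if class_id is None:
        class_id = res[0].class_id
    order = {s: i for i, s in enumerate(_STRATEGY_ORDER)}
    res.sort(key=lambda r: (r.cost, order[r.strategy]))

    status = {r.strategy: "on_frontier" for r in res}
    tie_flagged = False

    # Exact ties: keep the first in enumeration order, drop the rest.
    for i, r in enumerate(res):
        for prev in res[:i]:
            if status[prev.strategy] != "on_frontier":
                continue
            if r.cost == prev.cost and r.qalys == prev.qalys:
                status[r.strategy] = "dominated"
                tie_flagged = True

    # Strict dominance: costs are sorted ascending, so any option with QALYs
    # not exceeding the best cheaper-or-equal alternative is dominated.
    best_q = -math.inf
    for r in res:
        if status[r.strategy] != "on_frontier":
            continue
        if r.qalys <= best_q:
            status[r.strategy] = "dominated"
        else:
            best_q = r.qalys

    # Extended dominance: remove frontier members whose ICER exceeds that of
    # the next, more effective frontier member, until ICERs increase.
    while True:
        frontier = [r for r in res if status[r.strategy] == "on_frontier"]
        icers = [
            (frontier[i].cost - frontier[i - 1].cost)
            / (frontier[i].qalys - frontier[i - 1].qalys)
            for i in range(1, len(frontier))
        ]
        removed = False
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                status[frontier[i + 1].strategy] = "extended_dominated"
                removed = True
                break
        if not removed:
            break

    frontier = [r for r in res if status[r.strategy] == "on_frontier"]
    icer_map: dict[Strategy, float | None] = {frontier[0].strategy: None}
    for i in range(1, len(frontier)):
        icer_map[frontier[i].strategy] = (
            (frontier[i].cost - frontier[i - 1].cost)
            / (frontier[i].qalys - frontier[i - 1].qalys)
        )

    preferred = frontier[0].strategy
    for r in frontier[1:]:
        if icer_map[r.strategy] <= wtp:
            preferred = r.strategy

    rows = tuple(
        ICERRow(r.strategy, r.cost, r.qalys, status[r.strategy],
                icer_map.get(r.strategy)) for r in res
    )
    return ICERTable(class_id, rows, wtp, preferred, tie_flagged)


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneWayResult:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    base_icer: float
    spread: float
    thresholds: tuple[float, ...] = ()   # parameter values where preference flips


def _pair_icer(res_by_strategy: dict[Strategy, CEAResult], pair: tuple[Strategy, Strategy]) -> float:
    """ICER of pair[1] vs pair[0] (signed; +/-inf when QALYs tie or reverse)."""
    a, b = res_by_strategy[pair[0]], res_by_strategy[pair[1]]
    dq = b.qalys - a.qalys
    dc = b.cost - a.cost
    if dq == 0:
        return math.inf if dc > 0 else (-math.inf if dc < 0 else 0.0)
    icer = dc / dq
    # More effective and cheaper (dominant), or less effective and costlier
    # (dominated): the ratio is not a price per QALY gained; report signed inf
    # so sensitivity spreads rank these flips above any finite swing.
    if dq > 0 and dc < 0:
        return -math.inf
    if dq < 0:
        return math.inf if dc > 0 else -math.inf
    return icer


def one_way(
    param_name: str,
    cls: ClassId,
    pair: tuple[Strategy, Strategy],
    params: ParameterSet,
    lt: LifeTable,
    wtp: float,
    discount_rate: float | None = None,
    qaly_discount_rate: float | None = None,
    cost_discount_rate: float | None = None,
    grid_points: int = 64,
) -> OneWayResult:
    """Vary one parameter across its range; report ICERs and preference flips.

    The ICER of ``pair[1]`` vs ``pair[0]`` is recomputed at the low and high
    bounds. If the preferred strategy (argmax NMB at ``wtp``) flips anywhere in
    the range, each crossing of the NMB difference is located on a
    ``grid_points`` grid and refined by root finding, which is equivalent to
    |ICER - wtp| -> 0 while the incremental QALYs keep their sign.
    """
    p = params[param_name]

    def run_at(x: float) -> dict[Strategy, CEAResult]:
        ps = params.with_value(param_name, x)
        return {s: run_strategy(s, cls, ps, lt, discount_rate=discount_rate,
                                qaly_discount_rate=qaly_discount_rate,
                                cost_discount_rate=cost_discount_rate)
                for s in pair}

    def nmb_diff(x: float) -> float:
        r = run_at(x)
        return nmb(r[pair[1]], wtp) - nmb(r[pair[0]], wtp)

    icer_lo = _pair_icer(run_at(p.low), pair)
    icer_hi = _pair_icer(run_at(p.high), pair)
    base_icer = _pair_icer(run_at(p.base), pair)
    if math.isinf(icer_lo) or math.isinf(icer_hi):
        spread = math.inf
    else:
        spread = abs(icer_hi - icer_lo)

    thresholds: list[float] = []
    if p.low < p.high:
        xs = np.linspace(p.low, p.high, grid_points)
        gs = [nmb_diff(x) for x in xs]
        for i in range(len(xs) - 1):
            if gs[i] == 0.0:
                thresholds.append(float(xs[i]))
            elif gs[i] * gs[i + 1] < 0:
                thresholds.append(float(brentq(nmb_diff, xs[i], xs[i + 1],
                                               xtol=1e-12, rtol=1e-14)))
        if gs[-1] == 0.0:
            thresholds.append(float(xs[-1]))

    return OneWayResult(
        parameter=param_name, low=p.low, high=p.high,
        icer_at_low=icer_lo, icer_at_high=icer_hi, base_icer=base_icer,
        spread=spread, thresholds=tuple(thresholds),
    )


def tornado(
    cls: ClassId,
    pair: tuple[Strategy, Strategy],
    params: ParameterSet,
    lt: LifeTable,
    wtp: float,
    top_k: int = 10,
    param_names: Sequence[str] | None = None,
    discount_rate: float | None = None,
    qaly_discount_rate: float | None = None,
    cost_discount_rate: float | None = None,
    find_thresholds: bool = False,
) -> list[OneWayResult]:
    """Rank parameters by one-way ICER spread, largest first.

    Varies every non-setting parameter with a non-degenerate range (or the
    explicit ``param_names``). Infinite spreads (preference/dominance flips at a
    bound) rank above any finite swing; ties break on parameter name.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if param_names is None:
        param_names = [
            n for n, p in params.parameters.items()
            if p.role != "setting" and p.low < p.high
        ]
    results = [
        one_way(n, cls, pair, params, lt, wtp, discount_rate=discount_rate,
                qaly_discount_rate=qaly_discount_rate,
                cost_discount_rate=cost_discount_rate,
                grid_points=2 if not find_thresholds else 64)
        for n in param_names
    ]
    results.sort(key=lambda r: (-r.spread if math.isfinite(r.spread) else -math.inf,
                                r.parameter))
    results.sort(key=lambda r: 0 if math.isinf(r.spread) else 1)
    return results[:top_k]


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def sample_parameter(param: Parameter, rng: np.random.Generator, size: int | None = None):
    """Draw from a parameter's uncertainty distribution.

    The printed range is read as a 95% interval for beta/gamma moment matching
    (mean = base, sd = (high - low) / (2 * 1.96)); uniform ranges are hard
    bounds. Draws are truncated (clipped) to [low, high]. If beta moments are
    infeasible for the mean, sampling falls back to uniform with a logged
    warning.
    """
    if param.family == "fixed":
        return param.base if size is None else np.full(size, param.base)
    if param.family == "uniform":
        draws = rng.uniform(param.low, param.high, size=size)
        return draws
    mean = param.base
    sd = (param.high - param.low) / (2.0 * 1.96)
    if sd <= 0:
        return param.base if size is None else np.full(size, param.base)
    var = sd * sd
    if param.family == "beta":
        if var >= mean * (1.0 - mean) or not (0.0 < mean < 1.0):
            logger.warning(
                "beta moments infeasible for %s (mean=%g, sd=%g); falling back to uniform",
                param.name, mean, sd,
            )
            return rng.uniform(param.low, param.high, size=size)
        nu = mean * (1.0 - mean) / var - 1.0
        draws = rng.beta(mean * nu, (1.0 - mean) * nu, size=size)
    elif param.family == "gamma":
        shape = mean * mean / var
        scale = var / mean
        draws = rng.gamma(shape, scale, size=size)
    else:  # pragma: no cover - families validated upstream
        raise ValueError(f"unknown family {param.family}")
    return np.clip(draws, param.low, param.high)


def sample_parameter_set(
    params: ParameterSet,
    rng: np.random.Generator,
    n_draws: int,
    include_settings: bool = False,
) -> dict[str, np.ndarray | float]:
    """Jointly sample all non-fixed parameters (independently), as draw vectors.

    Settings (discount rate, ages, WTP) stay at base unless
    ``include_settings`` — the base case fixes the starting age at 65 even
    though an age range is listed among the varied inputs.
    """
    values: dict[str, np.ndarray | float] = {}
    for name, p in params.parameters.items():
        if p.family == "fixed" or (p.role == "setting" and not include_settings):
            values[name] = p.base
        else:
            values[name] = sample_parameter(p, rng, size=n_draws)
    return values


@dataclass(frozen=True)
class PSAResult:
    class_id: ClassId
    seed: int
    n_draws: int
    wtp_grid: np.ndarray
    draws: pd.DataFrame          # per draw: cost_<s>, qalys_<s> per strategy
    ceac: pd.DataFrame           # per wtp: acceptability per strategy
    strategies: tuple[Strategy, ...] = field(default=_STRATEGY_ORDER)


def run_psa(
    params: ParameterSet,
    lt: LifeTable,
    cls: ClassId,
    strategies: Sequence[Strategy] | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    wtp_grid: Sequence[float] | None = None,
    discount_rate: float | None = None,
    qaly_discount_rate: float | None = None,
    cost_discount_rate: float | None = None,
) -> PSAResult:
    """Monte Carlo PSA: jointly sampled parameters, per-draw model runs, CEAC.

    All strategies share each draw's parameter vector (common random
    parameters). The CEAC at each WTP is the fraction of draws in which a
    strategy attains the maximal net monetary benefit (ties go to the earliest
    strategy in the fixed enumeration order). Reproducible given the seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    strategies = tuple(strategies) if strategies is not None else _STRATEGY_ORDER
    if wtp_grid is None:
        wtp_grid = np.arange(0, 200_001, 10_000, dtype=float)
    wtp_grid = np.asarray(wtp_grid, dtype=float)

    rng = np.random.default_rng(seed)
    values = sample_parameter_set(params, rng, n_draws)

    draws = pd.DataFrame(index=pd.RangeIndex(n_draws, name="draw"))
    qalys = np.empty((len(strategies), n_draws))
    costs = np.empty((len(strategies), n_draws))
    for i, strat in enumerate(strategies):
        res = run_strategy(strat, cls, params, lt, values=values,
                           discount_rate=discount_rate,
                           qaly_discount_rate=qaly_discount_rate,
                           cost_discount_rate=cost_discount_rate)
        qalys[i] = np.broadcast_to(res.qalys, (n_draws,))
        costs[i] = np.broadcast_to(res.cost, (n_draws,))
        draws[f"qalys_{strat.value}"] = qalys[i]
        draws[f"cost_{strat.value}"] = costs[i]

    ceac_rows = []
    for wtp in wtp_grid:
        nmb_matrix = qalys * wtp - costs           # (n_strategies, n_draws)
        best = np.argmax(nmb_matrix, axis=0)       # argmax -> first max wins ties
        row = {"wtp": wtp}
        for i, strat in enumerate(strategies):
            row[f"p_{strat.value}"] = float(np.mean(best == i))
        ceac_rows.append(row)
    ceac = pd.DataFrame(ceac_rows)

    return PSAResult(cls, seed, n_draws, wtp_grid, draws, ceac, strategies)
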