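"""Analysis layer: dominance/ICER ranking, NMB, one-way DSA, sampling, PSA."""

import logging
import math

import numpy as np
import pytest

from t1crc_cea import (
    CEAResult,
    ClassId,
    Strategy,
    nmb,
    one_way,
    rank_and_icer,
    run_psa,
    sample_parameter,
    tornado,
)
from t1crc_cea.parameters import Parameter

from conftest import PUBLISHED


def _res(strategy, cost, qalys, cls=ClassId.class4):
    return CEAResult(strategy, cls, life_years=qalys, qalys=qalys, cost=cost)


# ---------------------------------------------------------------------------
# Ranking and ICERs
# ---------------------------------------------------------------------------

def test_icer_from_published_class4_cells():
    table = rank_and_icer(
        [_res(Strategy.ET, 41_444, 16.24), _res(Strategy.LC, 65_235, 16.45),
         _res(Strategy.OC, 68_619, 16.22)],
        wtp=100_000,
    )
    assert round(table.icer_of(Strategy.LC)) == 113_290
    assert table.preferred is Strategy.ET
    assert table.icer_of(Strategy.OC) is None  # dominated: costlier, fewer QALYs


def test_dominated_strategy_excluded_class1_cells():
    table = rank_and_icer(
        [_res(Strategy.ET, 77_785, 17.22, ClassId.class1),
         _res(Strategy.LC, 86_737, 17.03, ClassId.class1),
         _res(Strategy.OC, 87_609, 16.74, ClassId.class1)],
        wtp=100_000,
    )
    statuses = {r.strategy: r.status for r in table.rows}
    assert statuses[Strategy.OC] == "dominated"
    assert statuses[Strategy.LC] == "dominated"
    assert table.preferred is Strategy.ET


def test_extended_dominance():
    # B's ICER vs A (10k/0.1=100k) exceeds C's vs B (2k/0.4=5k): B is ruled
    # out by extended dominance and C is compared with A directly.
    table = rank_and_icer(
        [_res(Strategy.ET, 10_000, 1.0), _res(Strategy.LC, 20_000, 1.1),
         _res(Strategy.OC, 22_000, 1.5)],
        wtp=100_000,
    )
    assert table.icer_of(Strategy.LC) is None
    statuses = {r.strategy: r.status for r in table.rows}
    assert statuses[Strategy.LC] == "extended_dominated"
    assert table.icer_of(Strategy.OC) == pytest.approx(12_000 / 0.5)


def test_identical_strategies_tie_flagged():
    table = rank_and_icer(
        [_res(Strategy.ET, 10_000, 1.0), _res(Strategy.LC, 10_000, 1.0)],
        wtp=100_000,
    )
    assert table.tie_flagged
    statuses = {r.strategy: r.status for r in table.rows}
    assert statuses[Strategy.ET] == "on_frontier"
    assert statuses[Strategy.LC] == "dominated"


def test_frontier_icers_strictly_increase(base_case_published, params):
    for cls in ClassId:
        sub = base_case_published[base_case_published["class"] == cls.value]
        results = [
            CEAResult(Strategy(r.strategy), cls, r.life_years, r.qalys, r.cost)
            for r in sub.itertuples()
        ]
        table = rank_and_icer(results, wtp=100_000)
        icers = [r.icer for r in table.frontier() if r.icer is not None]
        assert all(a < b for a, b in zip(icers, icers[1:]))


# ---------------------------------------------------------------------------
# Net monetary benefit
# ---------------------------------------------------------------------------

def test_nmb_at_zero_wtp_is_negative_cost():
    assert nmb(_res(Strategy.ET, 41_444, 16.24), 0) == -41_444


def test_nmb_published_class4_et_at_100k():
    assert nmb(_res(Strategy.ET, 41_444, 16.24), 100_000) == pytest.approx(1_582_556)


@pytest.mark.parametrize("wtp", [0, 10_000, 50_000, 100_000, 150_000, 200_000])
def test_nmb_argmax_agrees_with_icer_preference(base_case_published, wtp):
    """Picking the frontier option by ICER thresholding equals argmax NMB."""
    for cls in ClassId:
        sub = base_case_published[base_case_published["class"] == cls.value]
        results = [
            CEAResult(Strategy(r.strategy), cls, r.life_years, r.qalys, r.cost)
            for r in sub.itertuples()
        ]
        table = rank_and_icer(results, wtp=wtp)
        by_nmb = max(results, key=lambda r: nmb(r, wtp))
        assert table.preferred is by_nmb.strategy


# ---------------------------------------------------------------------------
# One-way sensitivity analysis and tornado
# ---------------------------------------------------------------------------

def test_one_way_zero_effect_parameter(params, lt):
    """The pre-procedure utility is never accrued: zero spread, no threshold."""
    ow = one_way("u_pre", ClassId.class4, (Strategy.ET, Strategy.LC),
                 params, lt, wtp=100_000, grid_points=4, **PUBLISHED)
    assert ow.spread == 0.0
    assert ow.thresholds == ()


def test_one_way_reports_threshold_with_icer_at_wtp(params, lt):
    ow = one_way("cost_LC", ClassId.class4, (Strategy.ET, Strategy.LC),
                 params, lt, wtp=100_000, **PUBLISHED)
    assert len(ow.thresholds) == 1
    # at the reported threshold, the pairwise ICER equals WTP to < $1
    from t1crc_cea import run_strategy

    ps = params.with_value("cost_LC", ow.thresholds[0])
    res = {s: run_strategy(s, ClassId.class4, ps, lt, **PUBLISHED)
           for s in (Strategy.ET, Strategy.LC)}
    icer = (res[Strategy.LC].cost - res[Strategy.ET].cost) / (
        res[Strategy.LC].qalys - res[Strategy.ET].qalys
    )
    assert abs(icer - 100_000) <= 1.0


TORNADO_SUBSET = [
    "cost_LC", "cost_ET", "p_recur_LC", "p_recur_ET", "u_recur_ET",
    "cost_recur_treatment_ET", "u_pre", "cost_OC", "u_OC_m1", "u_OC_post",
]


def test_tornado_ranks_by_spread_and_truncates(params, lt):
    rows = tornado(ClassId.class4, (Strategy.ET, Strategy.LC), params, lt,
                   wtp=100_000, top_k=5, param_names=TORNADO_SUBSET, **PUBLISHED)
    assert len(rows) == 5
    finite = [r.spread for r in rows if math.isfinite(r.spread)]
    assert finite == sorted(finite, reverse=True)


def test_tornado_top_k_larger_than_parameter_count(params, lt):
    rows = tornado(ClassId.class4, (Strategy.ET, Strategy.LC), params, lt,
                   wtp=100_000, top_k=99, param_names=TORNADO_SUBSET[:4], **PUBLISHED)
    assert len(rows) == 4


def test_tornado_duplicate_spreads_break_ties_by_name(params, lt):
    # cost_OC, u_OC_m1, u_OC_post, u_pre all have zero effect on the ET/LC pair
    rows = tornado(ClassId.class4, (Strategy.ET, Strategy.LC), params, lt,
                   wtp=100_000, top_k=10, param_names=TORNADO_SUBSET, **PUBLISHED)
    zero_named = [r.parameter for r in rows if r.spread == 0.0]
    assert zero_named == sorted(zero_named)


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def test_fixed_family_returns_base(params):
    rng = np.random.default_rng(1)
    p = params["p_crcdeath_class1"]
    assert sample_parameter(p, rng) == p.base


def test_uniform_mean_matches_distribution():
    rng = np.random.default_rng(7)
    p = Parameter("cost_ET", 980, 490, 1960, family="uniform", role="cost")
    draws = sample_parameter(p, rng, size=100_000)
    se = (1960 - 490) / math.sqrt(12) / math.sqrt(100_000)
    assert np.mean(draws) == pytest.approx(1225, abs=3 * se)


def test_beta_draws_truncated_to_printed_range(params):
    rng = np.random.default_rng(11)
    draws = sample_parameter(params["p_recur_ET"], rng, size=50_000)
    assert draws.min() >= 0.0009 and draws.max() <= 0.0015
    assert np.mean(draws) == pytest.approx(0.0012, rel=0.02)


def test_gamma_draws_positive_and_centered(params):
    rng = np.random.default_rng(13)
    draws = sample_parameter(params["cost_LC"], rng, size=50_000)
    assert draws.min() >= params["cost_LC"].low and draws.max() <= params["cost_LC"].high
    # truncation to [base/2, 2*base] nudges the mean up slightly
    assert np.mean(draws) == pytest.approx(37_778, rel=0.05)


def test_infeasible_beta_falls_back_to_uniform(caplog):
    p = Parameter("p_tiny", 0.0001, 0.0, 1.0, family="beta", role="probability")
    rng = np.random.default_rng(3)
    with caplog.at_level(logging.WARNING, logger="t1crc_cea.cea"):
        draws = sample_parameter(p, rng, size=1000)
    assert "p_tiny" in caplog.text
    assert np.mean(draws) == pytest.approx(0.5, abs=0.05)  # uniform on [0, 1]


# ---------------------------------------------------------------------------
# PSA / CEAC
# ---------------------------------------------------------------------------

def test_all_fixed_families_degenerate_to_base_case(params, lt):
    from dataclasses import replace

    fixed = {n: replace(p, family="fixed") for n, p in params.parameters.items()}
    ps = type(params)(fixed, params.classes, params.currency)
    psa = run_psa(ps, lt, ClassId.class4, n_draws=8, seed=0, **PUBLISHED)
    from t1crc_cea import run_strategy

    base = run_strategy(Strategy.LC, ClassId.class4, params, lt, **PUBLISHED)
    assert np.allclose(psa.draws["qalys_LC"], base.qalys)
    assert np.allclose(psa.draws["cost_LC"], base.cost)
    # degenerate CEAC: one strategy takes probability 1 at every WTP
    assert (psa.ceac[["p_ET", "p_LC", "p_OC"]].max(axis=1) == 1.0).all()


def test_psa_reproducible_given_seed(params, lt):
    a = run_psa(params, lt, ClassId.class0, n_draws=64, seed=321, **PUBLISHED)
    b = run_psa(params, lt, ClassId.class0, n_draws=64, seed=321, **PUBLISHED)
    assert a.draws.equals(b.draws)
    assert a.ceac.equals(b.ceac)


def test_ceac_partition_of_unity(params, lt):
    psa = run_psa(params, lt, ClassId.class4, n_draws=128, seed=5, **PUBLISHED)
    sums = psa.ceac[["p_ET", "p_LC", "p_OC"]].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)
    assert psa.n_draws == 128 and len(psa.draws) == 128


def test_ceac_per_draw_preference_monotone_in_wtp(params, lt):
    """In a two-strategy comparison, once the higher-QALY strategy is preferred
    at some WTP it stays preferred at every higher WTP, draw by draw."""
    psa = run_psa(params, lt, ClassId.class4, strategies=(Strategy.ET, Strategy.LC),
                  n_draws=64, seed=9, **PUBLISHED)
    dq = psa.draws["qalys_LC"] - psa.draws["qalys_ET"]
    dc = psa.draws["cost_LC"] - psa.draws["cost_ET"]
    for wlo, whi in [(0, 50_000), (50_000, 100_000), (100_000, 200_000)]:
        pick_lo = (wlo * dq - dc) > 0
        pick_hi = (whi * dq - dc) > 0
        flips_down = pick_lo & ~pick_hi & (dq > 0)
        assert not flips_down.any()
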