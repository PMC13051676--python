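"""Unit and property tests for the deterministic economic engine."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import impact_oracle
from swineval import (
    CostItem,
    CostLedger,
    DERIVED_RWF_PER_USD,
    DomainError,
    ImpactParameters,
    adjust_success_rate,
    conception_prob_from_ipc,
    gross_income,
    incremental_rate,
    multiplier_decomposition,
    odds,
    per_farmer_metrics,
    production_cascade,
    relative_increase,
    roi,
    run_impact_model,
    sensitivity_sweep,
    total_cost,
)
from swineval.errors import ConfigurationError


# ---------------------------------------------------------------------------
# Elementary operations: worked examples
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p, expected", [(0.5, 1.0), (0.0, 0.0), (0.488, 0.953125)])
def test_odds_examples(p, expected):
    assert odds(p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("p", [1.0, -0.1, 1.5])
def test_odds_domain(p):
    with pytest.raises(DomainError):
        odds(p)


@pytest.mark.parametrize("p0, orv, expected", [
    (0.488, 1.51, 0.5900),  # counterfactual treatment rate
    (0.3, 1.0, 0.3),
    (0.0, 5.0, 0.0),
])
def test_adjust_success_rate_examples(p0, orv, expected):
    assert adjust_success_rate(p0, orv) == pytest.approx(expected, abs=5e-5)


@pytest.mark.parametrize("p0, orv, expected", [
    (0.488, 1.51, 0.1020),  # attributable percentage-point gain
    (0.488, 1.0, 0.0),
    (0.3, 2.0, 0.161538),
])
def test_incremental_rate_examples(p0, orv, expected):
    assert incremental_rate(p0, orv) == pytest.approx(expected, abs=5e-5)


def test_adjust_rejects_nonpositive_odds_ratio():
    with pytest.raises(DomainError):
        adjust_success_rate(0.5, 0.0)


def test_production_cascade_examples():
    # program-scale check: incremental piglets land on the published count
    _, _, piglets = production_cascade(7540, 0.102031, 0.796, 7.99)
    assert round(piglets) == 4893
    assert production_cascade(100, 0.5, 1.0, 10.0) == pytest.approx((50, 50, 500))
    assert production_cascade(123, 0.0, 0.7, 8.0) == pytest.approx((0, 0, 0))
    with pytest.raises(DomainError):
        production_cascade(-1, 0.5, 0.5, 5)
    with pytest.raises(DomainError):
        production_cascade(10, 1.5, 0.5, 5)


def test_gross_income_examples():
    assert gross_income(4893, 11.21) == pytest.approx(54850, abs=2)
    assert gross_income(0, 11.21) == 0
    assert gross_income(28552.6, 11.21) == pytest.approx(320075, abs=2)
    with pytest.raises(DomainError):
        gross_income(-1, 5)


def test_multiplier_decomposition_examples():
    indirect, induced, combined = multiplier_decomposition(320074.79, 1.16, 7.20)
    assert indirect == pytest.approx(51212, abs=2)
    assert induced == pytest.approx(1933252, abs=2)
    assert combined == pytest.approx(2304538, abs=2)
    assert multiplier_decomposition(100.0, 1.0, 1.0) == pytest.approx((0, 0, 100))
    assert multiplier_decomposition(100.0, 1.5, 2.0) == pytest.approx((50, 50, 200))
    with pytest.raises(DomainError):
        multiplier_decomposition(100.0, 0.9, 2.0)
    with pytest.raises(DomainError):
        multiplier_decomposition(100.0, 2.0, 1.5)


def test_roi_examples():
    assert roi(2304538, 191149).benefit_cost_ratio == pytest.approx(12.06, abs=0.01)
    equal = roi(191149, 191149)
    assert equal.roi == 0 and equal.benefit_cost_ratio == 1
    assert roi(320075, 191149).roi == pytest.approx(0.674, abs=5e-4)
    with pytest.raises(DomainError):
        roi(100, 0)


def test_per_farmer_metrics_examples():
    income, inc, share = per_farmer_metrics(320074.79, 54850, 3421)
    assert income == pytest.approx(93.56, abs=0.01)
    assert inc == pytest.approx(16.03, abs=0.01)
    assert share == pytest.approx(0.171, abs=0.001)
    assert per_farmer_metrics(1000, 500, 10) == pytest.approx((100, 50, 0.5))
    assert per_farmer_metrics(0, 0, 10).attributable_share == 0
    with pytest.raises(DomainError):
        per_farmer_metrics(1000, 500, 0)
    with pytest.raises(DomainError):
        per_farmer_metrics(0, 5, 10)


def test_conception_prob_and_relative_increase():
    assert conception_prob_from_ipc(1.89) == pytest.approx(0.529, abs=5e-4)
    assert conception_prob_from_ipc(1.0) == 1.0
    assert conception_prob_from_ipc(4.0) == 0.25
    assert relative_increase(0.488, 0.748) == pytest.approx(0.533, abs=1e-3)
    assert relative_increase(0.42, 0.42) == 0
    assert relative_increase(0.25, 0.50) == 1.0
    with pytest.raises(DomainError):
        conception_prob_from_ipc(0.8)
    with pytest.raises(DomainError):
        relative_increase(0.0, 0.5)


# ---------------------------------------------------------------------------
# Cost ledger
# ---------------------------------------------------------------------------

def test_total_cost_published_ledger(base_case):
    assert total_cost(base_case.ledger) == pytest.approx(191149, abs=1e-9)


def test_total_cost_empty_ledger():
    assert total_cost(CostLedger()) == 0


def test_rwf_conversion_reproduces_procurement_line():
    ledger = CostLedger((
        CostItem("RAB doses", 2220 * 3500, "RWF", DERIVED_RWF_PER_USD),
        CostItem("private doses", 5320 * 6500, "RWF", DERIVED_RWF_PER_USD),
    ))
    assert round(total_cost(ledger)) == 29312


def test_local_currency_requires_rate():
    with pytest.raises(ConfigurationError):
        CostItem("doses", 1000, "RWF")
    with pytest.raises(ConfigurationError):
        CostItem("doses", -5)


# ---------------------------------------------------------------------------
# Invariants (property-based)
# ---------------------------------------------------------------------------

probs = st.floats(min_value=0.0, max_value=0.999, allow_nan=False)
pos_or = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


@settings(max_examples=200, derandomize=True)
@given(p=probs)
def test_odds_round_trip_identity(p):
    assert adjust_success_rate(p, 1.0) == pytest.approx(p, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(p=st.floats(0.01, 0.98), orv=pos_or, eps=st.floats(1e-4, 0.5))
def test_adjust_strictly_increasing(p, orv, eps):
    assert adjust_success_rate(p + eps * (0.99 - p), orv) > adjust_success_rate(p, orv)
    assert adjust_success_rate(p, orv * (1 + eps)) > adjust_success_rate(p, orv)


@settings(max_examples=200, derandomize=True)
@given(direct=st.floats(0, 1e9), m1=st.floats(1, 10), spread=st.floats(0, 10))
def test_decomposition_conserves_combined(direct, m1, spread):
    indirect, induced, combined = multiplier_decomposition(direct, m1, m1 + spread)
    assert combined == pytest.approx(direct + indirect + induced, rel=1e-9, abs=1e-9)
    assert combined == pytest.approx(direct * (m1 + spread), rel=1e-9, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(doses=st.floats(0, 1e5), rate=st.floats(0, 1), ft=st.floats(0, 1),
       litter=st.floats(0, 20), k=st.floats(0.1, 10))
def test_cascade_homogeneous_in_doses(doses, rate, ft, litter, k):
    base = production_cascade(doses, rate, ft, litter)
    scaled = production_cascade(doses * k, rate, ft, litter)
    for a, b in zip(base, scaled):
        assert b == pytest.approx(k * a, rel=1e-9, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(benefit=st.floats(0, 1e9), cost=st.floats(1, 1e9))
def test_benefit_cost_ratio_is_roi_plus_one(benefit, cost):
    r = roi(benefit, cost)
    assert r.benefit_cost_ratio == pytest.approx(r.roi + 1.0, rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# Composite model
# ---------------------------------------------------------------------------

def _random_params(rng):
    m1 = rng.uniform(1.0, 3.0)
    return ImpactParameters(
        baseline_success_rate=rng.uniform(0.05, 0.9),
        endline_success_rate=rng.uniform(0.05, 0.95),
        round_odds_ratio=rng.uniform(1.0, 5.0),
        full_term_rate=rng.uniform(0.1, 1.0),
        doses_distributed=int(rng.integers(100, 100_000)),
        farmers_served=int(rng.integers(10, 10_000)),
        litter_size=rng.uniform(1.0, 15.0),
        price_per_piglet=rng.uniform(1.0, 100.0),
        multiplier_type1=m1,
        multiplier_type2=m1 + rng.uniform(0.0, 8.0),
    )


def test_run_impact_model_matches_oracle(base_case):
    rng = np.random.default_rng(42)
    ledger = base_case.ledger
    for _ in range(200):
        params = _random_params(rng)
        result, roi_d, roi_c = run_impact_model(params, ledger)
        expected = impact_oracle(
            params.baseline_success_rate, params.round_odds_ratio,
            params.full_term_rate, params.doses_distributed, params.farmers_served,
            params.litter_size, params.price_per_piglet,
            params.multiplier_type1, params.multiplier_type2)
        got = result.as_dict()
        for key, value in expected.items():
            assert got[key] == pytest.approx(value, rel=1e-9, abs=1e-12), key


def test_run_impact_model_null_odds_ratio(base_case):
    params = base_case.parameters.replace(round_odds_ratio=1.0)
    result, _, _ = run_impact_model(params, base_case.ledger)
    assert result.incremental_rate == pytest.approx(0, abs=1e-12)
    assert result.incremental_income == pytest.approx(0, abs=1e-9)
    assert result.combined_incremental == pytest.approx(0, abs=1e-9)


def test_run_impact_model_linear_in_doses(base_case):
    params = base_case.parameters
    doubled = params.replace(doses_distributed=2 * params.doses_distributed)
    r1, _, _ = run_impact_model(params, base_case.ledger)
    r2, _, _ = run_impact_model(doubled, base_case.ledger)
    for key in ("total_successful_ai", "total_piglets", "total_income",
                "incremental_piglets", "incremental_income", "combined_total"):
        assert getattr(r2, key) == pytest.approx(2 * getattr(r1, key), rel=1e-12)


def test_incremental_never_exceeds_total_under_shipped_policies(base_case):
    for policy, rate in (("adjusted", None), ("endline", None), ("custom", 0.62)):
        result, _, _ = run_impact_model(base_case.parameters, base_case.ledger,
                                        policy, rate)
        assert result.incremental_income <= result.total_income
        assert 0 <= result.incremental_rate <= result.adjusted_success_rate


def test_scope_rate_policies(base_case):
    params = base_case.parameters
    adjusted, _, _ = run_impact_model(params, base_case.ledger, "adjusted")
    endline, _, _ = run_impact_model(params, base_case.ledger, "endline")
    custom, _, _ = run_impact_model(params, base_case.ledger, "custom", 0.5954)
    assert adjusted.total_scope_rate == pytest.approx(0.59003, abs=1e-5)
    assert endline.total_scope_rate == params.endline_success_rate
    assert custom.total_scope_rate == 0.5954
    # incremental scope is policy-independent
    assert adjusted.incremental_income == endline.incremental_income == custom.incremental_income
    with pytest.raises(ConfigurationError):
        run_impact_model(params, base_case.ledger, "custom")


# ---------------------------------------------------------------------------
# Sensitivity sweep
# ---------------------------------------------------------------------------

def test_sweep_zero_width_spans_reproduce_base(base_case):
    p = base_case.parameters
    spans = {"price_per_piglet": (p.price_per_piglet, p.price_per_piglet),
             "round_odds_ratio": (p.round_odds_ratio, p.round_odds_ratio)}
    table = sensitivity_sweep(p, base_case.ledger, spans)
    assert np.allclose(table["low"], table["base"])
    assert np.allclose(table["high"], table["base"])


def test_sweep_price_scales_income_linearly(base_case):
    p = base_case.parameters
    table = sensitivity_sweep(p, base_case.ledger,
                              {"price_per_piglet": (p.price_per_piglet / 2,
                                                    p.price_per_piglet * 2)},
                              outputs=("incremental_income", "total_income"))
    for _, row in table.iterrows():
        assert row["low"] == pytest.approx(row["base"] / 2, rel=1e-12)
        assert row["high"] == pytest.approx(row["base"] * 2, rel=1e-12)


def test_sweep_odds_ratio_ci_brackets_base_case(base_case):
    # published 95% CI of the round odds ratio
    table = sensitivity_sweep(base_case.parameters, base_case.ledger,
                              {"round_odds_ratio": (1.23, 1.87)},
                              outputs=("incremental_income",))
    row = table.iloc[0]
    assert row["low"] < row["base"] < row["high"]
    assert row["base"] == pytest.approx(54850, abs=2)


def test_sweep_rejects_out_of_domain_bounds(base_case):
    with pytest.raises(DomainError):
        sensitivity_sweep(base_case.parameters, base_case.ledger,
                          {"full_term_rate": (0.5, 1.5)})
    with pytest.raises(ConfigurationError):
        sensitivity_sweep(base_case.parameters, base_case.ledger,
                          {"not_a_parameter": (0, 1)})
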