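"""Deterministic economic-impact engine.

The model chains four stages:

1. **Counterfactual success rate.** The baseline success probability is
   converted to odds, multiplied by the endline odds ratio from the
   binomial GLM, and converted back:
   ``p_adj = odds(p0)*OR / (1 + odds(p0)*OR)``. The difference
   ``p_adj - p0`` is the incremental success rate attributable to the
   program; the remaining movement up to the observed endline rate is
   treated as secular change.

2. **Production cascade.** Doses x success rate -> successful
   inseminations; x full-term rate -> farrowings; x litter size ->
   piglets; x piglet price -> gross farm income. Full floating-point
   precision is carried; rounding is presentation-only.

3. **Multiplier decomposition.** With Type I multiplier M_I and Type II
   multiplier M_II applied to direct income D: indirect = D*(M_I - 1),
   induced = D*(M_II - M_I), combined = D*M_II, so
   direct + indirect + induced == combined by construction.

4. **Cost accounting and ROI.** The ledger total (local-currency items
   converted at their attached rates) is compared with direct and
   combined benefits: ROI = (benefit - cost)/cost, B/C = benefit/cost.

The published total-scope figures imply a success rate (total
successful inseminations / doses) that matches neither the adjusted nor
the endline rate exactly, so the rate used for the *total* cascade is
explicit policy: ``"adjusted"`` (default), ``"endline"``, or
``"custom"`` with a caller-supplied rate. The incremental cascade always
uses ``p_adj - p0``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Literal, Mapping, NamedTuple, Sequence

import pandas as pd

from .config import CostLedger, ImpactParameters
from .errors import ConfigurationError, DomainError

RatePolicy = Literal["adjusted", "endline", "custom"]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def odds(p: float) -> float:
    """Odds ``p/(1-p)`` of a probability ``p`` in [0, 1)."""
    if not 0.0 <= p < 1.0:
        raise DomainError(f"odds() requires 0 <= p < 1, got {p!r}")
    return p / (1.0 - p)


def adjust_success_rate(p0: float, or_value: float) -> float:
    """Push a baseline probability through an odds ratio.

    Returns the counterfactual probability whose odds are
    ``odds(p0) * or_value`` — the model-predicted success rate under
    treatment when ``or_value`` is the fitted round odds ratio.
    """
    if or_value <= 0:
        raise DomainError(f"odds ratio must be > 0, got {or_value!r}")
    shifted = odds(p0) * or_value
    return shifted / (1.0 + shifted)


def incremental_rate(p0: float, or_value: float) -> float:
    """Percentage-point gain attributable to the odds ratio:
    ``adjust_success_rate(p0, or_value) - p0``."""
    return adjust_success_rate(p0, or_value) - p0


class CascadeResult(NamedTuple):
    successful_ai: float
    ft_pregnancies: float
    piglets: float


def production_cascade(doses: float, rate: float, ft: float, litter: float) -> CascadeResult:
    """Doses -> successful inseminations -> full-term pregnancies -> piglets.

    Real-valued counts; no intermediate rounding.
    """
    if doses < 0 or litter < 0:
        raise DomainError("doses and litter size must be >= 0")
    if not (0.0 <= rate <= 1.0 and 0.0 <= ft <= 1.0):
        raise DomainError("rate and full-term rate must lie in [0, 1]")
    successful = doses * rate
    pregnancies = successful * ft
    return CascadeResult(successful, pregnancies, pregnancies * litter)


def gross_income(piglets: float, price: float) -> float:
    """Market value of a piglet crop: ``piglets * price`` (USD)."""
    if piglets < 0 or price < 0:
        raise DomainError("piglets and price must be >= 0")
    return piglets * price


class Decomposition(NamedTuple):
    indirect: float
    induced: float
    combined: float


def multiplier_decomposition(direct: float, m1: float, m2: float) -> Decomposition:
    """Split direct income into indirect and induced ripple effects.

    Type I multiplier ``m1`` covers upstream supply-chain stimulus,
    Type II ``m2`` additionally covers household re-spending:
    indirect = direct*(m1-1), induced = direct*(m2-m1),
    combined = direct*m2 = direct + indirect + induced.
    """
    if direct < 0:
        raise DomainError("direct income must be >= 0")
    if not 1.0 <= m1 <= m2:
        raise DomainError(f"multipliers must satisfy 1 <= m1 <= m2, got {m1!r}, {m2!r}")
    indirect = direct * (m1 - 1.0)
    induced = direct * (m2 - m1)
    return Decomposition(indirect, induced, direct + indirect + induced)


@dataclass(frozen=True)
class RoiResult:
    """Return-on-investment summary: ``roi = (benefit - cost)/cost`` and
    ``benefit_cost_ratio = benefit/cost`` (= roi + 1)."""

    benefit: float
    cost: float
    roi: float
    benefit_cost_ratio: float


def roi(benefit: float, cost: float) -> RoiResult:
    if cost <= 0:
        raise DomainError(f"cost must be > 0, got {cost!r}")
    if benefit < 0:
        raise DomainError(f"benefit must be >= 0, got {benefit!r}")
    return RoiResult(benefit=benefit, cost=cost, roi=(benefit - cost) / cost,
                     benefit_cost_ratio=benefit / cost)


class PerFarmer(NamedTuple):
    income_per_farmer: float
    incremental_per_farmer: float
    attributable_share: float


def per_farmer_metrics(direct: float, incremental: float, farmers: int) -> PerFarmer:
    """Per-farmer incomes and the share of direct income attributable to
    the program (incremental / direct)."""
    if farmers <= 0:
        raise DomainError(f"farmers must be > 0, got {farmers!r}")
    if direct == 0:
        if incremental != 0:
            raise DomainError("nonzero incremental income with zero direct income")
        share = 0.0
    else:
        share = incremental / direct
    return PerFarmer(direct / farmers, incremental / farmers, share)


def total_cost(ledger: CostLedger) -> float:
    """Ledger total in USD, converting local-currency items at their
    attached rates. Validation of missing rates happens at item
    construction time; an invalid ledger cannot be built."""
    return ledger.total_usd()


def conception_prob_from_ipc(inseminations_per_conception: float) -> float:
    """Conception probability implied by a mean number of inseminations
    per conception (its reciprocal)."""
    if inseminations_per_conception < 1.0:
        raise DomainError("inseminations per conception must be >= 1")
    return 1.0 / inseminations_per_conception


def relative_increase(p0: float, p1: float) -> float:
    """Relative change ``(p1 - p0)/p0``."""
    if p0 <= 0:
        raise DomainError(f"baseline must be > 0, got {p0!r}")
    return (p1 - p0) / p0


# ---------------------------------------------------------------------------
# Composite model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpactResult:
    """Every computed quantity of the impact model, for both the total
    scope (all program output) and the incremental scope (the part
    attributable to the odds-ratio gain)."""

    adjusted_success_rate: float
    incremental_rate: float
    total_scope_rate: float

    total_successful_ai: float
    total_ft_pregnancies: float
    total_piglets: float
    total_income: float

    incremental_successful_ai: float
    incremental_ft_pregnancies: float
    incremental_piglets: float
    incremental_income: float

    direct_total: float
    indirect_total: float
    induced_total: float
    combined_total: float

    direct_incremental: float
    indirect_incremental: float
    induced_incremental: float
    combined_incremental: float

    income_per_farmer: float
    incremental_income_per_farmer: float
    attributable_share: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def run_impact_model(
    params: ImpactParameters,
    ledger: CostLedger,
    scope_rate_policy: RatePolicy = "adjusted",
    custom_rate: float | None = None,
) -> tuple[ImpactResult, RoiResult, RoiResult]:
    """Evaluate the full economic model.

    Returns ``(result, roi_direct, roi_combined)`` where the ROI results
    compare total direct income and total combined impact against the
    ledger total. The incremental-scope ROI (an extension beyond the
    published accounting) is available via :func:`roi` on
    ``result.direct_incremental`` / ``result.combined_incremental``.
    """
    p_adj = adjust_success_rate(params.baseline_success_rate, params.round_odds_ratio)
    delta = p_adj - params.baseline_success_rate
    # an estimated odds ratio can dip below 1 by sampling noise; the
    # incremental scope is then carried with its (negative) sign rather
    # than rejected, so a null program estimates an increment near zero
    sign = 1.0 if delta >= 0 else -1.0

    if scope_rate_policy == "adjusted":
        scope_rate = p_adj
    elif scope_rate_policy == "endline":
        scope_rate = params.endline_success_rate
    elif scope_rate_policy == "custom":
        if custom_rate is None:
            raise ConfigurationError("scope_rate_policy='custom' requires custom_rate")
        if not 0.0 <= custom_rate <= 1.0:
            raise DomainError(f"custom rate must lie in [0, 1], got {custom_rate!r}")
        scope_rate = custom_rate
    else:  # pragma: no cover - typing guards this
        raise ConfigurationError(f"unknown scope_rate_policy {scope_rate_policy!r}")

    tot = production_cascade(params.doses_distributed, scope_rate,
                             params.full_term_rate, params.litter_size)
    inc_mag = production_cascade(params.doses_distributed, abs(delta),
                                 params.full_term_rate, params.litter_size)
    inc = CascadeResult(*(sign * x for x in inc_mag))
    total_income = gross_income(tot.piglets, params.price_per_piglet)
    incremental_income = sign * gross_income(inc_mag.piglets, params.price_per_piglet)

    d_tot = multiplier_decomposition(total_income, params.multiplier_type1, params.multiplier_type2)
    d_inc_mag = multiplier_decomposition(abs(incremental_income), params.multiplier_type1,
                                         params.multiplier_type2)
    d_inc = Decomposition(*(sign * x for x in d_inc_mag))
    per = per_farmer_metrics(total_income, incremental_income, params.farmers_served)

    result = ImpactResult(
        adjusted_success_rate=p_adj,
        incremental_rate=delta,
        total_scope_rate=scope_rate,
        total_successful_ai=tot.successful_ai,
        total_ft_pregnancies=tot.ft_pregnancies,
        total_piglets=tot.piglets,
        total_income=total_income,
        incremental_successful_ai=inc.successful_ai,
        incremental_ft_pregnancies=inc.ft_pregnancies,
        incremental_piglets=inc.piglets,
        incremental_income=incremental_income,
        direct_total=total_income,
        indirect_total=d_tot.indirect,
        induced_total=d_tot.induced,
        combined_total=d_tot.combined,
        direct_incremental=incremental_income,
        indirect_incremental=d_inc.indirect,
        induced_incremental=d_inc.induced,
        combined_incremental=d_inc.combined,
        income_per_farmer=per.income_per_farmer,
        incremental_income_per_farmer=per.incremental_per_farmer,
        attributable_share=per.attributable_share,
    )
    cost = total_cost(ledger)
    return result, roi(total_income, cost), roi(d_tot.combined, cost)


#: Outputs reported by default in a sensitivity sweep.
DEFAULT_SWEEP_OUTPUTS: tuple[str, ...] = (
    "incremental_income",
    "combined_incremental",
    "total_income",
    "combined_total",
)


def sensitivity_sweep(
    params: ImpactParameters,
    ledger: CostLedger,
    spans: Mapping[str, tuple[float, float]],
    outputs: Sequence[str] = DEFAULT_SWEEP_OUTPUTS,
    scope_rate_policy: RatePolicy = "adjusted",
    custom_rate: float | None = None,
) -> pd.DataFrame:
    """One-way (tornado-style) sensitivity analysis.

    Each parameter in ``spans`` is set in turn to its low and high bound
    with every other parameter at base case, and the chosen outputs are
    re-evaluated. Returns a tidy frame with one row per
    (parameter, output) and columns ``low``, ``base``, ``high``.
    """
    valid = {f.name for f in fields(ImpactParameters)}
    base_result, _, _ = run_impact_model(params, ledger, scope_rate_policy, custom_rate)
    base_values = base_result.as_dict()
    unknown_outputs = [o for o in outputs if o not in base_values]
    if unknown_outputs:
        raise ConfigurationError(f"unknown output fields: {unknown_outputs}")

    rows = []
    for name, (low, high) in spans.items():
        if name not in valid:
            raise ConfigurationError(f"unknown parameter {name!r} in spans")
        if low > high:
            raise DomainError(f"span for {name!r} has low > high")
        evaluated = {}
        for bound, value in (("low", low), ("high", high)):
            if name in ("doses_distributed", "farmers_served"):
                value = int(round(value))
            try:
                varied = params.replace(**{name: value})
            except ConfigurationError as exc:
                raise DomainError(f"span bound for {name!r} outside its domain: {exc}") from exc
            res, _, _ = run_impact_model(varied, ledger, scope_rate_policy, custom_rate)
            evaluated[bound] = res.as_dict()
        for output in outputs:
            rows.append({
                "parameter": name,
                "output": output,
                "low": evaluated["low"][output],
                "base": base_values[output],
                "high": evaluated["high"][output],
            })
    return pd.DataFrame(rows, columns=["parameter", "output", "low", "base", "high"])
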