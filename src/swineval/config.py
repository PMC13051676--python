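"""Parameter and cost-ledger configuration.

The economic model is driven entirely by scalar inputs: survey-derived
rates (baseline/endline insemination success, full-term pregnancy rate),
the round odds ratio from the CAHW binomial GLM, program operations data
(doses distributed, farmers served), literature-sourced production
parameters (litter size, piglet price) and input-output multipliers.
``ImpactParameters`` carries those scalars; ``CostLedger`` carries the
itemized program costs, converting local-currency items at an attached
exchange rate.

Configurations are read from a flat YAML file whose keys match the
``ImpactParameters`` field names, plus a ``costs:`` list of
``{label, amount, currency, fx_rate?}`` mappings and an optional
``reference:`` mapping of printed values used by the reproduction
harness. ``load_base_case()`` returns the shipped base-case fixture.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError

#: Back-solved RWF-per-USD rate: the program procured 2,220 doses at
#: 3,500 RWF and 5,320 doses at 6,500 RWF (42,350,000 RWF in total),
#: reported as $29,312. The prevailing rate itself is not published, so
#: this derived value (42,350,000 / 29,312 ~= 1444.80) is a convenience
#: default, not an authoritative exchange rate.
DERIVED_RWF_PER_USD: float = 42_350_000 / 29_312


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ImpactParameters:
    """Scalar inputs of the deterministic economic-impact model.

    Attributes
    ----------
    baseline_success_rate:
        CAHW-reported insemination success probability before the program.
    endline_success_rate:
        CAHW-reported success probability at endline (includes secular change).
    round_odds_ratio:
        Endline-vs-baseline odds ratio from the binomial GLM; the share of
        the improvement attributed to the program.
    full_term_rate:
        Probability that a conception is carried to farrowing.
    doses_distributed:
        Semen doses delivered over the program period.
    farmers_served:
        Distinct farmers receiving at least one dose.
    litter_size:
        Live piglets per full-term pregnancy.
    price_per_piglet:
        Market value of a weaned piglet, USD.
    multiplier_type1:
        Type I output multiplier (direct + indirect) / direct, >= 1.
    multiplier_type2:
        Type II output multiplier (direct + indirect + induced) / direct,
        >= the Type I multiplier.
    """

    baseline_success_rate: float
    endline_success_rate: float
    round_odds_ratio: float
    full_term_rate: float
    doses_distributed: int
    farmers_served: int
    litter_size: float
    price_per_piglet: float
    multiplier_type1: float
    multiplier_type2: float

    def __post_init__(self) -> None:
        _check_prob("baseline_success_rate", self.baseline_success_rate)
        _check_prob("endline_success_rate", self.endline_success_rate)
        _check_prob("full_term_rate", self.full_term_rate)
        if self.round_odds_ratio <= 0:
            raise ConfigurationError(f"round_odds_ratio must be > 0, got {self.round_odds_ratio!r}")
        for name in ("doses_distributed", "farmers_served"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.litter_size <= 0:
            raise ConfigurationError(f"litter_size must be > 0, got {self.litter_size!r}")
        if self.price_per_piglet < 0:
            raise ConfigurationError(f"price_per_piglet must be >= 0, got {self.price_per_piglet!r}")
        if not 1.0 <= self.multiplier_type1 <= self.multiplier_type2:
            raise ConfigurationError(
                "multipliers must satisfy 1 <= multiplier_type1 <= multiplier_type2, got "
                f"{self.multiplier_type1!r}, {self.multiplier_type2!r}"
            )

    def replace(self, **changes: Any) -> "ImpactParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(changes)
        return ImpactParameters(**values)


@dataclass(frozen=True)
class CostItem:
    """One program cost line. ``fx_rate`` is local units per USD and is
    mandatory for any non-USD currency."""

    label: str
    amount: float
    currency: str = "USD"
    fx_rate: float | None = None

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ConfigurationError(f"cost item {self.label!r}: amount must be >= 0")
        if self.currency != "USD":
            if self.fx_rate is None:
                raise ConfigurationError(
                    f"cost item {self.label!r} is in {self.currency} but carries no fx_rate"
                )
            if self.fx_rate <= 0:
                raise ConfigurationError(f"cost item {self.label!r}: fx_rate must be > 0")

    @property
    def amount_usd(self) -> float:
        if self.currency == "USD":
            return self.amount
        return self.amount / self.fx_rate  # type: ignore[operator]


@dataclass(frozen=True)
class CostLedger:
    """Itemized program costs."""

    items: tuple[CostItem, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))

    def total_usd(self) -> float:
        return float(sum(item.amount_usd for item in self.items))


@dataclass(frozen=True)
class EvaluationConfig:
    """A parsed configuration: parameters, ledger, and printed reference
    values (row label -> value) for the reproduction harness."""

    parameters: ImpactParameters
    ledger: CostLedger
    reference: Mapping[str, float] = field(default_factory=dict)


_PARAM_NAMES = tuple(f.name for f in fields(ImpactParameters))
_INT_PARAMS = {"doses_distributed", "farmers_served"}


def parse_config(raw: Mapping[str, Any]) -> EvaluationConfig:
    """Build an :class:`EvaluationConfig` from a parsed YAML mapping."""
    missing = [k for k in _PARAM_NAMES if k not in raw]
    if missing:
        raise ConfigurationError(f"missing parameter keys: {missing}")
    kwargs: dict[str, Any] = {}
    for name in _PARAM_NAMES:
        value = raw[name]
        if name in _INT_PARAMS:
            if isinstance(value, float) and not value.is_integer():
                raise ConfigurationError(f"{name} must be an integer, got {value!r}")
            value = int(value)
        else:
            value = float(value)
        kwargs[name] = value
    parameters = ImpactParameters(**kwargs)

    items = []
    for entry in raw.get("costs", []):
        if not isinstance(entry, Mapping) or "label" not in entry or "amount" not in entry:
            raise ConfigurationError(f"malformed cost entry: {entry!r}")
        items.append(
            CostItem(
                label=str(entry["label"]),
                amount=float(entry["amount"]),
                currency=str(entry.get("currency", "USD")),
                fx_rate=float(entry["fx_rate"]) if entry.get("fx_rate") is not None else None,
            )
        )
    reference = {str(k): float(v) for k, v in (raw.get("reference") or {}).items()}
    return EvaluationConfig(parameters=parameters, ledger=CostLedger(tuple(items)), reference=reference)


def load_config(path: str | Path) -> EvaluationConfig:
    """Load and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return parse_config(raw)


def base_case_path() -> Path:
    """Path of the shipped base-case configuration fixture."""
    return Path(str(importlib.resources.files("swineval").joinpath("data/base_case.yaml")))


def load_base_case() -> EvaluationConfig:
    """The shipped base case: the program's published parameter set and
    cost ledger, with the printed table values attached as references."""
    return load_config(base_case_path())
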