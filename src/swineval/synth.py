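"""Seeded synthetic survey microdata.

Generates respondent-level tables with the statistical structure the
downstream analysis assumes, so every stage — descriptives, paired
tests, the binomial GLM, the farmer logistic model and the economic
engine — is testable end-to-end without external data.

Two-round cohorts (CAHWs, veterinarians)
    Baseline respondents are drawn with covariates (district, sex, age,
    experience, AI knowledge); the endline roster is a
    missing-completely-at-random subsample of the baseline roster
    (attrition is independent of outcomes by construction). Monthly
    procedure counts follow a zero-truncated Poisson whose truncated
    mean matches the configured round-specific target. Successes are
    binomial with

        logit(p_i) = intercept + district_effect
                     + (round_log_odds + secular_shift) * [endline]

    where ``round_log_odds`` is the program-attributable effect (the
    knob the binomial GLM should recover) and ``secular_shift`` absorbs
    system-wide change not attributable to the program. The two are
    collinear in a single-round-indicator model, so attribution
    analyses must generate with ``secular_shift=0``. The intercept is
    solved numerically so the expected baseline population success rate
    matches the configured target; when ``secular_shift`` is left
    unset, it is solved so the expected endline rate matches its
    target. Failure counts are allocated across cause categories by a
    round-specific multinomial.

One-shot farmer survey
    Sow ages follow a log-normal matched to the target mean/median and
    clipped to the configured range; success is Bernoulli on the logit
    scale with a breed effect (Large White vs. Landrace); full-term
    carriage and litter size apply only to successes.

Everything is reproducible from ``config.seed`` alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigurationError

DISTRICTS: tuple[str, ...] = (
    "Burera", "Gakenke", "Kayonza", "Ngoma",
    "Ngororero", "Nyamagabe", "Nyamasheke", "Rutsiro",
)

FAILURE_CAUSES: tuple[str, ...] = (
    "heat_detection", "animal_health", "expired_semen",
    "cold_chain", "technical_mistake", "other",
)

_SIMPLEX_TOL = 1e-9


def _check_simplex(name: str, probs: Mapping[str, float]) -> None:
    total = float(sum(probs.values()))
    if abs(total - 1.0) > _SIMPLEX_TOL:
        raise ConfigurationError(f"{name} must sum to 1 (got {total!r})")
    if any(v < 0 for v in probs.values()):
        raise ConfigurationError(f"{name} has negative entries")


def _uniform_district_weights() -> dict[str, float]:
    return {d: 1.0 / len(DISTRICTS) for d in DISTRICTS}


def _cahw_failure_probs() -> dict[str, dict[str, float]]:
    # narrative failure-cause shares; "other" absorbs the remainder
    base = {"heat_detection": 0.238, "animal_health": 0.221, "expired_semen": 0.118,
            "cold_chain": 0.105, "technical_mistake": 0.068}
    end = {"heat_detection": 0.278, "animal_health": 0.240, "expired_semen": 0.080,
           "cold_chain": 0.050, "technical_mistake": 0.020}
    base["other"] = 1.0 - sum(base.values())
    end["other"] = 1.0 - sum(end.values())
    return {"baseline": base, "endline": end}


def _vet_failure_probs() -> dict[str, dict[str, float]]:
    # synthetic: assembled from the reported challenge shares, remainder
    # in "other"; magnitudes per cause are not published as a simplex
    base = {"heat_detection": 0.504, "animal_health": 0.158, "expired_semen": 0.071,
            "cold_chain": 0.075, "technical_mistake": 0.049}
    end = {"heat_detection": 0.539, "animal_health": 0.088, "expired_semen": 0.118,
           "cold_chain": 0.080, "technical_mistake": 0.004}
    base["other"] = 1.0 - sum(base.values())
    end["other"] = 1.0 - sum(end.values())
    return {"baseline": base, "endline": end}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a two-round (baseline/endline) provider cohort.

    Defaults describe the CAHW cohort; :meth:`vet_default` returns the
    veterinarian parameterization (stable success, no round effect).
    """

    respondent_type: str = "cahw"
    n_baseline: int = 310
    n_endline: int = 240
    district_weights: Mapping[str, float] = field(default_factory=_uniform_district_weights)
    #: program-attributable endline log odds ratio of success
    round_log_odds: float = float(np.log(1.51))
    #: additional endline log-odds shift from system-wide change; None
    #: means "solve so the expected endline rate hits endline_mean_success"
    secular_shift: float | None = None
    baseline_mean_success: float = 0.488
    endline_mean_success: float = 0.748
    #: mean monthly procedures (of the zero-truncated count), per round
    procedures_rate_baseline: float = 3.2
    procedures_rate_endline: float = 4.3
    failure_cause_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=_cahw_failure_probs)
    #: elevated-success districts; magnitudes are synthetic defaults
    district_log_odds: Mapping[str, float] = field(
        default_factory=lambda: {"Nyamagabe": 0.3, "Nyamasheke": 0.3, "Rutsiro": 0.3})
    male_share: float = 0.66
    age_mean: float = 39.0
    age_sd: float = 10.0
    experience_mean: float = 3.5
    experience_median: float = 2.0
    ai_knowledge_mean: float = 1.39
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baseline <= 0 or self.n_endline <= 0:
            raise ConfigurationError("cohort sizes must be positive")
        if self.n_endline > self.n_baseline:
            raise ConfigurationError("endline roster cannot exceed baseline roster")
        _check_simplex("district_weights", self.district_weights)
        for rnd in ("baseline", "endline"):
            if rnd not in self.failure_cause_probs:
                raise ConfigurationError(f"failure_cause_probs missing round {rnd!r}")
            _check_simplex(f"failure_cause_probs[{rnd}]", self.failure_cause_probs[rnd])
            extra = set(self.failure_cause_probs[rnd]) - set(FAILURE_CAUSES)
            if extra:
                raise ConfigurationError(f"unknown failure causes {sorted(extra)}")
        for name in ("baseline_mean_success", "endline_mean_success", "male_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.baseline_mean_success < 1.0:
            raise ConfigurationError("baseline_mean_success of 0 or 1 is infeasible on the logit scale")
        if min(self.procedures_rate_baseline, self.procedures_rate_endline) <= 1.0:
            raise ConfigurationError("truncated procedure means must exceed 1")

    @property
    def attrition_rate(self) -> float:
        return 1.0 - self.n_endline / self.n_baseline

    @classmethod
    def cahw_default(cls, seed: int = 0, **overrides) -> "CohortConfig":
        return dataclasses.replace(cls(seed=seed), **overrides)

    @classmethod
    def vet_default(cls, seed: int = 0, **overrides) -> "CohortConfig":
        base = cls(
            respondent_type="vet",
            n_baseline=257,
            n_endline=221,
            round_log_odds=0.0,
            baseline_mean_success=0.745,
            endline_mean_success=0.748,
            procedures_rate_baseline=3.59,
            procedures_rate_endline=5.34,
            failure_cause_probs=_vet_failure_probs(),
            district_log_odds={},
            male_share=0.81,
            age_mean=33.6,
            age_sd=8.0,
            experience_mean=8.8,
            experience_median=7.0,
            ai_knowledge_mean=3.0,
            seed=seed,
        )
        return dataclasses.replace(base, **overrides)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        out["district_weights"] = dict(self.district_weights)
        out["district_log_odds"] = dict(self.district_log_odds)
        out["failure_cause_probs"] = {k: dict(v) for k, v in self.failure_cause_probs.items()}
        return out


def _default_farmer_districts() -> dict[str, float]:
    named = {"Gakenke": 0.285, "Nyamasheke": 0.207, "Burera": 0.112, "Nyamagabe": 0.108}
    rest = [d for d in DISTRICTS if d not in named]
    remainder = (1.0 - sum(named.values())) / len(rest)
    return {d: named.get(d, remainder) for d in DISTRICTS}


@dataclass(frozen=True)
class FarmerConfig:
    """Configuration of the one-shot farmer endline survey."""

    n: int = 233
    district_weights: Mapping[str, float] = field(default_factory=_default_farmer_districts)
    sow_age_mean: float = 14.88
    sow_age_median: float = 12.0
    sow_age_range: tuple[float, float] = (3.0, 96.0)
    parity_zero_share: float = 0.552
    parity_mean: float = 0.70
    first_time_share: float = 0.80
    breed_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Landrace": 0.85, "Large White": 0.15})
    #: log odds of success for Large White vs. Landrace
    breed_log_odds: float = float(np.log(0.24))
    overall_success_rate: float = 0.631
    district_log_odds: Mapping[str, float] = field(default_factory=dict)
    full_term_rate: float = 0.796
    litter_mean: float = 7.99
    litter_range: tuple[int, int] = (1, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError("n must be positive")
        _check_simplex("district_weights", self.district_weights)
        _check_simplex("breed_mix", self.breed_mix)
        if "Landrace" not in self.breed_mix:
            raise ConfigurationError("breed_mix must include the Landrace reference breed")
        for name in ("parity_zero_share", "first_time_share", "overall_success_rate",
                     "full_term_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.overall_success_rate < 1.0:
            raise ConfigurationError("overall_success_rate of 0 or 1 is infeasible")
        if self.sow_age_median <= 0 or self.sow_age_mean < self.sow_age_median:
            raise ConfigurationError("sow age needs mean >= median > 0 (right skew)")
        if self.parity_zero_share >= 1.0 and self.parity_mean > 0:
            raise ConfigurationError("parity_mean > 0 is infeasible with all-zero parity")

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        out["district_weights"] = dict(self.district_weights)
        out["breed_mix"] = dict(self.breed_mix)
        out["district_log_odds"] = dict(self.district_log_odds)
        return out


# ---------------------------------------------------------------------------
# Numeric helpers
# ---------------------------------------------------------------------------

def _solve_intercept(target: float, offsets: np.ndarray, weights: np.ndarray) -> float:
    """Intercept b0 with sum_j w_j * expit(b0 + offset_j) = target."""
    f = lambda b0: float(weights @ expit(b0 + offsets)) - target
    return float(brentq(f, -30.0, 30.0, xtol=1e-10))


def _truncated_poisson_rate(target_mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``target_mean``."""
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - target_mean
    return float(brentq(f, 1e-9, max(50.0, 10 * target_mean)))


def _sample_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    draws = rng.poisson(lam, size=size)
    while (mask := draws == 0).any():
        draws[mask] = rng.poisson(lam, size=int(mask.sum()))
    return draws


def _lognormal_params(mean: float, median: float) -> tuple[float, float]:
    mu = float(np.log(median))
    sigma = float(np.sqrt(2.0 * np.log(mean / median))) if mean > median else 0.0
    return mu, sigma


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _cohort_effects(config: CohortConfig) -> tuple[np.ndarray, float, float]:
    """Per-district offsets, solved intercept, and the realized secular
    shift for a cohort config."""
    weights = np.array([config.district_weights.get(d, 0.0) for d in DISTRICTS])
    offsets = np.array([config.district_log_odds.get(d, 0.0) for d in DISTRICTS])
    intercept = _solve_intercept(config.baseline_mean_success, offsets, weights)
    if config.secular_shift is not None:
        shift = config.secular_shift
    else:
        if not 0.0 < config.endline_mean_success < 1.0:
            raise ConfigurationError("endline_mean_success of 0 or 1 is infeasible")
        endline_intercept = _solve_intercept(config.endline_mean_success, offsets, weights)
        shift = endline_intercept - intercept - config.round_log_odds
    return offsets, intercept, shift


def generate_cahw_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a two-round CAHW (or, via config, veterinarian) cohort.

    One row per respondent-round; endline rows cover the retained
    subsample only. Columns: ``respondent_id, district, round, sex,
    age_years, experience_years, ai_knowledge_years, procedures,
    successes, failures`` plus one ``cause_*`` count column per failure
    cause.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_baseline

    weights = np.array([config.district_weights.get(d, 0.0) for d in DISTRICTS])
    district_idx = rng.choice(len(DISTRICTS), size=n, p=weights)
    sex = np.where(rng.random(n) < config.male_share, "male", "female")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 18.0, 80.0)
    exp_mu, exp_sigma = _lognormal_params(config.experience_mean, config.experience_median)
    experience = rng.lognormal(exp_mu, exp_sigma, size=n)
    knowledge = rng.exponential(config.ai_knowledge_mean, size=n)

    offsets, intercept, shift = _cohort_effects(config)
    base_logit = intercept + offsets[district_idx]
    retained = np.sort(rng.choice(n, size=config.n_endline, replace=False))

    frames = []
    for rnd, idx, extra, proc_mean in (
        ("baseline", np.arange(n), 0.0, config.procedures_rate_baseline),
        ("endline", retained, config.round_log_odds + shift, config.procedures_rate_endline),
    ):
        lam = _truncated_poisson_rate(proc_mean)
        procedures = _sample_truncated_poisson(rng, lam, len(idx))
        p = expit(base_logit[idx] + extra)
        successes = rng.binomial(procedures, p)
        frames.append(pd.DataFrame({
            "respondent_id": [f"{config.respondent_type}-{i:04d}" for i in idx],
            "district": [DISTRICTS[j] for j in district_idx[idx]],
            "round": rnd,
            "sex": sex[idx],
            "age_years": np.round(age[idx], 1),
            "experience_years": np.round(experience[idx], 2),
            "ai_knowledge_years": np.round(knowledge[idx], 2),
            "procedures": procedures,
            "successes": successes,
        }))
    records = pd.concat(frames, ignore_index=True)
    records["failures"] = records["procedures"] - records["successes"]
    return assign_failure_causes(records, config, rng=rng)


def generate_vet_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate the veterinarian cohort (stable success rate, no
    program-attributable round effect by default)."""
    return generate_cahw_cohort(config or CohortConfig.vet_default())


def assign_failure_causes(records: pd.DataFrame, config: CohortConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Allocate each record's failure count across the cause categories
    with the round-specific multinomial from the config. Returns a copy
    with one ``cause_<name>`` column per category."""
    if "failures" not in records.columns:
        raise ConfigurationError("records must carry a 'failures' column")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out = records.copy()
    counts = np.zeros((len(out), len(FAILURE_CAUSES)), dtype=int)
    for rnd in ("baseline", "endline"):
        mask = (out["round"] == rnd).to_numpy()
        if not mask.any():
            continue
        probs = np.array([config.failure_cause_probs[rnd].get(c, 0.0) for c in FAILURE_CAUSES])
        counts[mask] = rng.multinomial(out.loc[mask, "failures"].to_numpy(), probs)
    for j, cause in enumerate(FAILURE_CAUSES):
        out[f"cause_{cause}"] = counts[:, j]
    return out


def generate_farmer_survey(config: FarmerConfig | None = None) -> pd.DataFrame:
    """Generate the one-shot farmer endline survey.

    Columns: ``farmer_id, district, sow_age_months, parity, first_time,
    breed, ai_success, full_term, piglet_count`` (piglet count present
    only for full-term pregnancies).
    """
    config = config or FarmerConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n

    weights = np.array([config.district_weights.get(d, 0.0) for d in DISTRICTS])
    district_idx = rng.choice(len(DISTRICTS), size=n, p=weights)
    mu, sigma = _lognormal_params(config.sow_age_mean, config.sow_age_median)
    sow_age = np.clip(rng.lognormal(mu, sigma, size=n), *config.sow_age_range)

    nonzero = rng.random(n) >= config.parity_zero_share
    parity = np.zeros(n, dtype=int)
    if nonzero.any() and config.parity_zero_share < 1.0:
        # mean of the nonzero component chosen so the overall mean matches
        nz_mean = config.parity_mean / (1.0 - config.parity_zero_share)
        if nz_mean < 1.0:
            raise ConfigurationError("parity_mean too small for the configured zero share")
        parity[nonzero] = 1 + rng.poisson(nz_mean - 1.0, size=int(nonzero.sum()))
    first_time = rng.random(n) < config.first_time_share

    breeds = sorted(config.breed_mix)
    breed_probs = np.array([config.breed_mix[b] for b in breeds])
    breed = np.array(breeds, dtype=object)[rng.choice(len(breeds), size=n, p=breed_probs)]
    breed_offset = np.where(breed == "Landrace", 0.0, config.breed_log_odds)

    district_offset = np.array([config.district_log_odds.get(d, 0.0) for d in DISTRICTS])
    # expected offsets under the configured mixes, for the intercept solve
    combo_offsets, combo_weights = [], []
    for b in breeds:
        for j, d in enumerate(DISTRICTS):
            combo_offsets.append((0.0 if b == "Landrace" else config.breed_log_odds)
                                 + district_offset[j])
            combo_weights.append(config.breed_mix[b] * weights[j])
    intercept = _solve_intercept(config.overall_success_rate,
                                 np.array(combo_offsets), np.array(combo_weights))

    p = expit(intercept + breed_offset + district_offset[district_idx])
    success = rng.random(n) < p
    full_term = success & (rng.random(n) < config.full_term_rate)
    litter = np.clip(rng.poisson(config.litter_mean, size=n), *config.litter_range)
    piglets = np.where(full_term, litter, np.nan)

    return pd.DataFrame({
        "farmer_id": [f"farmer-{i:04d}" for i in range(n)],
        "district": [DISTRICTS[j] for j in district_idx],
        "sow_age_months": np.round(sow_age, 1),
        "parity": parity,
        "first_time": first_time.astype(int),
        "breed": breed,
        "ai_success": success.astype(int),
        "full_term": full_term.astype(int),
        "piglet_count": piglets,
    })


def write_survey(records: pd.DataFrame, config: CohortConfig | FarmerConfig,
                 out_dir: str | Path, name: str) -> tuple[Path, Path]:
    """Write a generated table as CSV plus a JSON provenance sidecar
    (config and seed). Returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{name}.csv"
    sidecar_path = out_dir / f"{name}.provenance.json"
    records.to_csv(csv_path, index=False)
    sidecar = {"table": name, "n_records": int(len(records)),
               "seed": config.seed, "config": config.to_jsonable()}
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
    return csv_path, sidecar_path
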