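"""Statistical stages of the pre-post survey analysis.

Implements the inferential toolkit applied to the survey microdata:
descriptive summaries, paired tests for baseline-to-endline change
within a cohort, an OLS model of the self-reported success *proportion*,
a binomial GLM of successes/failures per CAHW (the model whose round
odds ratio feeds the economic engine), and a farmer-level logistic
regression of insemination success on sow characteristics.

All model fits are maximum likelihood via statsmodels (IRLS for the
GLMs, relative-deviance tolerance 1e-8, at most 100 iterations);
reference categories are fixed so contrasts are deterministic: district
Burera (first alphabetically), round baseline, sex female, breed
Landrace. Inference is two-sided Wald throughout; no multiple-testing
adjustment is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    RankDeficiencyError,
    SeparationError,
)

logger = logging.getLogger(__name__)

#: Reference level for each categorical regressor.
REFERENCE_LEVELS: dict[str, str] = {
    "district": "Burera",
    "round": "baseline",
    "sex": "female",
    "breed": "Landrace",
}


@dataclass(frozen=True)
class Term:
    name: str
    coefficient: float
    standard_error: float


@dataclass(frozen=True)
class ModelFit:
    """A fitted regression stage.

    ``terms`` carries (name, coefficient, SE) triples; for logit-link
    fits ``exp(coefficient)`` is the odds ratio for that term.
    """

    terms: tuple[Term, ...]
    family: str  # "gaussian" | "binomial"
    link: str  # "identity" | "logit"
    n_observations: int
    converged: bool
    n_excluded: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term {name!r}; available: {[t.name for t in self.terms]}")

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def to_dict(self) -> dict:
        out = {
            "family": self.family,
            "link": self.link,
            "n_observations": self.n_observations,
            "n_excluded": self.n_excluded,
            "converged": self.converged,
            "terms": [],
        }
        for t in self.terms:
            entry = {"name": t.name, "coefficient": t.coefficient,
                     "standard_error": t.standard_error}
            if self.link == "logit":
                odds_ratio = extract_odds_ratio(self, t.name)
                entry.update(odds_ratio._asdict())
            out["terms"].append(entry)
        return out


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    mean_difference: float | None = None


# ---------------------------------------------------------------------------
# Descriptives and paired tests
# ---------------------------------------------------------------------------

def descriptive_summary(records: pd.DataFrame, fields: Sequence[str]) -> pd.DataFrame:
    """Per-field summary statistics, excluding missing values per field.

    Binary fields (two or fewer distinct values, all in {0, 1, True,
    False}) additionally report a proportion.
    """
    if len(records) == 0:
        raise InsufficientDataError("empty record collection")
    unknown = [f for f in fields if f not in records.columns]
    if unknown:
        raise ConfigurationError(f"unknown field(s): {unknown}")
    rows = []
    for name in fields:
        col = records[name]
        values = pd.to_numeric(col, errors="coerce") if col.dtype == object else col
        values = values.dropna().astype(float)
        is_binary = len(values) > 0 and set(np.unique(values)) <= {0.0, 1.0}
        rows.append({
            "field": name,
            "n": int(len(values)),
            "n_missing": int(len(col) - len(values)),
            "mean": float(values.mean()) if len(values) else np.nan,
            "median": float(values.median()) if len(values) else np.nan,
            "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            "proportion": float(values.mean()) if is_binary else np.nan,
        })
    return pd.DataFrame(rows).set_index("field")


def paired_t_test(before: Mapping | pd.Series, after: Mapping | pd.Series) -> PairedTestResult:
    """Paired-sample t-test on differences, matching observations by
    respondent id (the mapping key / Series index).

    Degenerate case: zero variance of the differences with a nonzero
    mean is reported as an infinite statistic with p = 0.
    """
    before = pd.Series(dict(before) if not isinstance(before, pd.Series) else before)
    after = pd.Series(dict(after) if not isinstance(after, pd.Series) else after)
    ids = before.index.intersection(after.index)
    d = (after.loc[ids].astype(float) - before.loc[ids].astype(float)).dropna()
    n = len(d)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 complete pairs, got {n}")
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTestResult(0.0, df, 1.0, 0.0)
        stat = float(np.sign(mean_d)) * float("inf")
        return PairedTestResult(stat, df, 0.0, mean_d)
    stat = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(stat), df)
    return PairedTestResult(float(stat), df, float(p), mean_d)


def mcnemar_test(discordant_b: int, discordant_c: int,
                 continuity_correction: bool = False) -> PairedTestResult:
    """McNemar's chi-square test on the discordant-pair counts of a
    paired binary outcome. Continuity correction is off by default."""
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise DomainError("discordant counts must be >= 0")
    if b + c == 0:
        raise InsufficientDataError("no discordant pairs: statistic undefined")
    diff = abs(b - c)
    if continuity_correction:
        diff = max(diff - 1.0, 0.0)
    stat = diff**2 / (b + c)
    p = float(scipy.stats.chi2.sf(stat, df=1))
    return PairedTestResult(float(stat), 1, p)


# ---------------------------------------------------------------------------
# Design-matrix construction
# ---------------------------------------------------------------------------

def _design_matrix(df: pd.DataFrame, numeric: Sequence[str],
                   categorical: Sequence[str]) -> pd.DataFrame:
    """Intercept + numeric columns + treatment-coded dummies.

    Reference levels come from :data:`REFERENCE_LEVELS` (first observed
    level otherwise). Single-level categoricals are dropped: a cohort
    from one district still fits, just without district contrasts.
    """
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    for col in numeric:
        X[col] = df[col].astype(float)
    for col in categorical:
        levels = sorted(df[col].astype(str).unique())
        if len(levels) < 2:
            logger.info("dropping single-level categorical %r", col)
            continue
        ref = REFERENCE_LEVELS.get(col)
        if ref not in levels:
            ref = levels[0]
        for level in levels:
            if level == ref:
                continue
            X[f"{col}[{level}]"] = (df[col].astype(str) == level).astype(float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR: columns pivoted beyond the numerical rank are the
        # ones expressible in terms of the others
        _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[j] for j in piv[np.count_nonzero(diag > tol):]]
        raise RankDeficiencyError(bad)


CAHW_NUMERIC = ("age_years", "experience_years", "ai_knowledge_years")
CAHW_CATEGORICAL = ("sex", "district", "round")


def _present(columns: Sequence[str], df: pd.DataFrame) -> list[str]:
    # absent covariate columns are simply not modelled, so aggregated
    # tables (e.g. a 2x2 round-by-outcome layout) fit as saturated models
    return [c for c in columns if c in df.columns]


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

def fit_success_rate_ols(records: pd.DataFrame) -> ModelFit:
    """OLS of the per-respondent success proportion (successes /
    procedures over the recall window) on sex, age, experience, AI
    knowledge, district and survey round.

    Records with zero procedures carry no defined proportion and are
    excluded (count logged and reported on the fit).
    """
    usable = records[records["procedures"] > 0]
    n_excluded = len(records) - len(usable)
    if n_excluded:
        logger.info("fit_success_rate_ols: excluded %d zero-procedure records", n_excluded)
    if len(usable) < 2:
        raise InsufficientDataError("too few records with procedures > 0")
    y = (usable["successes"] / usable["procedures"]).astype(float)
    X = _design_matrix(usable, _present(CAHW_NUMERIC, usable), _present(CAHW_CATEGORICAL, usable))
    _check_rank(X)
    res = sm.OLS(y.to_numpy(), X.to_numpy(float)).fit()
    terms = tuple(Term(n, float(b), float(se))
                  for n, b, se in zip(X.columns, res.params, res.bse))
    return ModelFit(terms, "gaussian", "identity", int(len(usable)), True, n_excluded)


def _fit_binomial(endog: np.ndarray, X: pd.DataFrame, n_excluded: int) -> ModelFit:
    _check_rank(X)
    successes, failures = endog[:, 0], endog[:, 1]
    # a saturated outcome admits no finite MLE for some term; detect the
    # trivial global cases up front with a clear message
    if successes.sum() == 0 or failures.sum() == 0:
        raise SeparationError("outcome", "all observations share one outcome: no finite MLE")
    model = sm.GLM(endog, X.to_numpy(float), family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # statsmodels raises PerfectSeparationError among others
        if "separat" in str(exc).lower():
            raise SeparationError("unknown", str(exc)) from exc
        raise
    # complete separation by a covariate shows up as a diverging
    # coefficient with an enormous standard error
    for name, beta, se in zip(X.columns, res.params, res.bse):
        if name != "intercept" and (abs(beta) > 30 or not np.isfinite(se) or se > 1e3):
            raise SeparationError(name)
    terms = tuple(Term(n, float(b), float(se))
                  for n, b, se in zip(X.columns, res.params, res.bse))
    return ModelFit(terms, "binomial", "logit", int(len(X)), bool(res.converged), n_excluded)


def fit_binomial_glm(records: pd.DataFrame) -> ModelFit:
    """Binomial GLM (logit link) of successes vs. failures per CAHW on
    the covariate set with district fixed effects.

    The ``round[endline]`` coefficient is the log odds ratio of success
    at endline — the quantity that drives the attributable share of the
    economic model.
    """
    if (records["successes"] > records["procedures"]).any():
        raise DomainError("successes exceed procedures in at least one record")
    usable = records[records["procedures"] > 0]
    n_excluded = len(records) - len(usable)
    if n_excluded:
        logger.info("fit_binomial_glm: excluded %d zero-trial records", n_excluded)
    if len(usable) < 2:
        raise InsufficientDataError("too few records with procedures > 0")
    endog = np.column_stack([
        usable["successes"].to_numpy(float),
        (usable["procedures"] - usable["successes"]).to_numpy(float),
    ])
    X = _design_matrix(usable, _present(CAHW_NUMERIC, usable), _present(CAHW_CATEGORICAL, usable))
    return _fit_binomial(endog, X, n_excluded)


FARMER_NUMERIC = ("sow_age_months", "parity")
FARMER_CATEGORICAL = ("breed", "district")


def fit_farmer_logistic(records: pd.DataFrame) -> ModelFit:
    """Logistic regression of farmer-reported insemination success on
    sow characteristics (breed vs. Landrace, age, pregnancy history)
    with district fixed effects."""
    if len(records) < 2:
        raise InsufficientDataError("too few farmer records")
    y = records["ai_success"].astype(float).to_numpy()
    endog = np.column_stack([y, 1.0 - y])
    X = _design_matrix(records, _present(FARMER_NUMERIC, records), _present(FARMER_CATEGORICAL, records))
    return _fit_binomial(endog, X, 0)


class OddsRatio(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def extract_odds_ratio(fit: ModelFit, term: str, level: float = 0.95) -> OddsRatio:
    """Odds ratio ``exp(beta)`` with Wald confidence interval
    ``exp(beta +/- z*SE)`` and two-sided Wald p-value for one term of a
    logit-link fit."""
    if fit.link != "logit":
        raise ConfigurationError(f"odds ratios require a logit link, fit has {fit.link!r}")
    if not 0.0 < level < 1.0:
        raise DomainError(f"confidence level must lie in (0, 1), got {level!r}")
    t = fit.term(term)
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    wald = t.coefficient / t.standard_error
    return OddsRatio(
        odds_ratio=float(np.exp(t.coefficient)),
        ci_low=float(np.exp(t.coefficient - z * t.standard_error)),
        ci_high=float(np.exp(t.coefficient + z * t.standard_error)),
        p_value=float(2.0 * scipy.stats.norm.sf(abs(wald))),
    )
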