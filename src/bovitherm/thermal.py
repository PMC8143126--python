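"""Temperature-difference construction and staged AICc model selection.

The response of interest is either the animal's surface temperature
(``temp_cow``) or its signed difference from ambient air temperature,
``delta_t = temp_cow - temp_amb``. Candidate predictors are daily weather and
radiation covariates plus animal attributes (hide albedo, and the surface
temperature itself when the response is ``delta_t``).

Model selection follows a three-step information-theoretic protocol:

1. within-source-group correlation pruning removes one variable of every pair
   with |Pearson r| above a cutoff (default 0.7), using an explicit
   drop-preference list;
2. the best single "weather" predictor and the best single "radiation"
   predictor are each chosen by AICc against a null (intercept-only) model;
3. nested combinations of the two step winners and the animal attributes are
   ranked by AICc, with Akaike weights, the dAICc <= 2 top set, and a final
   95%-confidence-interval screen flagging coefficients whose interval
   excludes zero as informative.

AICc is the small-sample-corrected Akaike criterion
``-2 logL + 2K + 2K(K+1)/(n - K - 1)`` with K counting the intercept, every
slope, and the residual variance (so a one-predictor model has K = 3 and the
null K = 2).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: Source of each covariate: pruning compares only similarly sourced variables.
DEFAULT_SOURCE_GROUPS: dict[str, str] = {
    "temp_amb": "field",
    "humidity": "station",
    "wind_speed": "station",
    "temp_dew": "prism",
    "vpd": "prism",
    "temp_earth": "satellite",
    "ktclear": "satellite",
    "rad_lw": "satellite",
    "rad_sw": "satellite",
}

#: Of a flagged correlated pair, drop the member appearing in this list.
DEFAULT_DROP_PREFERENCE: tuple[str, ...] = ("temp_earth", "humidity", "vpd")

#: Step-1 "weather" and step-2 "radiation" candidate predictors.
DEFAULT_WEATHER_CANDIDATES: tuple[str, ...] = ("temp_amb", "temp_dew", "wind_speed")
DEFAULT_RADIATION_CANDIDATES: tuple[str, ...] = ("ktclear", "rad_lw", "rad_sw")

#: Models within this dAICc of the best are reported as the top set.
TOP_SET_DELTA = 2.0


def fahrenheit_to_celsius(f):
    """Convert degrees Fahrenheit to degrees Celsius."""
    arr = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("temperature must be finite")
    out = (arr - 32.0) * 5.0 / 9.0
    return float(out) if arr.ndim == 0 else out


def compute_delta_t(temp_cow, temp_amb):
    """Signed temperature difference dT = temp_cow - temp_amb (degC).

    The difference is kept signed: an animal surface slightly colder than the
    air (radiative cooling on clear nights) yields a negative dT, and the
    negative regression slopes of dT on ambient temperature only make sense
    on the signed scale.
    """
    a = np.asarray(temp_cow, dtype=float)
    b = np.asarray(temp_amb, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("temperatures must be finite")
    out = a - b
    return float(out) if out.ndim == 0 else out


def assemble_dataset(observations: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Join observations with daily covariates on ``date_index``.

    Every observation date must be present in the covariate table; the merge
    preserves the observation row count and order.
    """
    for frame, name in ((observations, "observations"), (covariates, "covariates")):
        if "date_index" not in frame.columns:
            raise ValueError(f"{name} table lacks a date_index column")
    missing = sorted(set(observations["date_index"]) - set(covariates["date_index"]))
    if missing:
        raise ValueError(f"covariates missing for date_index values: {missing}")
    merged = observations.merge(covariates, on="date_index", how="left", validate="m:1")
    assert len(merged) == len(observations)
    return merged


def prune_correlated(
    data: pd.DataFrame,
    source_groups: Mapping[str, str] | None = None,
    threshold: float = 0.7,
    drop_preference: Sequence[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Remove one member of every highly correlated same-source pair.

    Within each source group, every pair of variables with |Pearson r| >
    ``threshold`` is resolved by dropping the member named in
    ``drop_preference``; a flagged pair containing neither (or both) preferred
    names is an error demanding an explicit rule. Returns the retained
    variable names and a report listing each flagged pair, its r, and the
    variable removed. The operation is idempotent: re-running it on its own
    output removes nothing.
    """
    if source_groups is None:
        source_groups = DEFAULT_SOURCE_GROUPS
    if drop_preference is None:
        drop_preference = DEFAULT_DROP_PREFERENCE
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    variables = [v for v in data.columns if v in source_groups]
    if len(variables) < 2:
        raise ValueError("need at least two source-tagged variables to prune")
    dropped: set[str] = set()
    rows = []
    by_group: dict[str, list[str]] = {}
    for v in variables:
        by_group.setdefault(source_groups[v], []).append(v)
    for group_vars in by_group.values():
        for a, b in itertools.combinations(group_vars, 2):
            r = float(np.corrcoef(data[a], data[b])[0, 1])
            if abs(r) <= threshold:
                continue
            a_pref, b_pref = a in drop_preference, b in drop_preference
            if a_pref == b_pref:
                raise ValueError(
                    f"correlated pair ({a}, {b}) with r = {r:.3f}: the drop "
                    "preference list resolves neither or both members; supply "
                    "an explicit rule"
                )
            victim = a if a_pref else b
            dropped.add(victim)
            rows.append({"var_a": a, "var_b": b, "r": r, "dropped": victim})
    retained = [v for v in variables if v not in dropped]
    report = pd.DataFrame(rows, columns=["var_a", "var_b", "r", "dropped"])
    return retained, report


@dataclass(frozen=True)
class ModelFit:
    """One fitted linear model with its information-criterion bookkeeping."""

    terms: tuple[str, ...]
    n: int
    k: int  # intercept + slopes + residual variance
    loglik: float
    aicc: float
    params: pd.Series
    conf_int: pd.DataFrame  # columns "lower", "upper"
    ssr: float

    @property
    def name(self) -> str:
        return " + ".join(self.terms) if self.terms else "null"


def fit_ols(data: pd.DataFrame, response: str, terms: Sequence[str]) -> ModelFit:
    """Ordinary least squares fit of ``response`` on ``terms`` plus intercept.

    Gaussian log-likelihood and 95% confidence intervals from the t
    distribution with the residual degrees of freedom. The empty term list
    fits the null (intercept-only) model.
    """
    terms = tuple(terms)
    y = data[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y))] + [data[t].to_numpy(dtype=float) for t in terms]
    )
    n, p = X.shape
    k = p + 1  # + residual variance
    if n <= k + 1:
        raise ValueError(f"n = {n} too small for K = {k}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"design matrix for terms {terms} is rank deficient")
    result = sm.OLS(y, X).fit()
    ci = result.conf_int(alpha=0.05)
    index = ["intercept", *terms]
    params = pd.Series(result.params, index=index)
    conf = pd.DataFrame(ci, index=index, columns=["lower", "upper"])
    fit = ModelFit(
        terms=terms,
        n=n,
        k=k,
        loglik=float(result.llf),
        aicc=aicc(float(result.llf), k, n),
        params=params,
        conf_int=conf,
        ssr=float(result.ssr),
    )
    logger.info("fit %s: n=%d K=%d AICc=%.2f", fit.name, fit.n, fit.k, fit.aicc)
    return fit


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n = {n}, K = {k} (need n > K + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Rescale AICc values to (dAICc, Akaike weights).

    dAICc is relative to the smallest value; weights are the renormalized
    relative likelihoods exp(-dAICc/2) and sum to one. Invariant to adding a
    constant to every AICc.
    """
    arr = np.asarray(aiccs, dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValueError("need at least one finite AICc value")
    delta = arr - arr.min()
    rel = np.exp(-delta / 2.0)
    return delta, rel / rel.sum()


def ci_screen(fit: ModelFit, level: float = 0.95) -> dict[str, bool]:
    """Flag each slope coefficient informative iff its CI excludes zero."""
    if level != 0.95:
        raise NotImplementedError("only the 95% screening level is supported")
    flags = {}
    for term in fit.terms:
        lo, hi = fit.conf_int.loc[term, "lower"], fit.conf_int.loc[term, "upper"]
        flags[term] = bool(lo > 0 or hi < 0)
    return flags


@dataclass(frozen=True)
class SelectionStep:
    """Ranked ledger of one selection step."""

    name: str
    table: pd.DataFrame  # model, K, AICc, delta_aicc, weight, in_top_set
    fits: tuple[ModelFit, ...]
    winner: ModelFit


@dataclass(frozen=True)
class SelectionReport:
    """Full ledger of the three-step selection."""

    steps: tuple[SelectionStep, ...]
    weather_term: str
    radiation_term: str
    final_fit: ModelFit
    ci_flags: Mapping[str, bool]

    @property
    def final_terms(self) -> tuple[str, ...]:
        return self.final_fit.terms


def _rank_models(name: str, fits: Sequence[ModelFit]) -> SelectionStep:
    delta, weights = akaike_weights([f.aicc for f in fits])
    # deterministic ranking: AICc, then parsimony, then lexicographic
    order = sorted(
        range(len(fits)),
        key=lambda i: (fits[i].aicc, len(fits[i].terms), fits[i].terms),
    )
    fits = [fits[i] for i in order]
    delta, weights = delta[order], weights[order]
    delta = delta - delta[0]  # exact zero for the top model after reordering
    table = pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "K": [f.k for f in fits],
            "AICc": [f.aicc for f in fits],
            "delta_aicc": delta,
            "weight": weights,
            "in_top_set": delta <= TOP_SET_DELTA,
        }
    )
    return SelectionStep(name=name, table=table, fits=tuple(fits), winner=fits[0])


def _step3_candidates(
    weather: str, radiation: str, animal_terms: Sequence[str]
) -> list[tuple[str, ...]]:
    """Nested candidate set: winners with every subset of animal attributes,
    then each winner alone, then the null."""
    candidates: list[tuple[str, ...]] = []
    animal_terms = list(animal_terms)
    for size in range(len(animal_terms), -1, -1):
        for subset in itertools.combinations(animal_terms, size):
            candidates.append((weather, radiation, *subset))
    candidates.append((weather,))
    candidates.append((radiation,))
    candidates.append(())
    return candidates


def staged_selection(
    data: pd.DataFrame,
    response: str = "temp_cow",
    weather_candidates: Sequence[str] = DEFAULT_WEATHER_CANDIDATES,
    radiation_candidates: Sequence[str] = DEFAULT_RADIATION_CANDIDATES,
    animal_terms: Sequence[str] | None = None,
) -> SelectionReport:
    """Run the three-step AICc selection and CI screen on an analysis table.

    ``animal_terms`` defaults to hide albedo, plus the surface temperature
    when the response is the temperature difference. A null model is included
    in every step; ties in AICc are broken by parsimony, then lexicographic
    term order.
    """
    if animal_terms is None:
        animal_terms = ("albedo", "temp_cow") if response == "delta_t" else ("albedo",)
    if not weather_candidates or not radiation_candidates:
        raise ValueError("candidate sets must be non-empty")

    step1 = _rank_models(
        "step1_weather",
        [fit_ols(data, response, [v]) for v in weather_candidates]
        + [fit_ols(data, response, [])],
    )
    step2 = _rank_models(
        "step2_radiation",
        [fit_ols(data, response, [v]) for v in radiation_candidates]
        + [fit_ols(data, response, [])],
    )
    # carry the best single-term model forward even if the null ranks first
    weather = next(f for f in step1.fits if f.terms).terms[0]
    radiation = next(f for f in step2.fits if f.terms).terms[0]
    step3 = _rank_models(
        "step3_combined",
        [
            fit_ols(data, response, terms)
            for terms in _step3_candidates(weather, radiation, animal_terms)
        ],
    )
    final = step3.winner
    return SelectionReport(
        steps=(step1, step2, step3),
        weather_term=weather,
        radiation_term=radiation,
        final_fit=final,
        ci_flags=ci_screen(final),
    )


class StagedAICcSelector(BaseEstimator):
    """Scikit-learn-style wrapper around the staged AICc selection.

    Parameters mirror :func:`staged_selection`; ``prune`` controls whether
    within-source correlation pruning runs first (its report is stored).

    Attributes (after :meth:`fit`): ``report_``, ``final_terms_``,
    ``final_fit_``, ``ci_flags_``, ``retained_``, ``pruning_report_``.
    """

    def __init__(
        self,
        response: str = "temp_cow",
        weather_candidates: Sequence[str] = DEFAULT_WEATHER_CANDIDATES,
        radiation_candidates: Sequence[str] = DEFAULT_RADIATION_CANDIDATES,
        animal_terms: Sequence[str] | None = None,
        prune: bool = True,
        correlation_threshold: float = 0.7,
        drop_preference: Sequence[str] = DEFAULT_DROP_PREFERENCE,
    ):
        self.response = response
        self.weather_candidates = weather_candidates
        self.radiation_candidates = radiation_candidates
        self.animal_terms = animal_terms
        self.prune = prune
        self.correlation_threshold = correlation_threshold
        self.drop_preference = drop_preference

    def fit(self, X: pd.DataFrame, y=None):
        data = X
        weather = list(self.weather_candidates)
        radiation = list(self.radiation_candidates)
        if self.prune:
            self.retained_, self.pruning_report_ = prune_correlated(
                data,
                threshold=self.correlation_threshold,
                drop_preference=self.drop_preference,
            )
            weather = [v for v in weather if v in self.retained_]
            radiation = [v for v in radiation if v in self.retained_]
        else:
            self.retained_, self.pruning_report_ = None, None
        self.report_ = staged_selection(
            data,
            response=self.response,
            weather_candidates=weather,
            radiation_candidates=radiation,
            animal_terms=self.animal_terms,
        )
        self.final_fit_ = self.report_.final_fit
        self.final_terms_ = self.report_.final_terms
        self.ci_flags_ = dict(self.report_.ci_flags)
        return self
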