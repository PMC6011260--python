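"""Crude and model-based absolute and relative injury-rate estimation.

Crude rates pool events and person-time over a cumulative window of months
before the interview; because of memory decay they are negatively biased for
windows extending beyond month 1. Model-based estimates weight predicted
month-1 (t = 0) rates by observed month-1 person-years, which removes the
decay bias when the fitted model carries a time effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .cohort import PersonTimeTable
from .factors import FACTORS, check_level
from .model import RecallDecayResults, design_matrix

Z95 = 1.959963984540054

__all__ = [
    "RateEstimate",
    "crude_rate",
    "cumulative_crude_rates",
    "percent_decline",
    "model_based_rate",
    "relative_rate",
]


@dataclass(frozen=True)
class RateEstimate:
    """A rate per 100 person-years with a 95% confidence interval."""

    rate: float
    ci_low: float
    ci_high: float
    events: int
    person_years: float
    window: tuple[int, ...]
    flagged: bool = False  # CI not available by the standard formula


def crude_rate(
    events: int, person_years: float, window: Iterable[int] = ()
) -> RateEstimate:
    """Crude incidence per 100 person-years with a log-scale Wald 95% CI.

    The CI is ``rate * exp(+/- 1.96 / sqrt(events))``; with zero events the
    point estimate is 0 and the upper bound uses the exact zero-count Poisson
    limit 3.0 * 100 / person_years (the flagged "rule of three").
    """
    if person_years <= 0:
        raise ValueError(f"person_years must be positive; got {person_years}")
    events = int(events)
    if events < 0:
        raise ValueError("events must be nonnegative")
    rate = 100.0 * events / person_years
    if events == 0:
        return RateEstimate(
            rate=0.0,
            ci_low=0.0,
            ci_high=300.0 / person_years,
            events=0,
            person_years=person_years,
            window=tuple(window),
            flagged=True,
        )
    half = Z95 / math.sqrt(events)
    return RateEstimate(
        rate=rate,
        ci_low=rate * math.exp(-half),
        ci_high=rate * math.exp(half),
        events=events,
        person_years=person_years,
        window=tuple(window),
    )


def cumulative_crude_rates(
    table: PersonTimeTable, windows: Sequence[Iterable[int]]
) -> list[RateEstimate]:
    """Crude rates for a list of cumulative month windows (e.g. {1}, {1..11})."""
    out = []
    for window in windows:
        months = sorted(int(m) for m in window)
        if not months:
            raise ValueError("empty month window")
        events, py = table.window_totals(months)
        out.append(crude_rate(events, py, window=months))
    return out


def percent_decline(reference: RateEstimate, other: RateEstimate) -> float:
    """Percent decline from a reference-window rate to another window's rate."""
    return 100.0 * (reference.rate - other.rate) / reference.rate


def _month1_weights(table: PersonTimeTable, spec) -> pd.DataFrame:
    """Observed covariate combinations with month-1 person-year weights."""
    df = table.data
    m1 = df[df["month"] == 1]
    if m1.empty:
        raise ValueError("table has no month-1 exposure to weight predictions by")
    w = (
        m1.groupby(list(FACTORS), observed=True, sort=True)["person_years"]
        .sum()
        .reset_index()
    )
    w = w[w["person_years"] > 0].reset_index(drop=True)
    w["month"] = 1
    return w


def model_based_rate(
    results: RecallDecayResults,
    table: PersonTimeTable,
    window: Iterable[int] = (1,),
) -> RateEstimate:
    """Person-year-weighted mean of predicted month-1 rates, per 100 PY.

    Predictions are evaluated at t = 0 for every covariate combination
    observed in month 1 and weighted by that combination's month-1
    person-years; with a time effect in the spec this is the decay-corrected
    overall rate. The fit must not include a household random intercept:
    random effects systematically shrink population-level predicted rates,
    so such fits are rejected.

    The CI is a delta-method Wald interval propagated from the coefficient
    covariance (the window's pooled events/person-years are reported
    alongside for reference).
    """
    if results.spec.random_household:
        raise ValueError(
            "model_based_rate requires a fit without a household random effect"
        )
    weights = _month1_weights(table, results.spec)
    rates = results.predict_rate(weights)  # per person-year
    w = weights["person_years"].to_numpy()
    w = w / w.sum()
    point = 100.0 * float(w @ rates)

    # delta method: d(rate)/d(beta) = 100 * sum_i w_i rate_i x_i
    X, _ = design_matrix(results.spec, weights)
    grad = 100.0 * (w * rates) @ X
    cov = results.cov_params.loc[
        results.fixed_params.index, results.fixed_params.index
    ].to_numpy()
    var = float(grad @ cov @ grad)
    se = math.sqrt(max(var, 0.0))
    events, py = table.window_totals(window)
    return RateEstimate(
        rate=point,
        ci_low=point - Z95 * se,
        ci_high=point + Z95 * se,
        events=events,
        person_years=py,
        window=tuple(sorted(int(m) for m in window)),
    )


def model_based_rate_se(
    results: RecallDecayResults, table: PersonTimeTable
) -> float:
    """Delta-method standard error of :func:`model_based_rate` (per 100 PY)."""
    est = model_based_rate(results, table)
    return (est.ci_high - est.rate) / Z95


def relative_rate(
    results: RecallDecayResults,
    factor: str,
    level: str,
    reference: str | None = None,
    alpha: float = 0.05,
):
    """Rate ratio between two levels of a main-effect factor, with a Wald CI.

    In models with effect modification of the time term, main effects are
    defined at t = 0, so the contrast is the month-1 (true-rate) relative
    rate. Returns ``(ratio, ci_low, ci_high)``.
    """
    from scipy.stats import norm

    check_level(factor, level)
    if factor not in results.spec.main_effects:
        raise ValueError(f"factor {factor!r} is not a main effect in this fit")
    ref = reference if reference is not None else results.spec.reference(factor)
    check_level(factor, ref)

    names = results.fixed_params.index

    def coef_vec(lev):
        v = pd.Series(0.0, index=names)
        name = f"{factor}[{lev}]"
        if lev == results.spec.reference(factor):
            return v
        if name not in names:
            raise ValueError(f"level {lev!r} has no coefficient in this fit")
        v[name] = 1.0
        return v

    contrast = coef_vec(level) - coef_vec(ref)
    b = float(contrast @ results.fixed_params)
    cov = results.cov_params.loc[names, names].to_numpy()
    se = math.sqrt(float(contrast.to_numpy() @ cov @ contrast.to_numpy()))
    z = norm.ppf(1 - alpha / 2)
    return math.exp(b), math.exp(b - z * se), math.exp(b + z * se)
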