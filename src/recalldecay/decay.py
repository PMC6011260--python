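"""Memory-decay curves and rate/average-rate conversions.

The reporting probability for an injury that occurred in month ``m`` before
the interview is modelled as ``exp(b1*t + b2*t^2 + b3*t^3)`` with ``t = m - 1``,
anchored at 1 in month 1. The time origin ``t = 0`` corresponds to the middle
of the month immediately preceding the interview, which is where the derived
half-recall times live.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

LOG_HALF = math.log(0.5)
#: Upper end of the t range searched for the half-recall time (months).
T_MAX = 11.0


@dataclass(frozen=True)
class DecayCurve:
    """Polynomial log-reporting-probability coefficients (linear term first)."""

    coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.coeffs) <= 3:
            raise ValueError("DecayCurve supports degrees 1..3")
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))

    @property
    def degree(self) -> int:
        return len(self.coeffs)

    def log_reporting(self, t):
        """Log reporting probability at elapsed time ``t`` (months)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for j, c in enumerate(self.coeffs, start=1):
            out = out + c * t**j
        return out


def reporting_probability(curve: DecayCurve, month: int) -> float:
    """Probability that an injury occurring in a given month is reported.

    Evaluates ``exp(sum_j b_j (m-1)^j)``. Month 1 gives exactly 1. A value
    above 1 (non-decay-like coefficients) is returned as-is with a warning:
    the exponential term is only interpretable as a probability when it is
    a decreasing function of elapsed time.
    """
    m = int(month)
    if not 1 <= m <= 12:
        raise ValueError(f"month must be in 1..12; got {month}")
    p = float(np.exp(curve.log_reporting(m - 1)))
    if p > 1.0:
        warnings.warn(
            f"reporting probability {p:.3f} > 1 in month {m}; "
            "coefficients are not decay-like",
            stacklevel=2,
        )
    return p


def half_recall_time(curve: DecayCurve) -> float | None:
    """Elapsed time (months) at which the reporting probability falls to 0.5.

    Smallest ``t > 0`` solving ``sum_j b_j t^j = ln(1/2)``, on the same t
    scale as the curve (t = 0 at the middle of the month preceding the
    interview). Returns ``None`` when no root lies in ``(0, 11]`` — e.g. when
    reporting never drops to one half within the recall window.
    """
    if all(c == 0.0 for c in curve.coeffs):
        raise ValueError("curve must have at least one nonzero coefficient")
    g = lambda t: float(curve.log_reporting(t)) - LOG_HALF

    if curve.degree == 1:
        b1 = curve.coeffs[0]
        if b1 >= 0:
            return None
        t = LOG_HALF / b1
        return t if 0 < t <= T_MAX else None

    if curve.degree == 2:
        b1, b2 = curve.coeffs
        if b2 == 0.0:
            return half_recall_time(DecayCurve((b1,)))
        # roots of b2 t^2 + b1 t - ln(1/2) = 0, via the cancellation-free
        # Citardauq form (stable for |b2| << |b1|)
        c = -LOG_HALF
        disc = b1 * b1 - 4.0 * b2 * c
        if disc < 0:
            return None
        q = -(b1 + math.copysign(math.sqrt(disc), b1)) / 2.0
        roots = sorted(r for r in (q / b2 if q else math.nan, c / q if q else math.nan)
                       if math.isfinite(r))
        for t in roots:
            if 0 < t <= T_MAX:
                return t
        return None

    # degree 3: scan for a sign change, then bracketed root-finding
    grid = np.linspace(1e-9, T_MAX, 4096)
    vals = curve.log_reporting(grid) - LOG_HALF
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        return None
    i = sign_change[0]
    return float(brentq(g, grid[i], grid[i + 1], xtol=1e-12))


@dataclass(frozen=True)
class AvgRateModel:
    """Instantaneous-rate model ``mu(t)`` with a closed or numeric window average.

    Forms (rate at elapsed time t, before averaging):

    - ``exp_linear``:    mu(t) = alpha * exp(-beta t)          (constant decay)
    - ``exp_quadratic``: mu(t) = alpha * exp(-beta t^2)
    - ``polynomial``:    mu(t) = alpha + beta t + gamma t^2
    """

    form: str
    alpha: float
    beta: float = 0.0
    gamma: float = 0.0

    _FORMS = ("exp_linear", "exp_quadratic", "polynomial")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"form must be one of {self._FORMS}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def rate(self, t):
        t = np.asarray(t, dtype=float)
        if self.form == "exp_linear":
            return self.alpha * np.exp(-self.beta * t)
        if self.form == "exp_quadratic":
            return self.alpha * np.exp(-self.beta * t**2)
        return self.alpha + self.beta * t + self.gamma * t**2


def average_rate(
    model: "AvgRateModel | DecayCurve",
    t: float,
    alpha: float | None = None,
) -> float:
    """Average rate over the cumulative window [0, t]: (1/t) * int_0^t mu(w) dw.

    The instantaneous rate mu is given either by an :class:`AvgRateModel` or
    by a :class:`DecayCurve` together with its month-1 intercept ``alpha``
    (mu(t) = alpha * exp(poly(t))). Closed forms are used where they exist:
    exponential decay gives ``alpha (1 - e^{-beta t}) / (beta t)``, and a
    polynomial rate averages to the same-degree polynomial with the j-th
    coefficient divided by j + 1. Other forms use adaptive quadrature.
    """
    if t <= 0:
        raise ValueError(f"window length t must be positive; got {t}")

    if isinstance(model, DecayCurve):
        if alpha is None:
            raise ValueError("alpha (month-1 rate) required with a DecayCurve")
        val, _ = quad(lambda w: alpha * math.exp(float(model.log_reporting(w))), 0, t)
        return val / t

    if model.form == "exp_linear":
        bt = model.beta * t
        if abs(bt) < 1e-8:
            return model.alpha * (1 - bt / 2 + bt * bt / 6)
        return model.alpha * (1 - math.exp(-bt)) / bt
    if model.form == "polynomial":
        return model.alpha + model.beta * t / 2 + model.gamma * t**2 / 3
    val, _ = quad(model.rate, 0, t)
    return val / t
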