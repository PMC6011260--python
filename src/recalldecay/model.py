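"""Poisson random-intercept models for reported-injury rates.

The rate of *reported* injuries in month ``m`` before the interview is

    lambda(x; t) = lambda0(x) * exp(b1 t + b2 t^2 + b3 t^3),   t = m - 1,

where ``lambda0(x)`` is a multiplicative (log-linear) function of categorical
risk factors describing the true injury rate in month 1, and the exponential
time term describes memory decay — interpretable as the probability that an
injury occurring t months earlier is still reported. Effect modification of
the time term (separate decay coefficients per level of a factor) separates
influences on recall from influences on true rates; a categorical month
effect serves as the nonparametric reference. Cells of the backward
person-time table are treated as independent Poisson counts with log
person-time offsets, and a household-level normal random intercept is
integrated out by Gauss-Hermite quadrature.

The public surface follows the Model/Results convention: build a
:class:`RecallDecayModel` from a person-time table and a :class:`ModelSpec`,
call :meth:`~RecallDecayModel.fit`, and read estimates off the returned
:class:`RecallDecayResults`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .cohort import PersonTimeTable
from .factors import FACTORS, FACTOR_LEVELS, check_level, ordered_levels

__all__ = [
    "ModelSpec",
    "RecallDecayModel",
    "RecallDecayResults",
    "count_parameters",
    "build_design",
    "lrt",
    "month12_model",
    "load_fit_json",
]

DEFAULT_MONTHS = frozenset(range(1, 12))
_TIME_EFFECTS = ("none", "categorical", "polynomial", "piecewise")
_TIME_NAMES = ("t", "t2", "t3")


@dataclass(frozen=True, eq=True)
class ModelSpec:
    """Declarative description of one member of the model family.

    Parameters
    ----------
    time_effect
        ``"none"``, ``"categorical"`` (dummy per month, month 1 reference),
        ``"polynomial"`` (degree 1-3 in t = month - 1), or ``"piecewise"``
        (polynomial with a per-modifier-level degree map).
    degree
        Polynomial degree for ``time_effect="polynomial"``.
    main_effects
        Factors entering lambda0(x) as dummy-coded main effects.
    time_modifier
        Factor whose levels get separate time coefficients (effect
        modification). May be absent from ``main_effects``: such
        non-hierarchical models are meaningful here because main effects are
        defined at t = 0, i.e. on true month-1 rates.
    piecewise_degrees
        For ``"piecewise"``: mapping modifier level -> polynomial degree.
    random_household
        Include a normal random intercept per household.
    months
        Months before interview entering the fit (default 1..11; month 12 is
        handled separately because of forward telescoping).
    reference_levels
        Optional overrides of the default reference category per factor.
    """

    time_effect: str = "polynomial"
    degree: int = 2
    main_effects: tuple[str, ...] = FACTORS
    time_modifier: str | None = None
    piecewise_degrees: Mapping[str, int] | None = None
    random_household: bool = True
    months: frozenset[int] = DEFAULT_MONTHS
    reference_levels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.time_effect not in _TIME_EFFECTS:
            raise ValueError(f"time_effect must be one of {_TIME_EFFECTS}")
        object.__setattr__(self, "main_effects", tuple(self.main_effects))
        object.__setattr__(self, "months", frozenset(int(m) for m in self.months))
        for f in self.main_effects:
            if f not in FACTOR_LEVELS:
                raise ValueError(f"unknown main effect {f!r}")
        if not self.months or not self.months <= set(range(1, 13)):
            raise ValueError("months must be a nonempty subset of 1..12")
        if self.time_effect == "polynomial" and not 1 <= self.degree <= 3:
            raise ValueError("polynomial degree must be in 1..3")
        if self.time_modifier is not None:
            if self.time_modifier not in FACTOR_LEVELS:
                raise ValueError(f"unknown time_modifier {self.time_modifier!r}")
            if self.time_effect not in ("polynomial", "piecewise"):
                raise ValueError("time_modifier requires a polynomial time effect")
        if self.time_effect == "piecewise":
            if self.time_modifier is None or self.piecewise_degrees is None:
                raise ValueError(
                    "piecewise time effect requires time_modifier and piecewise_degrees"
                )
            levels = set(FACTOR_LEVELS[self.time_modifier])
            got = set(self.piecewise_degrees)
            if got != levels:
                raise ValueError(
                    f"piecewise_degrees must cover levels {sorted(levels)}; got {sorted(got)}"
                )
            if any(not 1 <= d <= 3 for d in self.piecewise_degrees.values()):
                raise ValueError("piecewise degrees must be in 1..3")
        if self.reference_levels:
            for f, lev in self.reference_levels.items():
                check_level(f, lev)

    def reference(self, factor: str) -> str:
        if self.reference_levels and factor in self.reference_levels:
            return self.reference_levels[factor]
        return FACTOR_LEVELS[factor][0]

    @property
    def label(self) -> str:
        names = {1: "log-linear", 2: "log-quadratic", 3: "log-cubic"}
        if self.time_effect == "none":
            base = "no time effect"
        elif self.time_effect == "categorical":
            base = "categorical month"
        elif self.time_effect == "polynomial":
            base = names[self.degree]
        else:
            degs = ",".join(
                f"{l}:{d}" for l, d in sorted(self.piecewise_degrees.items())
            )
            base = f"piecewise({degs})"
        if self.time_modifier and self.time_effect != "piecewise":
            base += f" x {self.time_modifier}"
        elif self.time_effect == "piecewise":
            base += f" by {self.time_modifier}"
        return base

    def to_dict(self) -> dict:
        d = {
            "time_effect": self.time_effect,
            "degree": self.degree,
            "main_effects": list(self.main_effects),
            "time_modifier": self.time_modifier,
            "piecewise_degrees": dict(self.piecewise_degrees)
            if self.piecewise_degrees
            else None,
            "random_household": self.random_household,
            "months": sorted(self.months),
            "reference_levels": dict(self.reference_levels)
            if self.reference_levels
            else None,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        d = dict(d)
        if "months" in d and d["months"] is not None:
            d["months"] = frozenset(d["months"])
        if "main_effects" in d and d["main_effects"] is not None:
            d["main_effects"] = tuple(d["main_effects"])
        return cls(**{k: v for k, v in d.items() if v is not None or k in
                      ("time_modifier", "piecewise_degrees", "reference_levels")})


def _modifier_time_terms(spec: ModelSpec) -> list[tuple[str, int]]:
    """(level, power) pairs for modified time effects, all levels included."""
    terms: list[tuple[str, int]] = []
    for level in ordered_levels(spec.time_modifier, spec.reference(spec.time_modifier)):
        if spec.time_effect == "piecewise":
            deg = spec.piecewise_degrees[level]
        else:
            deg = spec.degree
        terms.extend((level, j) for j in range(1, deg + 1))
    return terms


def count_parameters(spec: ModelSpec) -> int:
    """Number of model parameters: fixed coefficients plus the random variance.

    Intercept, (levels - 1) dummy contrasts per main effect, the time-effect
    parameters (categorical: one per non-reference month; polynomial: the
    degree, per modifier level when modified; piecewise: the per-level degree
    sum), and one variance parameter when a household random intercept is
    included.
    """
    p = 1
    for f in spec.main_effects:
        p += len(FACTOR_LEVELS[f]) - 1
    if spec.time_effect == "categorical":
        p += len(spec.months) - 1
    elif spec.time_effect == "polynomial":
        if spec.time_modifier is None:
            p += spec.degree
        else:
            p += spec.degree * len(FACTOR_LEVELS[spec.time_modifier])
    elif spec.time_effect == "piecewise":
        p += sum(spec.piecewise_degrees.values())
    if spec.random_household:
        p += 1
    return p


def design_matrix(spec: ModelSpec, frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix for rows carrying factor columns and ``month``.

    Time covariates use t = month - 1. Modified time effects are
    parameterized as one full time curve per modifier level (dummy x t^j for
    every level), so non-hierarchical specs and per-level piecewise degrees
    are directly expressible; predicted rates are invariant to the
    (re)parameterization choice.
    """
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    for f in spec.main_effects:
        levels = ordered_levels(f, spec.reference(f))
        vals = frame[f].to_numpy()
        for level in levels[1:]:
            cols.append((vals == level).astype(float))
            names.append(f"{f}[{level}]")

    month = frame["month"].to_numpy(dtype=float)
    t = month - 1.0
    if spec.time_effect == "categorical":
        ref_month = min(spec.months)
        for m in sorted(spec.months):
            if m == ref_month:
                continue
            cols.append((month == m).astype(float))
            names.append(f"month[{m}]")
    elif spec.time_effect == "polynomial" and spec.time_modifier is None:
        for j in range(1, spec.degree + 1):
            cols.append(t**j)
            names.append(_TIME_NAMES[j - 1])
    elif spec.time_effect in ("polynomial", "piecewise") and spec.time_modifier:
        mod = frame[spec.time_modifier].to_numpy()
        for level, j in _modifier_time_terms(spec):
            cols.append((mod == level).astype(float) * t**j)
            names.append(f"{_TIME_NAMES[j - 1]}:{spec.time_modifier}[{level}]")

    return np.column_stack(cols), names


@dataclass
class Design:
    """Likelihood-ready arrays for one spec on one person-time table."""

    X: np.ndarray
    y: np.ndarray
    exposure: np.ndarray
    offset: np.ndarray
    names: list[str]
    household: np.ndarray | None  # integer codes, rows sorted by household
    frame: pd.DataFrame  # the (possibly aggregated) rows behind X

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


def build_design(spec: ModelSpec, table: PersonTimeTable) -> Design:
    """Assemble the design for fitting *spec* to *table*.

    Rows outside ``spec.months`` or with zero exposure are excluded. The cell
    granularity (stratum x household x month) is kept as-is whether or not a
    random intercept is present, so the sigma^2 = 0 marginal likelihood
    coincides exactly with the fixed-effect Poisson likelihood.
    """
    df = table.data
    df = df[df["month"].isin(spec.months) & (df["person_years"] > 0)].copy()
    if df.empty:
        raise ValueError("person-time table has no usable cells for this spec")

    if spec.random_household:
        df = df.sort_values("household_id", kind="stable").reset_index(drop=True)
        household = pd.factorize(df["household_id"])[0]
    else:
        df = df.reset_index(drop=True)
        household = None

    X, names = design_matrix(spec, df)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in np.nonzero(np.abs(np.diag(r)) < 1e-8)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    y = df["events"].to_numpy(dtype=float)
    exposure = df["person_years"].to_numpy(dtype=float)
    return Design(
        X=X,
        y=y,
        exposure=exposure,
        offset=np.log(exposure),
        names=names,
        household=household,
        frame=df,
    )


class RecallDecayModel:
    """Poisson (random-intercept) regression of reported-injury counts.

    Parameters
    ----------
    table
        Backward person-time table from :func:`~recalldecay.cohort.build_person_time`.
    spec
        Model specification.
    quad_nodes
        Number of Gauss-Hermite nodes used to integrate the household random
        intercept out of the likelihood (ignored without a random effect).
    """

    def __init__(self, table: PersonTimeTable, spec: ModelSpec, quad_nodes: int = 20):
        self.spec = spec
        self.quad_nodes = int(quad_nodes)
        self.design = build_design(spec, table)
        d = self.design
        if spec.random_household:
            z, w = hermgauss(self.quad_nodes)
            self._gh_z = z
            self._gh_logw = np.log(w) - 0.5 * math.log(math.pi)
            # household boundaries for per-household sums (rows pre-sorted)
            h = d.household
            self._h_starts = np.r_[0, np.nonzero(np.diff(h))[0] + 1]
            self._n_households = len(self._h_starts)
            self._h_index = h

    # -- likelihood ------------------------------------------------------

    @property
    def n_params(self) -> int:
        return self.design.n_fixed + (1 if self.spec.random_household else 0)

    def _split(self, params: np.ndarray) -> tuple[np.ndarray, float]:
        params = np.asarray(params, dtype=float)
        if len(params) != self.n_params:
            raise ValueError(
                f"expected {self.n_params} parameters, got {len(params)}"
            )
        if self.spec.random_household:
            return params[:-1], float(params[-1])
        return params, 0.0

    def _eta(self, beta: np.ndarray) -> np.ndarray:
        eta = self.design.X @ beta + self.design.offset
        if not np.all(np.isfinite(eta)):
            i = int(np.nonzero(~np.isfinite(eta))[0][0])
            cell = self.design.frame.iloc[i].to_dict()
            raise ValueError(f"non-finite linear predictor at cell {cell}")
        return eta

    def loglike(self, params: Sequence[float]) -> float:
        """Marginal log-likelihood at ``params`` (= [beta, sigma] if random).

        The random intercept u ~ N(0, sigma^2) is integrated out per
        household by Gauss-Hermite quadrature; at sigma = 0 (or without a
        random effect) this reduces exactly to the independent Poisson
        log-likelihood.
        """
        return self._loglike_score(np.asarray(params, float), want_score=False)[0]

    def score(self, params: Sequence[float]) -> np.ndarray:
        return self._loglike_score(np.asarray(params, float), want_score=True)[1]

    def _loglike_score(self, params, want_score):
        beta, sigma = self._split(params)
        d = self.design
        y, off = d.y, d.offset
        const = float(gammaln(y + 1).sum())
        if not self.spec.random_household:
            eta = self._eta(beta)
            mu = np.exp(np.minimum(eta, 60.0))
            ll = float(y @ eta - mu.sum()) - const
            if not want_score:
                return ll, None
            return ll, d.X.T @ (y - mu)

        eta = self._eta(beta)
        shifts = math.sqrt(2.0) * sigma * self._gh_z  # (K,)
        lin = eta[None, :] + shifts[:, None]  # (K, n)
        lin = np.minimum(lin, 60.0)
        cell_ll = y[None, :] * lin - np.exp(lin)
        A = np.add.reduceat(cell_ll, self._h_starts, axis=1)  # (K, H)
        logS = logsumexp(self._gh_logw[:, None] + A, axis=0)  # (H,)
        ll = float(logS.sum()) - const
        if not want_score:
            return ll, None
        P = np.exp(self._gh_logw[:, None] + A - logS[None, :])  # (K, H)
        P_cells = P[:, self._h_index]  # (K, n)
        R = y[None, :] - np.exp(lin)
        wcell = (P_cells * R).sum(axis=0)
        g_beta = d.X.T @ wcell
        g_sigma = math.sqrt(2.0) * float((self._gh_z[:, None] * P_cells * R).sum())
        return ll, np.r_[g_beta, g_sigma]

    # -- fitting ---------------------------------------------------------

    def _irls(self, maxiter: int = 100, tol: float = 1e-10):
        """Newton/Fisher-scoring fit of the fixed-effect Poisson GLM."""
        d = self.design
        X, y, off = d.X, d.y, d.offset
        beta = np.zeros(d.n_fixed)
        beta[0] = math.log(max(y.sum(), 0.5) / d.exposure.sum())
        converged = False
        for _ in range(maxiter):
            eta = X @ beta + off
            mu = np.exp(np.minimum(eta, 60.0))
            score = X.T @ (y - mu)
            info = X.T @ (X * mu[:, None])
            try:
                delta = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                break
            # damp wild steps far from the optimum
            step = min(1.0, 5.0 / max(np.abs(delta).max(), 1e-12))
            beta = beta + step * delta
            if np.abs(delta).max() < tol:
                converged = True
                break
        return beta, converged

    def fit(self, start_params: Sequence[float] | None = None,
            maxiter: int = 500) -> "RecallDecayResults":
        """Maximum-likelihood fit.

        Fixed-effect-only specs use Newton scoring; random-intercept specs
        start from the GLM solution with sigma^2 = 0.1 and maximize the
        quadrature likelihood by L-BFGS-B with an analytic gradient and the
        boundary sigma = 0 permitted. Deterministic given the (fixed default)
        starting values. Standard errors come from the observed information
        matrix at the optimum.
        """
        d = self.design
        all_zero = d.y.sum() == 0

        if not self.spec.random_household:
            if start_params is not None:
                beta = np.asarray(start_params, dtype=float)
                res = minimize(
                    lambda p: -self.loglike(p), beta,
                    jac=lambda p: -self.score(p), method="BFGS",
                    options={"gtol": 1e-10, "maxiter": maxiter},
                )
                beta, conv = res.x, bool(res.success)
            else:
                beta, conv = self._irls()
            params = beta
            sigma = 0.0
            converged = conv and not all_zero
        else:
            beta0, _ = self._irls()
            x0 = np.r_[beta0, math.sqrt(0.1)] if start_params is None else np.asarray(
                start_params, float
            )
            bounds = [(None, None)] * d.n_fixed + [(0.0, None)]
            res = minimize(
                lambda p: -self._loglike_score(p, True)[0],
                x0,
                jac=lambda p: -self._loglike_score(p, True)[1],
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
            )
            params = res.x
            sigma = float(params[-1])
            converged = bool(res.success) and not all_zero

        llf = self.loglike(params) if not all_zero else -math.inf
        cov = self._cov_params(params) if not all_zero else np.full(
            (self.n_params, self.n_params), np.nan
        )
        if all_zero:
            warnings.warn("all-zero event table: rate intercept diverges; "
                          "fit flagged as non-converged", stacklevel=2)
        names = list(d.names) + (["sigma"] if self.spec.random_household else [])
        return RecallDecayResults(
            model=self,
            params=np.asarray(params, dtype=float),
            names=names,
            cov_params_arr=cov,
            llf=llf,
            converged=converged,
        )

    def _cov_params(self, params: np.ndarray) -> np.ndarray:
        """Inverse observed information via central differences of the score."""
        params = np.asarray(params, dtype=float)
        k = len(params)
        at_boundary = self.spec.random_household and params[-1] < 1e-5
        free = k - 1 if at_boundary else k
        H = np.zeros((free, free))
        for j in range(free):
            h = 1e-5 * (1.0 + abs(params[j]))
            up, dn = params.copy(), params.copy()
            up[j] += h
            dn[j] -= h
            H[:, j] = (self.score(up)[:free] - self.score(dn)[:free]) / (2 * h)
        H = (H + H.T) / 2.0
        cov = np.full((k, k), np.nan)
        try:
            cov[:free, :free] = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov[:free, :free] = np.linalg.pinv(-H)
        return cov


class RecallDecayResults:
    """Fitted-model results: estimates, uncertainties, and derived summaries."""

    def __init__(self, model, params, names, cov_params_arr, llf, converged):
        self.model = model
        self.spec: ModelSpec = model.spec
        self.names = names
        self.params = pd.Series(params, index=names)
        self.cov_params = pd.DataFrame(cov_params_arr, index=names, columns=names)
        self.llf = float(llf)
        self.converged = bool(converged)

    # -- basic quantities ------------------------------------------------

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.names)

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def aic(self) -> float:
        """Akaike information criterion, 2 * n_params - 2 * loglik."""
        return 2.0 * self.n_params - 2.0 * self.llf

    @property
    def sigma2(self) -> float:
        """Estimated household random-intercept variance (0 without one)."""
        if not self.spec.random_household:
            return 0.0
        return float(self.params["sigma"] ** 2)

    @property
    def fixed_params(self) -> pd.Series:
        return self.params.drop("sigma") if self.spec.random_household else self.params

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    # -- prediction ------------------------------------------------------

    def predict_rate(self, frame: pd.DataFrame) -> np.ndarray:
        """Predicted rates (events per person-year) for covariate/month rows.

        ``frame`` carries the factor columns the spec uses plus ``month``.
        Month 1 (t = 0) gives lambda0(x), the decay-free true-rate scale.
        The household random effect is not included (population-level,
        u = 0 prediction).
        """
        X, names = design_matrix(self.spec, frame)
        if names != [n for n in self.names if n != "sigma"]:
            raise ValueError("prediction frame is inconsistent with the fitted spec")
        return np.exp(X @ self.fixed_params.to_numpy())

    def rate_ratio_for(self, name: str, alpha: float = 0.05):
        """exp(coefficient) for one design column, with a Wald CI."""
        from scipy.stats import norm

        if name not in self.names:
            raise ValueError(f"no coefficient {name!r} in this fit")
        z = norm.ppf(1 - alpha / 2)
        b, se = float(self.params[name]), float(self.bse[name])
        return math.exp(b), math.exp(b - z * se), math.exp(b + z * se)

    def decay_curves(self) -> dict:
        """Fitted decay curve(s) keyed by modifier level ('all' if unmodified)."""
        from .decay import DecayCurve

        if self.spec.time_effect == "polynomial" and self.spec.time_modifier is None:
            coeffs = [
                float(self.params[_TIME_NAMES[j - 1]])
                for j in range(1, self.spec.degree + 1)
            ]
            return {"all": DecayCurve(tuple(coeffs))}
        if self.spec.time_effect in ("polynomial", "piecewise") and self.spec.time_modifier:
            out = {}
            for level in FACTOR_LEVELS[self.spec.time_modifier]:
                coeffs = []
                for j in range(1, 4):
                    name = f"{_TIME_NAMES[j - 1]}:{self.spec.time_modifier}[{level}]"
                    if name in self.names:
                        coeffs.append(float(self.params[name]))
                out[level] = DecayCurve(tuple(coeffs))
            return out
        raise ValueError("no polynomial decay terms in this spec")

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        rows = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.params / self.bse,
            }
        )
        lines = [
            "Poisson recall-decay model",
            f"  spec:        {self.spec.label}",
            f"  months:      {sorted(self.spec.months)}",
            f"  n cells:     {len(self.model.design.y)}",
            f"  n params:    {self.n_params}",
            f"  loglik:      {self.llf:.4f}",
            f"  AIC:         {self.aic:.4f}",
            f"  sigma^2:     {self.sigma2:.4f}",
            f"  converged:   {self.converged}",
            "",
            rows.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> dict:
        obj = {
            "coefficients": {n: float(v) for n, v in self.fixed_params.items()},
            "std_errors": {
                n: float(self.bse[n]) for n in self.fixed_params.index
            },
            "random_variance": self.sigma2,
            "loglik": self.llf,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "spec": self.spec.to_dict(),
            "settings": {"quad_nodes": self.model.quad_nodes},
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2)
        return obj


def load_fit_json(path) -> dict:
    """Load a serialized fit; returns the dict written by ``to_json``."""
    with open(path) as fh:
        obj = json.load(fh)
    obj["spec"] = ModelSpec.from_dict(obj["spec"])
    return obj


def lrt(nested: RecallDecayResults, full: RecallDecayResults) -> tuple[float, int]:
    """Likelihood-ratio test of a nested against a fuller model.

    Returns ``(chi_square, df)`` with chi^2 = 2 (l_full - l_nested) and df
    the parameter-count difference. Requires the same months and table and
    that the nested fixed-effect design lies in the column span of the full
    one (so e.g. polynomial specs are recognized as nested in the categorical
    spec). A slightly negative chi^2 from optimizer noise is clamped to 0
    with a warning.
    """
    if nested.spec.months != full.spec.months:
        raise ValueError("models were fitted on different month windows")
    if nested.n_params > full.n_params:
        raise ValueError("nested model must not have more parameters")
    dn, df_ = nested.model.design, full.model.design
    if len(dn.y) != len(df_.y) or not np.allclose(dn.y, df_.y) or not np.allclose(
        dn.exposure, df_.exposure
    ):
        raise ValueError("models were fitted to different tables")
    proj, *_ = np.linalg.lstsq(df_.X, dn.X, rcond=None)
    resid = dn.X - df_.X @ proj
    if np.abs(resid).max() > 1e-6 * max(1.0, np.abs(dn.X).max()):
        raise ValueError("models are not nested (designs are not spanned)")
    chi2 = 2.0 * (full.llf - nested.llf)
    if chi2 < 0:
        warnings.warn(
            f"negative LRT statistic {chi2:.3g} clamped to 0 (optimizer noise)",
            stacklevel=2,
        )
        chi2 = 0.0
    df = full.n_params - nested.n_params
    return chi2, df


def month12_model(
    table: PersonTimeTable,
    main_effects: tuple[str, ...] = FACTORS,
    random_household: bool = True,
    quad_nodes: int = 20,
) -> RecallDecayResults:
    """Categorical comparison of reported rates in month 12 vs month 1.

    Fits a two-level month effect (month 1 reference) with the usual main
    effects on the table restricted to months {1, 12}. The month-12:month-1
    rate ratio and its 95% CI are available as
    ``results.rate_ratio_for("month[12]")``.
    """
    spec = ModelSpec(
        time_effect="categorical",
        main_effects=main_effects,
        random_household=random_household,
        months=frozenset({1, 12}),
    )
    return RecallDecayModel(table.restrict({1, 12}), spec, quad_nodes=quad_nodes).fit()
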