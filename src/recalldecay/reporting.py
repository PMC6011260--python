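"""Model-comparison tables and decay summaries in publication layout."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import PersonTimeTable
from .decay import DecayCurve, half_recall_time, reporting_probability
from .model import ModelSpec, RecallDecayModel, RecallDecayResults, lrt

logger = logging.getLogger(__name__)


def decay_summary(curves: Mapping[str, DecayCurve]) -> pd.DataFrame:
    """Derived decay columns per group: reporting probabilities in months 6
    and 11 and the half-recall time (months on the t scale, anchored at the
    middle of month 1)."""
    rows = []
    for group, curve in curves.items():
        half = half_recall_time(curve)
        rows.append(
            {
                "group": group,
                "coefficients": tuple(round(c, 6) for c in curve.coeffs),
                "prob_month6": reporting_probability(curve, 6),
                "prob_month11": reporting_probability(curve, 11),
                "half_recall_months": np.nan if half is None else half,
            }
        )
    return pd.DataFrame(rows)


def run_model_comparison(
    table: PersonTimeTable,
    specs: Sequence[ModelSpec],
    labels: Sequence[str] | None = None,
    background: int | None = None,
    quad_nodes: int = 20,
) -> pd.DataFrame:
    """Fit each spec and tabulate parameter counts, AIC, and LRTs.

    ``background`` indexes the spec every other (nested) model is tested
    against by likelihood ratio — conventionally the categorical-month model.
    Non-converged or non-nested fits get flagged rows; the run continues.
    The AIC-minimal converged model is marked.
    """
    labels = list(labels) if labels is not None else [s.label for s in specs]
    fits: list[RecallDecayResults] = []
    for spec, label in zip(specs, labels):
        res = RecallDecayModel(table, spec, quad_nodes=quad_nodes).fit()
        if not res.converged:
            logger.warning("fit %r did not converge", label)
        fits.append(res)

    bg = fits[background] if background is not None else None
    rows = []
    for label, res in zip(labels, fits):
        chi2 = df = np.nan
        if bg is not None and res is not bg and res.converged and bg.converged:
            try:
                chi2, df = lrt(res, bg)
            except ValueError:
                pass
        rows.append(
            {
                "model": label,
                "n_params": res.n_params,
                "loglik": res.llf,
                "aic": res.aic,
                "lrt_chi2": chi2,
                "lrt_df": df,
                "sigma2": res.sigma2,
                "converged": res.converged,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["converged"]
    out["aic_best"] = False
    if ok.any():
        out.loc[out.loc[ok, "aic"].idxmin(), "aic_best"] = True
    return out
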