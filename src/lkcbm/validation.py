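"""Comparison of model predictions with growth experiments.

Covers specific-growth-rate estimation from OD600 time courses, running a
table of experimental conditions (substrate/O2 uptakes) through FBA, and
correlating predicted against measured growth rates and respiratory
quotients.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fba import fba, respiratory_quotient
from .model import DEFAULT_BOUND, Medium, MetabolicModel

__all__ = ["estimate_growth_rate", "run_condition_table", "correlate"]


def estimate_growth_rate(
    series: pd.DataFrame,
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Specific growth rate from an OD600 time course.

    mu = ln(OD(t_final)/OD(t_initial)) / (t_final - t_initial), positive
    for growth, assuming exponential phase over the window (defaults to
    the full series).  ``series`` needs columns ``t`` (h, strictly
    increasing) and ``od`` (> 0).
    """
    t = np.asarray(series["t"], dtype=float)
    od = np.asarray(series["od"], dtype=float)
    if np.any(od <= 0):
        raise ValueError("OD must be positive everywhere")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if window is None:
        ti, tf = t[0], t[-1]
    else:
        ti, tf = window
    if tf <= ti:
        raise ValueError("window end must be after window start")

    def od_at(tq):
        idx = np.nonzero(np.isclose(t, tq))[0]
        if idx.size == 0:
            raise ValueError(f"time point {tq} not in series")
        return od[idx[0]]

    return math.log(od_at(tf) / od_at(ti)) / (tf - ti)


def run_condition_table(
    model: MetabolicModel,
    table: pd.DataFrame,
    o2_exchange: str = "EX_o2_e",
    co2_exchange: str = "EX_co2_e",
    base_medium: Optional[Medium] = None,
) -> pd.DataFrame:
    """FBA predictions (mu, RQ) for each experimental condition row.

    ``table`` columns: condition, substrate_exchange, substrate_uptake,
    o2_uptake (mmol/gDW/h) and optionally measured_mu / measured_rq.
    Infeasible rows are marked, never abort the table.
    """
    base = base_medium or Medium("base")
    rows = []
    for _, cond in table.iterrows():
        out = dict(cond)
        out.update({"predicted_mu": np.nan, "predicted_rq": np.nan, "status": ""})
        limits = dict(base.uptake_limits)
        try:
            limits[cond["substrate_exchange"]] = float(cond["substrate_uptake"])
            limits[o2_exchange] = float(cond["o2_uptake"])
            medium = Medium(str(cond["condition"]), limits, set(base.unrestricted))
            sol = fba(model, medium)
        except Exception as e:  # per-row errors recorded, table continues
            out["status"] = f"error: {e}"
            rows.append(out)
            continue
        out["status"] = sol.status
        if sol.optimal:
            out["predicted_mu"] = sol.objective_value
            try:
                out["predicted_rq"] = respiratory_quotient(sol, co2_exchange, o2_exchange)
            except ValueError:
                pass
        rows.append(out)
    return pd.DataFrame(rows)


def correlate(predicted: Sequence[float], measured: Sequence[float]) -> Tuple[float, float]:
    """Pearson r and one-sided p-value for positive association.

    The p-value comes from the t-distribution with n - 2 degrees of
    freedom under H1 "positively correlated".  Requires n >= 3, finite
    values and non-zero variance in both vectors.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)
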