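"""Relative growth rates from destructive weight time series.

Seedling roots are weighed destructively, so growth is measured on
independent replicate plants per day.  The relative growth rate at a time
point is the weight gained since treatment onset expressed as a fraction
of the final harvest weight per hour:

    RGR_t = dW_t / (W_f · dt),  dW_t = W_t − W_0,  W_0 = 0,  dt = t − t_0

With the initial root mass taken as zero, dW_t is simply the measurement
at time t.  The physiological normalizer used for synthesis rates is the
unweighted mean of RGR_t across the daily time points inside the labelling
window (t_0 excluded — dt = 0 there).  This is a fraction-of-final-weight
rate, not a log-slope: the exponential/log-linear RGR model is deliberately
not used because weight accumulation in germinating roots is far from
log-linear (r² < 0.5 on every measured variable).

Because weighing is destructive, W_f is the mean over final-day replicates
per condition; per-replicate pairing across days is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import AnovaTukeyResult, anova_tukey  # re-exported shared utility

__all__ = ["RGRResult", "rgr", "rgr_table", "read_weights", "anova_tukey",
           "AnovaTukeyResult"]


@dataclass
class RGRResult:
    """Per-time-point RGR series and its labelling-window average."""

    condition: str
    variable: str
    per_time: pd.DataFrame  # time_h, rgr, n_replicates
    average: float  # mean RGR over window time points (h^-1)
    w_final: float
    flags: list


def read_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "replicate", "time_h", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight table is missing column(s): {sorted(missing)}")
    return df


def rgr(
    series: pd.DataFrame,
    window: tuple[float, float] | None = None,
    t0: float = 0.0,
) -> RGRResult:
    """RGR series for one condition × variable block of the weight table.

    ``series`` needs columns replicate, time_h, value.  Replicates are
    averaged within each time point first, then RGR_t is averaged across
    the time points inside ``window`` (default: everything after t0 up to
    the final time).
    """
    cond = str(series["condition"].iloc[0]) if "condition" in series else ""
    var = str(series["variable"].iloc[0]) if "variable" in series else ""
    flags: list[str] = []
    times = np.sort(series["time_h"].unique())
    if len(times) == 0:
        raise ValueError("empty growth series")
    t_f = times[-1]
    w_f = float(series.loc[series["time_h"] == t_f, "value"].mean())
    if w_f <= 0:
        raise ValueError("final weight W_f must be positive")
    lo, hi = window if window is not None else (t0, t_f)

    rows = []
    prev_w = 0.0
    for t in times:
        dt = t - t0
        if dt <= 0:
            continue  # RGR undefined at dt = 0
        vals = series.loc[series["time_h"] == t, "value"]
        w_t = float(vals.mean())  # replicate-first averaging
        if w_t < 0:
            raise ValueError("negative weight measurement")
        if w_t < prev_w:  # shrinkage between sampling days: allowed but flagged
            flags.append(f"shrinkage_at_{t:g}h")
        prev_w = w_t
        dw = w_t - 0.0  # W_0 = 0 by assumption
        rows.append({"time_h": t, "rgr": dw / (w_f * dt), "n_replicates": len(vals)})
    per_time = pd.DataFrame(rows)
    in_window = per_time[(per_time["time_h"] >= max(lo, t0 + 1e-12))
                         & (per_time["time_h"] <= hi)]
    if in_window.empty:
        raise ValueError("no time points inside the averaging window")
    avg = float(in_window["rgr"].mean())
    return RGRResult(cond, var, per_time, avg, w_f, flags)


def rgr_table(
    weights: pd.DataFrame, window: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Average RGR per condition × variable (long table of the per-time series
    plus an ``average`` column repeated per block)."""
    out = []
    for (cond, var), block in weights.groupby(["condition", "variable"]):
        res = rgr(block, window=window)
        tab = res.per_time.copy()
        tab.insert(0, "condition", cond)
        tab.insert(1, "variable", var)
        tab["average"] = res.average
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def average_rgr(weights: pd.DataFrame, variable: str = "DW",
                window: tuple[float, float] | None = None) -> dict[str, float]:
    """Condition → average RGR for one growth variable."""
    sub = weights[weights["variable"] == variable]
    if sub.empty:
        raise ValueError(f"no rows for variable {variable!r}")
    return {
        str(cond): rgr(block, window=window).average
        for cond, block in sub.groupby("condition")
    }
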