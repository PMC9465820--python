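"""Growth rates and lag times from confluence time series.

Confluence (the fraction of the well bottom covered by cells) under
exponential growth is linear in log10 space; instantaneous growth rates
are OLS slopes over a moving time window (default 24 h, i.e. 16
consecutive points at 1.5-h sampling, shifted by 8 h). The lag time after
a growth stimulus is the intersection of the tangent at the
maximum-growth-rate window with the initial confluence, and can be
corrected for its dependence on initial confluence by interpolating lag
times of untreated cultures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "moving_window_rates",
    "lag_time",
    "expected_lag_interpolation",
    "LagEstimate",
]


@dataclass
class LagEstimate:
    """Tangent-method lag estimate and the window it came from."""

    lag_hours: float
    max_rate: float            # log10 confluence change per hour
    window: tuple[float, float]
    intercept: float           # log10-space intercept of the tangent
    initial_confluence: float
    censored: bool = False     # no positive-rate window: lag >= series end
    negative: bool = False     # tangent intersects before the segment start


def _check_grid(time: np.ndarray) -> float:
    diffs = np.diff(time)
    if len(diffs) == 0 or np.any(diffs <= 0):
        raise ValueError("time must be strictly increasing")
    dt = float(np.median(diffs))
    if np.any(np.abs(diffs - dt) > 1e-6):
        raise ValueError("time grid must be regular (within 1e-6 h)")
    return dt


def moving_window_rates(
    time,
    confluence,
    window_hours: float = 24.0,
    shift_hours: float = 8.0,
    plateau_threshold: float = 0.95,
) -> pd.DataFrame:
    """Log-linear growth rates over a moving time window.

    Confluence is log10-transformed and an OLS slope fitted per window of
    ``round(window_hours/dt)`` consecutive points, advanced by
    ``round(shift_hours/dt)`` points (at 1.5-h sampling: 16-point windows
    shifted by 5 points = 7.5 h); partial trailing windows are dropped.
    Windows containing non-positive confluence are skipped with a flag.

    Returns a DataFrame: ``t_start, t_end, rate, intercept, r_squared,
    mean_confluence, skipped, plateau``.
    """
    t = np.asarray(time, dtype=float)
    c = np.asarray(confluence, dtype=float)
    dt = _check_grid(t)
    n_win = max(2, int(round(window_hours / dt)))
    shift = max(1, int(round(shift_hours / dt)))
    if len(t) < n_win:
        raise ValueError("series shorter than one full window")

    rows = []
    for start in range(0, len(t) - n_win + 1, shift):
        tw = t[start : start + n_win]
        cw = c[start : start + n_win]
        row = {
            "t_start": tw[0], "t_end": tw[-1],
            "rate": np.nan, "intercept": np.nan, "r_squared": np.nan,
            "mean_confluence": float(np.mean(cw)),
            "skipped": False,
            "plateau": bool(np.mean(cw) > plateau_threshold),
        }
        if np.any(cw <= 0):
            row["skipped"] = True
        else:
            fit = stats.linregress(tw, np.log10(cw))
            row.update(
                rate=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=float(fit.rvalue**2) if np.isfinite(fit.rvalue) else np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def lag_time(
    time,
    confluence,
    rates: pd.DataFrame | None = None,
    initial_confluence: float | None = None,
    **rate_kwargs,
) -> LagEstimate:
    """Lag time by tangent intersection with the initial confluence.

    Using slope ``b`` and intercept ``a`` of the log10-space fit in the
    maximum-rate window (plateau and skipped windows excluded),
    ``lag = (log10(c_init) - a) / b`` where ``c_init`` is the first
    observation of the segment unless given explicitly. If no window has
    a positive rate the culture never resumed growth and the lag is
    censored at the series end.
    """
    t = np.asarray(time, dtype=float)
    c = np.asarray(confluence, dtype=float)
    if rates is None:
        rates = moving_window_rates(t, c, **rate_kwargs)
    c_init = float(c[0]) if initial_confluence is None else float(initial_confluence)
    if c_init <= 0:
        raise ValueError("initial confluence must be > 0")

    usable = rates[~rates["skipped"] & ~rates["plateau"] & np.isfinite(rates["rate"])]
    if len(usable) == 0 or usable["rate"].max() <= 0:
        return LagEstimate(
            lag_hours=float(t[-1]), max_rate=float(usable["rate"].max()) if len(usable) else np.nan,
            window=(np.nan, np.nan), intercept=np.nan,
            initial_confluence=c_init, censored=True,
        )
    best = usable.loc[usable["rate"].idxmax()]
    lag = (np.log10(c_init) - best["intercept"]) / best["rate"]
    return LagEstimate(
        lag_hours=float(lag),
        max_rate=float(best["rate"]),
        window=(float(best["t_start"]), float(best["t_end"])),
        intercept=float(best["intercept"]),
        initial_confluence=c_init,
        negative=bool(lag < 0),
    )


def expected_lag_interpolation(
    reference: pd.DataFrame,
    query_initial_confluence: float,
) -> tuple[float, bool]:
    """Expected lag at a given initial confluence, from untreated curves.

    ``reference`` holds ``initial_confluence`` and ``lag_hours`` pairs
    measured in untreated cultures; the expected lag is their piecewise
    linear interpolation at the query confluence. Queries outside the
    reference range are extrapolated along the nearest segment and
    flagged. The excess lag of a treated culture is then
    ``observed - expected``.

    Returns ``(expected_lag_hours, extrapolated)``.
    """
    if len(reference) < 2:
        raise ValueError("need >= 2 reference (confluence, lag) pairs")
    ref = reference.sort_values("initial_confluence")
    x = ref["initial_confluence"].to_numpy(dtype=float)
    y = ref["lag_hours"].to_numpy(dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("reference initial confluences must be distinct")
    q = float(query_initial_confluence)
    if x[0] <= q <= x[-1]:
        return float(np.interp(q, x, y)), False
    if q < x[0]:  # extend the first segment
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return float(y[0] + slope * (q - x[0])), True
    slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
    return float(y[-1] + slope * (q - x[-1])), True
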