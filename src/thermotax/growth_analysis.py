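"""Growth-curve metrics from OD600 time series.

Two delay statistics are in circulation for plate-reader growth data and
they are not equivalent; both are provided and neither is privileged
beyond the stated default:

* ``growth_delay_halfmax`` — time from inoculation until the culture
  reaches half its maximal OD600 (the default "growth delay").
* ``time_to_max_rate`` — time until the maximal specific growth rate is
  reached.

The specific growth rate is the slope of ln(OD) versus time, estimated by
a least-squares fit in a sliding window (default 5 points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthMetrics",
    "UndefinedMetricError",
    "max_growth_rate",
    "time_to_max_rate",
    "growth_delay_halfmax",
    "compute_growth_metrics",
    "read_growth_table",
]

OD_FLOOR = 1e-4  # applied before taking logs; blank subtraction is the caller's job


class UndefinedMetricError(RuntimeError):
    """The requested growth metric is undefined for this curve."""


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series: hours since inoculation and blanked readings."""

    t: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if self.t.shape != self.od.shape or self.t.ndim != 1:
            raise ValueError("t and od must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("a growth curve needs at least 2 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class GrowthMetrics:
    mu_max: float          # maximal specific growth rate (1/h)
    t_mu_max: float        # time of maximal growth rate (h)
    delay_halfmax: float   # time to half-maximal OD (h); NaN if undefined


def _window_slopes(t: np.ndarray, y: np.ndarray, window: int):
    """Least-squares slope of y vs t in every contiguous window."""
    n = len(t) - window + 1
    slopes = np.empty(n)
    for i in range(n):
        tw = t[i : i + window]
        yw = y[i : i + window]
        tc = tw - tw.mean()
        slopes[i] = float(tc @ (yw - yw.mean()) / (tc @ tc))
    centers = t[window // 2 : window // 2 + n]
    return slopes, centers


def max_growth_rate(curve: GrowthCurve, window: int = 5) -> tuple[float, float]:
    """Maximal specific growth rate and the time it is attained.

    Fits ln(OD) vs t by least squares in every contiguous ``window``-point
    stretch and returns the largest slope with its window-center time.
    Ties (e.g. a pure exponential) resolve to the earliest window.
    """
    if window < 2:
        raise ValueError("window must be >= 2 points")
    if len(curve.t) < window:
        raise ValueError(f"need at least {window} points")
    if np.any(~np.isfinite(curve.od)):
        raise ValueError("OD contains non-finite values")
    y = np.log(np.maximum(curve.od, OD_FLOOR))
    slopes, centers = _window_slopes(curve.t, y, window)
    best = float(np.max(slopes))
    # earliest window within a small tolerance of the maximum
    idx = int(np.argmax(slopes >= best - 1e-9 * max(1.0, abs(best))))
    return slopes[idx], float(centers[idx])


def time_to_max_rate(curve: GrowthCurve, window: int = 5) -> float:
    """Delay measured as the time until the maximal growth rate."""
    return max_growth_rate(curve, window)[1]


def growth_delay_halfmax(curve: GrowthCurve) -> float:
    """Time from inoculation (t = 0 of the series) to half-maximal OD600.

    The crossing is located by interpolating ln(OD) linearly between the
    bracketing samples.  Raises :class:`UndefinedMetricError` if the curve
    never reaches half its maximum before the final point.
    """
    od = np.maximum(curve.od, OD_FLOOR)
    target = float(np.max(od)) / 2.0
    if od[0] >= target:
        return float(curve.t[0])
    above = np.flatnonzero(od >= target)
    if len(above) == 0:
        raise UndefinedMetricError("OD never reaches half its maximum")
    i = int(above[0])
    if od[i] == target:
        return float(curve.t[i])
    ln_lo, ln_hi = np.log(od[i - 1]), np.log(od[i])
    frac = (np.log(target) - ln_lo) / (ln_hi - ln_lo)
    return float(curve.t[i - 1] + frac * (curve.t[i] - curve.t[i - 1]))


def compute_growth_metrics(curve: GrowthCurve, window: int = 5) -> GrowthMetrics:
    """All metrics at once; delay_halfmax is NaN when undefined."""
    mu, t_mu = max_growth_rate(curve, window)
    try:
        delay = growth_delay_halfmax(curve)
    except UndefinedMetricError:
        delay = float("nan")
    return GrowthMetrics(mu_max=mu, t_mu_max=t_mu, delay_halfmax=delay)


def read_growth_table(path) -> dict[str, GrowthCurve]:
    """Read growth curves from CSV.

    Long format needs columns ``time_h, od600`` (one well); wide plate
    format needs ``time_h`` plus one column per well (A1...H12).  Returns a
    mapping from well name (``od600`` for long format) to curve.
    """
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError("growth CSV must have a time_h column")
    t = df["time_h"].to_numpy(float)
    wells = [c for c in df.columns if c != "time_h"]
    if not wells:
        raise ValueError("growth CSV has no OD columns")
    return {w: GrowthCurve(t, df[w].to_numpy(float)) for w in wells}
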