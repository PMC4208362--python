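"""Front-displacement time series: containers, averaging, and the E metric.

The common currency of experiment and simulation is the net leading-edge
displacement Y(t) - Y(0) in µm at a handful of observation times.  Averaged
simulation data is the pointwise mean over M identically prepared
realizations.  Discrepancy between an experimental series Y^i and an
averaged series <Y^i> is scored by the normalized L1 metric

    E = (1 / (N * Y_max)) * sum_i |<Y^i> - Y^i|

over the N selected post-initial time indices, Y_max being the largest
experimental value among them; E is dimensionless, zero iff the series
agree on the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FrontSeries",
    "AveragedSeries",
    "average_series",
    "error_metric",
    "read_series_csv",
    "write_series_csv",
]


@dataclass
class FrontSeries:
    """Displacement series: ``times`` (h), ``y`` (µm), optional per-time ``sd``."""

    times: np.ndarray
    y: np.ndarray
    sd: np.ndarray | None = None
    label: str = "experimental"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape:
                raise ValueError("sd length must match times")
        if self.times.ndim != 1 or self.y.shape != self.times.shape:
            raise ValueError("times and y must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and abs(self.times[0]) < 1e-9 and abs(self.y[0]) > 1e-6:
            raise ValueError("displacement at t=0 must be 0")

    def shifted(self, k: float) -> "FrontSeries":
        """Series displaced by k standard deviations (needs ``sd``)."""
        if self.sd is None:
            raise ValueError("series carries no standard deviations")
        y = self.y + k * self.sd
        y = y - y[0] if abs(self.times[0]) < 1e-9 else y
        return FrontSeries(times=self.times.copy(), y=y, sd=self.sd.copy(),
                           label=f"{self.label}{k:+g}sd")


@dataclass
class AveragedSeries:
    """Mean displacement over ``m`` identically prepared realizations."""

    times: np.ndarray
    ybar: np.ndarray
    m: int
    label: str = "averaged"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ybar = np.asarray(self.ybar, dtype=float)
        if self.m < 1:
            raise ValueError("m must be at least 1")


def average_series(series: list[FrontSeries]) -> AveragedSeries:
    """Pointwise mean over realizations sharing one time grid."""
    if not series:
        raise ValueError("need at least one realization")
    t0 = series[0].times
    for s in series[1:]:
        if s.times.shape != t0.shape or not np.allclose(s.times, t0):
            raise ValueError("all realizations must share the same time grid")
    ybar = np.mean([s.y for s in series], axis=0)
    return AveragedSeries(times=t0.copy(), ybar=ybar, m=len(series))


def _select_window(
    times: np.ndarray,
    window: tuple[float, float] | None,
    include_upper: bool,
) -> np.ndarray:
    if window is None:
        # post-initial points only: the t=0 reference contributes nothing
        # to the numerator but would inflate N
        return times > 1e-9
    lo, hi = window
    upper = times <= hi + 1e-9 if include_upper else times < hi - 1e-9
    return (times > lo + 1e-9) & upper


def error_metric(
    sim: AveragedSeries,
    exp: FrontSeries,
    window: tuple[float, float] | None = None,
    *,
    include_upper: bool = True,
) -> float:
    """Normalized L1 discrepancy E between averaged-simulation and experiment.

    ``window=(t_lo, t_hi)`` restricts the sum to times with t_lo < t <= t_hi
    (strictly below t_hi when ``include_upper`` is False); by default all
    post-initial experimental times enter.  N and Y_max are computed on the
    selected window, keeping E dimensionless on sub-windows.
    """
    if sim.times.shape != exp.times.shape or not np.allclose(sim.times, exp.times):
        raise ValueError("sim must be evaluated on the experimental time stamps")
    sel = _select_window(exp.times, window, include_upper)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("window selects no experimental points")
    y_max = float(np.max(exp.y[sel]))
    if y_max <= 0:
        raise ValueError("degenerate normalization: Y_max = 0 on the window")
    return float(np.sum(np.abs(sim.ybar[sel] - exp.y[sel])) / (n * y_max))


def write_series_csv(series: FrontSeries, path: str | Path) -> None:
    """Write ``time_h,displacement_um,sd_um`` (sd column empty when absent)."""
    df = pd.DataFrame(
        {
            "time_h": series.times,
            "displacement_um": series.y,
            "sd_um": series.sd if series.sd is not None else np.full(series.times.shape, np.nan),
        }
    )
    df.to_csv(path, index=False)


def read_series_csv(path: str | Path, label: str = "experimental") -> FrontSeries:
    """Load a displacement series; tolerant of column naming and extra columns."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}

    def pick(*names):
        for nm in names:
            if nm in cols:
                return df[cols[nm]].to_numpy(dtype=float)
        return None

    times = pick("time_h", "time", "t_h", "t")
    y = pick("displacement_um", "displacement", "y_um", "y")
    if times is None or y is None:
        raise ValueError(f"{path}: need time and displacement columns")
    sd = pick("sd_um", "sd", "std_um", "std")
    if sd is not None and np.all(np.isnan(sd)):
        sd = None
    return FrontSeries(times=times, y=y, sd=sd, label=label)
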