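"""Recovering (Pm, Pp) — hence (D, lam) — from leading-edge data.

Two calibration routes are provided.  The naive route scores a full grid of
(Pm, Pp) pairs against the whole displacement series and exposes the
identifiability problem: short-time leading-edge data admit a long, flat
valley of nearly equivalent parameter pairs.  The iterative route exploits
the separation of time scales between motility (minutes per event) and
proliferation (tens of hours per division): Pm is estimated from the early
window t < T with Pp = 0, Pp from the late window t > T with Pm fixed, and
the two one-dimensional scans are alternated until the grid-point estimates
stop changing.  Refinement re-runs the iteration on a denser sub-grid with
more realizations; uncertainty re-runs it on the mean +/- 1 s.d. series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .edges import EdgeConfig, front_series, occupancy_to_image
from .lattice import ModelParams, RateParams, params_to_rates, simulate
from .series import AveragedSeries, FrontSeries, average_series, error_metric

__all__ = [
    "GridSpec",
    "ErrorSurface",
    "EstimateResult",
    "averaged_front_series",
    "grid_scan",
    "estimate_pm",
    "estimate_pp",
    "iterative_estimate",
    "refine",
    "uncertainty",
    "fkpp_wave_speed",
]

log = logging.getLogger(__name__)

# phase tags keep the motility-scan, proliferation-scan and naive-scan seed
# streams disjoint while staying reproducible from one base seed
_TAG_PM, _TAG_PP, _TAG_GRID = 1, 2, 3


@dataclass(frozen=True)
class GridSpec:
    """Equally spaced parameter grid and the realization count per point.

    Defaults follow the standard protocol: Pm on [0, 1] and Pp on [0, 0.01],
    51 values each (2601 combinations), M = 10 realizations per point.
    """

    pm_lo: float = 0.0
    pm_hi: float = 1.0
    pp_lo: float = 0.0
    pp_hi: float = 0.01
    n_pm: int = 51
    n_pp: int = 51
    m: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.pm_lo < self.pm_hi <= 1 and 0 <= self.pp_lo < self.pp_hi <= 1):
            raise ValueError("grid bounds must be ordered and within [0, 1]")
        if self.n_pm < 2 or self.n_pp < 2:
            raise ValueError("need at least 2 grid values per axis")
        if self.m < 1:
            raise ValueError("m must be at least 1")

    @property
    def pm_values(self) -> np.ndarray:
        return np.linspace(self.pm_lo, self.pm_hi, self.n_pm)

    @property
    def pp_values(self) -> np.ndarray:
        return np.linspace(self.pp_lo, self.pp_hi, self.n_pp)

    @property
    def pm_spacing(self) -> float:
        return (self.pm_hi - self.pm_lo) / (self.n_pm - 1)

    @property
    def pp_spacing(self) -> float:
        return (self.pp_hi - self.pp_lo) / (self.n_pp - 1)


@dataclass
class ErrorSurface:
    """E over a (Pm, Pp) grid scored against one reference series."""

    pm_values: np.ndarray
    pp_values: np.ndarray
    e: np.ndarray  # shape (n_pm, n_pp)
    reference: str = "experimental"

    @property
    def argmin(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmin(self.e)), self.e.shape)
        return float(self.pm_values[i]), float(self.pp_values[j])

    def sublevel_pm_span(self, factor: float = 1.5) -> float:
        """Fraction of the Pm axis range covered by {E <= factor * min E}.

        The flat-valley diagnostic: a well-posed problem concentrates the
        sublevel set near the minimum, an ill-posed one spreads it across
        the axis.
        """
        emin = float(self.e.min())
        rows = np.any(self.e <= factor * emin, axis=1)
        pm = self.pm_values[rows]
        rng = self.pm_values[-1] - self.pm_values[0]
        return float((pm.max() - pm.min()) / rng) if pm.size else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        i, j = np.meshgrid(range(len(self.pm_values)), range(len(self.pp_values)), indexing="ij")
        return pd.DataFrame(
            {
                "pm": self.pm_values[i.ravel()],
                "pp": self.pp_values[j.ravel()],
                "e": self.e.ravel(),
            }
        )


@dataclass
class EstimateResult:
    """Converged point estimates with their macroscopic counterparts."""

    pm_hat: float
    pp_hat: float
    d_hat: float
    lam_hat: float
    t_split: float
    iterations: int
    grid: GridSpec
    history: list[tuple[float, float]] = field(default_factory=list)
    pm_range: tuple[float, float] | None = None
    pp_range: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "pm_hat": self.pm_hat,
            "pp_hat": self.pp_hat,
            "d_um2_per_h": self.d_hat,
            "lam_per_h": self.lam_hat,
            "t_split_h": self.t_split,
            "iterations": self.iterations,
            "history": [list(h) for h in self.history],
        }
        if self.pm_range is not None:
            d["pm_range"] = list(self.pm_range)
        if self.pp_range is not None:
            d["pp_range"] = list(self.pp_range)
        return d


def _realization_seed(base_seed: int, tag: int, i: int, j: int, rep: int) -> int:
    return int(np.random.SeedSequence([base_seed, tag, i, j, rep]).generate_state(1)[0] % (2**31))


def averaged_front_series(
    template: ModelParams,
    pm: float,
    pp: float,
    times: np.ndarray,
    m: int,
    *,
    base_seed: int = 0,
    tag: int = 0,
    idx: tuple[int, int] = (0, 0),
    cfg: EdgeConfig | None = None,
) -> AveragedSeries:
    """Averaged simulation data at the given observation times.

    Each of the ``m`` realizations is simulated from the confluent initial
    condition up to the last requested time, rendered to images, and pushed
    through the edge pipeline; the displacement series are then averaged
    pointwise.  Seeds derive deterministically from (base_seed, tag, idx,
    replicate), so repeated calls with the same arguments reproduce the same
    realizations.
    """
    times = np.asarray(times, dtype=float)
    if abs(times[0]) > 1e-9:
        raise ValueError("observation times must start at 0 (displacement reference)")
    p0 = replace(template, pm=pm, pp=pp, t_end=float(times[-1]))
    runs = []
    for r in range(m):
        p = replace(p0, seed=_realization_seed(base_seed, tag, idx[0], idx[1], r))
        snaps = simulate(p, times)
        runs.append(front_series([(t, occupancy_to_image(s)) for t, s in zip(times, snaps)], cfg))
    return average_series(runs)


def grid_scan(
    exp: FrontSeries,
    grid: GridSpec,
    template: ModelParams,
    *,
    base_seed: int = 0,
    cfg: EdgeConfig | None = None,
) -> ErrorSurface:
    """Naive full-series calibration: E over the whole (Pm, Pp) grid.

    Every grid point runs ``grid.m`` fresh realizations for the full
    experimental duration and scores the averaged series against ``exp``
    over all post-initial times.
    """
    if float(np.max(exp.y)) <= 0:
        raise ValueError("degenerate reference series: Y_max = 0")
    times = exp.times if abs(exp.times[0]) < 1e-9 else np.concatenate([[0.0], exp.times])
    e = np.empty((grid.n_pm, grid.n_pp))
    for i, pm in enumerate(grid.pm_values):
        for j, pp in enumerate(grid.pp_values):
            sim = averaged_front_series(
                template, pm, pp, times, grid.m,
                base_seed=base_seed, tag=_TAG_GRID, idx=(i, j), cfg=cfg,
            )
            e[i, j] = error_metric(_on_times(sim, exp.times), exp)
        log.debug("grid_scan: pm=%.3f row done", pm)
    return ErrorSurface(pm_values=grid.pm_values, pp_values=grid.pp_values, e=e,
                        reference=exp.label)


def _on_times(sim: AveragedSeries, times: np.ndarray) -> AveragedSeries:
    """Restrict an averaged series to the given time stamps."""
    sel = np.isin(np.round(sim.times, 9), np.round(times, 9))
    return AveragedSeries(times=sim.times[sel], ybar=sim.ybar[sel], m=sim.m)


def _sub_experiment(exp: FrontSeries, mask: np.ndarray) -> FrontSeries:
    times = np.concatenate([[0.0], exp.times[mask]])
    y = np.concatenate([[0.0], exp.y[mask]])
    return FrontSeries(times=times, y=y, label=exp.label)


def estimate_pm(
    exp: FrontSeries,
    t_split: float,
    pp_fixed: float,
    pm_values: np.ndarray,
    m: int,
    template: ModelParams,
    *,
    base_seed: int = 0,
    cfg: EdgeConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Scan Pm at fixed Pp, scoring E on the early window t < T (strict).

    Returns the argmin-E grid value (ties to the smaller Pm) and the E
    curve.  Simulations run from t = 0; only times inside the window are
    compared.
    """
    mask = (exp.times > 1e-9) & (exp.times < t_split - 1e-9)
    if not mask.any():
        raise ValueError(f"no experimental point falls in 0 < t < {t_split}")
    sub = _sub_experiment(exp, mask)
    e = np.empty(len(pm_values))
    for i, pm in enumerate(pm_values):
        sim = averaged_front_series(
            template, pm, pp_fixed, sub.times, m,
            base_seed=base_seed, tag=_TAG_PM, idx=(i, 0), cfg=cfg,
        )
        e[i] = error_metric(sim, sub)
    return float(pm_values[int(np.argmin(e))]), e


def estimate_pp(
    exp: FrontSeries,
    t_split: float,
    pm_fixed: float,
    pp_values: np.ndarray,
    m: int,
    template: ModelParams,
    *,
    base_seed: int = 0,
    cfg: EdgeConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Scan Pp at fixed Pm, scoring E on the late window t > T (strict)."""
    mask = exp.times > t_split + 1e-9
    if not mask.any():
        raise ValueError(f"no experimental point falls in t > {t_split}")
    sub = _sub_experiment(exp, mask)
    e = np.empty(len(pp_values))
    for j, pp in enumerate(pp_values):
        sim = averaged_front_series(
            template, pm_fixed, pp, sub.times, m,
            base_seed=base_seed, tag=_TAG_PP, idx=(0, j), cfg=cfg,
        )
        e[j] = error_metric(sim, sub)
    return float(pp_values[int(np.argmin(e))]), e


def iterative_estimate(
    exp: FrontSeries,
    t_split: float,
    grid: GridSpec,
    template: ModelParams,
    *,
    pp_template: ModelParams | None = None,
    base_seed: int = 0,
    cfg: EdgeConfig | None = None,
    max_iter: int = 20,
) -> EstimateResult:
    """Separation-of-timescales estimator.

    Starting from Pp = 0, alternate the early-window Pm scan and the
    late-window Pp scan until both estimates converge to within one grid
    spacing between consecutive passes.  Because realization seeds are a
    deterministic function of the scanned grid point, a pass whose Pm
    exactly reproduces the previous pass necessarily reproduces its Pp as
    well, so the iteration also terminates as soon as Pm repeats;
    ``iterations`` counts the (Pm, Pp) passes performed.

    On a discrete grid the deterministic pass map can enter a limit cycle
    between nearby grid points instead of reaching a fixed point; a
    revisited pair is therefore also accepted as converged.

    ``pp_template``, when given, is used for the late-window ensembles
    only — typically a narrower domain, since the expected front
    displacement is independent of the lateral width while the full-length
    simulations carry almost all of the cost.
    """
    pm_values, pp_values = grid.pm_values, grid.pp_values
    pp_tmpl = pp_template if pp_template is not None else template
    pp_cur = 0.0
    history: list[tuple[float, float]] = []
    pm_prev = pp_prev = None
    for k in range(1, max_iter + 1):
        pm_hat, _ = estimate_pm(exp, t_split, pp_cur, pm_values, grid.m, template,
                                base_seed=base_seed, cfg=cfg)
        if pm_prev is not None and pm_hat == pm_prev:
            # identical Pm with identical per-grid-point seeds => the Pp
            # scan would reproduce pp_prev; converged
            history.append((pm_hat, pp_prev))
            return _finish(pm_hat, pp_prev, t_split, k, grid, history, template)
        pp_hat, _ = estimate_pp(exp, t_split, pm_hat, pp_values, grid.m, pp_tmpl,
                                base_seed=base_seed, cfg=cfg)
        log.info("iteration %d: pm=%.4g pp=%.4g", k, pm_hat, pp_hat)
        revisited = (pm_hat, pp_hat) in history
        history.append((pm_hat, pp_hat))
        within_tol = (
            pm_prev is not None
            and abs(pm_hat - pm_prev) <= grid.pm_spacing + 1e-12
            and abs(pp_hat - pp_prev) <= grid.pp_spacing + 1e-12
        )
        if within_tol or revisited:
            return _finish(pm_hat, pp_hat, t_split, k, grid, history, template)
        pm_prev, pp_prev, pp_cur = pm_hat, pp_hat, pp_hat
    raise RuntimeError(f"estimates did not converge within {max_iter} iterations")


def _finish(pm, pp, t_split, k, grid, history, template) -> EstimateResult:
    rates = params_to_rates(template.with_probs(pm, pp))
    return EstimateResult(
        pm_hat=pm, pp_hat=pp, d_hat=rates.d, lam_hat=rates.lam,
        t_split=t_split, iterations=k, grid=grid, history=history,
    )


def refine(
    exp: FrontSeries,
    prev: EstimateResult,
    subgrid: GridSpec,
    template: ModelParams,
    *,
    pp_template: ModelParams | None = None,
    base_seed: int = 0,
    cfg: EdgeConfig | None = None,
) -> EstimateResult:
    """Re-run the iteration on a denser sub-grid with more realizations.

    The sub-grid must bracket the previous estimates (typically the halved
    intervals, with M raised from 10 to 50).
    """
    if not (subgrid.pm_lo <= prev.pm_hat <= subgrid.pm_hi
            and subgrid.pp_lo <= prev.pp_hat <= subgrid.pp_hi):
        raise ValueError("refinement sub-grid must contain the previous estimates")
    return iterative_estimate(exp, prev.t_split, subgrid, template,
                              pp_template=pp_template, base_seed=base_seed, cfg=cfg)


def uncertainty(
    exp: FrontSeries,
    t_split: float,
    grid: GridSpec,
    template: ModelParams,
    *,
    pp_template: ModelParams | None = None,
    base_seed: int = 0,
    cfg: EdgeConfig | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Estimate ranges by re-running on the mean +/- 1 sample s.d. series.

    Returns ``(pm_range, pp_range)``: the min/max of the three point
    estimates (mean, mean+sd, mean-sd) per parameter.
    """
    if exp.sd is None:
        raise ValueError("uncertainty quantification needs per-time standard deviations")
    results = [
        iterative_estimate(series, t_split, grid, template, pp_template=pp_template,
                           base_seed=base_seed, cfg=cfg)
        for series in (exp, exp.shifted(+1.0), exp.shifted(-1.0))
    ]
    pms = [r.pm_hat for r in results]
    pps = [r.pp_hat for r in results]
    return (min(pms), max(pms)), (min(pps), max(pps))


def fkpp_wave_speed(r: RateParams) -> float:
    """Long-time Fisher-Kolmogorov travelling-wave speed 2*sqrt(lam*D), µm/h.

    Valid only in the t -> infinity limit; short-time assay fronts move
    slower than this because no travelling wave has formed yet.
    """
    return 2.0 * float(np.sqrt(r.lam * r.d))
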