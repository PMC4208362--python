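"""Shared fixtures: synthetic experiments and the heavier calibration runs.

Everything is generated programmatically and seeded; the expensive
estimator runs are session-scoped so several tests can interrogate one
computation.

Study conditions: the assay geometry (delta = 25 µm, tau = 0.09191 h,
Ly = 3.75 mm, Y0 = 750 µm, 24 h) is never scaled.  The data-generating
realization and the short early-window scan ensembles run at the full
12.5 mm lateral width; the full-length late-window ensembles run on a
5 mm domain (the expected front displacement is width-independent — the
lateral extent only sets Monte-Carlo noise — while the 24 h simulations
carry almost all of the cost).  The naive-scan valley and the
in-vitro-like protocol use their own smaller domains, as noted.
"""

from __future__ import annotations

import numpy as np
import pytest

import scratchcal as sc
from scratchcal.fixtures import in_silico_sample_times, make_in_vitro_like_series

TRUTH_PM, TRUTH_PP = 0.5, 5e-3
FULL_LX = 12500.0
PP_SCAN_LX = 5000.0
BASE_SEED = 5


@pytest.fixture(scope="session")
def full_truth() -> sc.ModelParams:
    return sc.ModelParams(pm=TRUTH_PM, pp=TRUTH_PP, lx=FULL_LX)


@pytest.fixture(scope="session")
def pp_scan_template() -> sc.ModelParams:
    return sc.ModelParams(pm=TRUTH_PM, pp=TRUTH_PP, lx=PP_SCAN_LX)


@pytest.fixture(scope="session")
def in_silico_experiment(full_truth):
    """One 24 h full-width realization at (0.5, 5e-3), observed through the edge pipeline."""
    times = in_silico_sample_times(full_truth)
    return sc.make_in_silico_experiment(full_truth, times, seed=1)


@pytest.fixture(scope="session")
def iterative_result(in_silico_experiment, full_truth, pp_scan_template):
    """Separation-of-timescales run: T = 3 h, 51-value grids, M = 10."""
    return sc.iterative_estimate(
        in_silico_experiment.series, 3.0, sc.GridSpec(), full_truth,
        pp_template=pp_scan_template, base_seed=BASE_SEED,
    )


@pytest.fixture(scope="session")
def t_robustness_results(in_silico_experiment, full_truth, pp_scan_template):
    """Estimates for T in {2, 3, 4} h on the same realization (21-value grids)."""
    grid = sc.GridSpec(n_pm=21, n_pp=21, m=10)
    return {
        t: sc.iterative_estimate(in_silico_experiment.series, t, grid, full_truth,
                                 pp_template=pp_scan_template, base_seed=BASE_SEED)
        for t in (2.0, 3.0, 4.0)
    }


@pytest.fixture(scope="session")
def naive_surface():
    """Whole-series grid scan against a full-width 6-time-point realization.

    The reference keeps the quiet full-width realization; the ensembles run
    on a 1.25 mm domain.  The Pp axis is kept dense (41 values) because a
    coarse Pp grid misses each row's valley-bottom Pp and artificially
    inflates the off-centre row minima that the flat-valley diagnostic
    measures.
    """
    ref_truth = sc.ModelParams(pm=TRUTH_PM, pp=TRUTH_PP, lx=FULL_LX)
    scan_t = sc.ModelParams(pm=TRUTH_PM, pp=TRUTH_PP, lx=1250.0)
    times = np.array([0.0, 3.0, 6.0, 9.0, 12.0, 24.0])
    fx = sc.make_in_silico_experiment(ref_truth, times, seed=3)
    grid = sc.GridSpec(n_pm=17, n_pp=41, m=10)
    return sc.grid_scan(fx.series, grid, scan_t, base_seed=9)


@pytest.fixture(scope="session")
def vitro_series():
    """In-vitro-like 6-point series with per-field standard deviations."""
    return make_in_vitro_like_series(seed=7)


@pytest.fixture(scope="session")
def vitro_scan_template() -> sc.ModelParams:
    # ensemble domain for calibrating the in-vitro-like series: wider than
    # the 2 mm field of view to keep the averaged curves quiet
    return sc.ModelParams(pm=0.17, pp=2.7e-3, lx=PP_SCAN_LX)


@pytest.fixture(scope="session")
def vitro_results(vitro_series, vitro_scan_template):
    """Estimates for T in {6, 9} h on the in-vitro-like series."""
    grid = sc.GridSpec(n_pm=26, n_pp=26, m=10)
    return {
        t: sc.iterative_estimate(vitro_series, t, grid, vitro_scan_template,
                                 base_seed=BASE_SEED)
        for t in (6.0, 9.0)
    }
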