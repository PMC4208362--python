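"""Unit and property tests for the exclusion-process simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scratchcal as sc
from scratchcal.lattice import record_steps_for_times


class TestParameterConversion:
    def test_in_vitro_estimates_map_to_reported_rates(self):
        # (0.17, 2.7e-3) at delta=25 µm, tau=0.09191 h is quoted as
        # (D, lam) ~ (300 µm²/h, 0.03 /h) with a ~34 h doubling scale
        r = sc.params_to_rates(sc.ModelParams(pm=0.17, pp=2.7e-3))
        assert round(r.d, -2) == 300.0
        assert round(r.lam, 2) == 0.03
        assert abs(1.0 / r.lam - 34.0) < 0.5

    @pytest.mark.parametrize(
        "pm,pp,d,lam",
        [
            (0.0, 0.0, 0.0, 0.0),
            (0.5, 5e-3, 850.0163203, 0.054401044),
        ],
    )
    def test_closed_form(self, pm, pp, d, lam):
        r = sc.params_to_rates(sc.ModelParams(pm=pm, pp=pp))
        assert r.d == pytest.approx(d)
        assert r.lam == pytest.approx(lam)

    def test_inverse_recovers_probabilities(self):
        pm, pp = sc.rates_to_params(sc.RateParams(d=289.0, lam=0.02938), 25.0, 0.09191)
        assert pm == pytest.approx(0.17, abs=1e-3)
        assert pp == pytest.approx(2.7e-3, abs=1e-5)

    def test_out_of_range_diffusivity_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sc.rates_to_params(sc.RateParams(d=1e6, lam=0.0), 25.0, 0.09191)

    @given(pm=st.floats(0, 1), pp=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, pm, pp):
        p = sc.ModelParams(pm=pm, pp=pp)
        pm2, pp2 = sc.rates_to_params(sc.params_to_rates(p), p.delta, p.tau)
        assert pm2 == pytest.approx(pm, abs=1e-12)
        assert pp2 == pytest.approx(pp, abs=1e-12)


class TestInitialCondition:
    def test_full_scale_monolayer_counts(self):
        p = sc.ModelParams(pm=0.5, pp=0.0)
        occ = sc.init_monolayer(p)
        assert occ.grid[:30, :].all() and not occ.grid[30:, :].any()
        assert occ.n_agents == 30 * 500 == 15000

    def test_single_row_strip(self):
        p = sc.ModelParams(pm=0.1, pp=0.0, lx=250, ly=250, y0=25)
        assert sc.init_monolayer(p).n_agents == 10

    def test_degenerate_strip_rejected(self):
        with pytest.raises(ValueError):
            sc.ModelParams(pm=0.1, pp=0.0, lx=250, ly=250, y0=0)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            sc.ModelParams(pm=1.2, pp=0.0)


def _lone_agent(p, row, col):
    grid = np.zeros((p.n_rows, p.n_cols), np.uint8)
    grid[row, col] = 1
    return sc.Occupancy(grid=grid, delta=p.delta)


class TestStep:
    def test_conservation_without_proliferation(self):
        p = sc.ModelParams(pm=0.8, pp=0.0, lx=500, ly=500, y0=250)
        occ = sc.init_monolayer(p)
        rng = np.random.default_rng(0)
        for _ in range(20):
            occ = sc.step(occ, p, rng)
            assert occ.n_agents == 200
            assert occ.grid.max() <= 1

    def test_full_lattice_is_frozen(self):
        p = sc.ModelParams(pm=1.0, pp=1.0, lx=250, ly=250, y0=225)
        grid = np.ones((10, 10), np.uint8)
        occ = sc.Occupancy(grid=grid, delta=25.0)
        out = sc.step(occ, p, np.random.default_rng(1))
        assert np.array_equal(out.grid, grid)

    def test_monotone_growth_with_proliferation(self):
        p = sc.ModelParams(pm=0.2, pp=0.5, lx=500, ly=500, y0=100)
        occ = sc.init_monolayer(p)
        rng = np.random.default_rng(2)
        counts = [occ.n_agents]
        for _ in range(15):
            occ = sc.step(occ, p, rng)
            counts.append(occ.n_agents)
        assert np.all(np.diff(counts) >= 0) and counts[-1] > counts[0]

    def test_msd_matches_unbiased_walk(self):
        # a lone always-moving agent performs an unbiased 4-neighbour walk:
        # MSD after n steps is n * delta^2
        p = sc.ModelParams(pm=1.0, pp=0.0, lx=1025, ly=1025, y0=25)
        n_steps, reps = 8, 4000
        rng = np.random.default_rng(3)
        sq = 0.0
        for _ in range(reps):
            occ = _lone_agent(p, 20, 20)
            for _ in range(n_steps):
                occ = sc.step(occ, p, rng)
            r, c = np.argwhere(occ.grid)[0]
            sq += ((r - 20) ** 2 + (c - 20) ** 2) * p.delta**2
        msd = sq / reps
        assert msd == pytest.approx(n_steps * p.delta**2, rel=0.08)

    def test_bulk_strip_drift_is_unbiased(self):
        # a strip placed mid-domain spreads symmetrically: centre of mass
        # stays put within Monte-Carlo error
        p = sc.ModelParams(pm=1.0, pp=0.0, lx=750, ly=1500, y0=25)
        rng = np.random.default_rng(4)
        drifts = []
        for _ in range(30):
            grid = np.zeros((p.n_rows, p.n_cols), np.uint8)
            grid[27:33, :] = 1
            occ = sc.Occupancy(grid=grid, delta=p.delta)
            y0 = np.argwhere(occ.grid)[:, 0].mean()
            for _ in range(25):
                occ = sc.step(occ, p, rng)
            drifts.append((np.argwhere(occ.grid)[:, 0].mean() - y0) * p.delta)
        se = np.std(drifts, ddof=1) / np.sqrt(len(drifts))
        assert abs(np.mean(drifts)) < 4 * se + 1e-9


class TestSimulate:
    def test_zero_duration_returns_initial_state(self):
        p = sc.ModelParams(pm=0.5, pp=5e-3, lx=500, ly=500, y0=100, t_end=0.0)
        snaps = sc.simulate(p, [0.0])
        assert len(snaps) == 1
        assert np.array_equal(snaps[0].grid, sc.init_monolayer(p).grid)

    def test_determinism_for_fixed_seed(self):
        p = sc.ModelParams(pm=0.5, pp=5e-3, lx=1000, t_end=6.0, seed=9)
        a = sc.simulate(p, [0.0, 3.0, 6.0])
        b = sc.simulate(p, [0.0, 3.0, 6.0])
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.grid, s2.grid)

    def test_record_time_beyond_duration_rejected(self):
        p = sc.ModelParams(pm=0.5, pp=0.0, lx=500, t_end=6.0)
        with pytest.raises(ValueError, match="within"):
            sc.simulate(p, [0.0, 12.0])

    def test_growth_and_boundary_containment(self):
        p = sc.ModelParams(pm=0.5, pp=5e-3, lx=1000, seed=4)
        snaps = sc.simulate(p, [0.0, 24.0])
        assert snaps[-1].n_agents > snaps[0].n_agents
        # no agent reaches the far boundary within 24 h at assay geometry
        assert not snaps[-1].grid[-1, :].any()
        assert snaps[-1].grid.max() <= 1

    def test_nearest_step_snapshot_rule(self):
        p = sc.ModelParams(pm=0.1, pp=0.0, lx=500, t_end=1.0)
        steps = record_steps_for_times(p, [0.0, 0.0460, 0.1378, 1.0])
        # tau = 0.09191 h: 0.0460 h is nearest step 1 (ties go earlier),
        # 0.1378 h sits midway between steps 1 and 2 -> earlier step wins
        assert list(steps) == [0, 1, 1, 11]
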