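"""Lattice-based exclusion-process model of a scratch assay.

Cells are agents on a 2-D square lattice (spacing ``delta`` µm); each site
holds at most one agent.  Per time step of duration ``tau`` hours, ``Z(t)``
agents are selected at random (with replacement) and each moves with
probability ``Pm`` to a uniformly chosen nearest-neighbour site; a further
``Z(t)`` selections then attempt, with probability ``Pp``, to place a
daughter on a uniformly chosen neighbour.  Crowding aborts both kinds of
event: an attempt onto an occupied or out-of-domain site does nothing.

The discrete probabilities map onto macroscopic rates via

    D = Pm * delta**2 / (4 * tau)        (cell diffusivity, µm²/h)
    lam = Pp / tau                        (proliferation rate, 1/h)

so ``(Pm, Pp)`` and ``(D, lam)`` are interchangeable at fixed ``(delta,
tau)``.  The domain mimics the scratched-monolayer geometry: rows are
indexed by ``y`` with ``y = 0`` on the monolayer side, the strip
``y < Y0`` starts confluent, and boundaries are zero-flux (attempts that
leave the domain are aborted).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "ModelParams",
    "RateParams",
    "Occupancy",
    "params_to_rates",
    "rates_to_params",
    "init_monolayer",
    "step",
    "simulate",
]

# Lattice/domain constants used throughout the assay geometry (µm, h).
DELTA_UM = 25.0
TAU_H = 0.09191
LX_UM = 12.5e3
LY_UM = 3.75e3
Y0_UM = 750.0
T_END_H = 24.0


def _check_multiple(name: str, value: float, delta: float) -> int:
    n = value / delta
    n_int = int(round(n))
    if n_int <= 0 or abs(n - n_int) > 1e-9:
        raise ValueError(f"{name}={value} must be a positive integer multiple of delta={delta}")
    return n_int


@dataclass(frozen=True)
class ModelParams:
    """One simulation's full parameterization.

    ``pm``/``pp`` are per-step event probabilities, ``delta`` the lattice
    spacing (µm), ``tau`` the step duration (h); ``lx``/``ly`` the domain
    extent and ``y0`` the initially confluent monolayer height (µm, all
    integer multiples of ``delta``); ``t_end`` the simulated duration (h).
    """

    pm: float
    pp: float
    delta: float = DELTA_UM
    tau: float = TAU_H
    lx: float = LX_UM
    ly: float = LY_UM
    y0: float = Y0_UM
    t_end: float = T_END_H
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pm <= 1.0 and 0.0 <= self.pp <= 1.0):
            raise ValueError(f"pm={self.pm}, pp={self.pp} must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.t_end < 0:
            raise ValueError("t_end must be non-negative")
        _check_multiple("lx", self.lx, self.delta)
        _check_multiple("ly", self.ly, self.delta)
        _check_multiple("y0", self.y0, self.delta)
        if not self.y0 < self.ly:
            raise ValueError("y0 must be smaller than ly")

    @property
    def n_cols(self) -> int:
        return int(round(self.lx / self.delta))

    @property
    def n_rows(self) -> int:
        return int(round(self.ly / self.delta))

    @property
    def y0_rows(self) -> int:
        return int(round(self.y0 / self.delta))

    @property
    def n_steps(self) -> int:
        return int(np.ceil(self.t_end / self.tau - 1e-12))

    def with_probs(self, pm: float, pp: float, **kw) -> "ModelParams":
        return replace(self, pm=pm, pp=pp, **kw)

    def to_dict(self) -> dict:
        return {
            "pm": self.pm,
            "pp": self.pp,
            "delta_um": self.delta,
            "tau_h": self.tau,
            "lx_um": self.lx,
            "ly_um": self.ly,
            "y0_um": self.y0,
            "t_end_h": self.t_end,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            pm=float(d["pm"]),
            pp=float(d["pp"]),
            delta=float(d.get("delta_um", DELTA_UM)),
            tau=float(d.get("tau_h", TAU_H)),
            lx=float(d.get("lx_um", LX_UM)),
            ly=float(d.get("ly_um", LY_UM)),
            y0=float(d.get("y0_um", Y0_UM)),
            t_end=float(d.get("t_end_h", T_END_H)),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class RateParams:
    """Macroscopic rates: diffusivity ``d`` (µm²/h), proliferation ``lam`` (1/h)."""

    d: float
    lam: float

    def __post_init__(self) -> None:
        if self.d < 0 or self.lam < 0:
            raise ValueError("d and lam must be non-negative")


@dataclass(frozen=True)
class Occupancy:
    """Binary lattice state; ``grid[j, i]`` is the site at y = j*delta, x = i*delta."""

    grid: np.ndarray  # uint8, shape (n_rows, n_cols)
    delta: float

    @property
    def n_agents(self) -> int:
        return int(self.grid.sum())


def params_to_rates(p: ModelParams) -> RateParams:
    """Convert per-step probabilities to (D, lam)."""
    return RateParams(d=p.pm * p.delta**2 / (4.0 * p.tau), lam=p.pp / p.tau)


def rates_to_params(r: RateParams, delta: float, tau: float) -> tuple[float, float]:
    """Invert :func:`params_to_rates`; raises when a probability would exceed 1."""
    pm = 4.0 * r.d * tau / delta**2
    pp = r.lam * tau
    if pm > 1.0 + 1e-12 or pp > 1.0 + 1e-12:
        raise ValueError(
            f"(d={r.d}, lam={r.lam}) implies (pm={pm:.4g}, pp={pp:.4g}) outside [0, 1] "
            f"at delta={delta}, tau={tau}"
        )
    return min(pm, 1.0), min(pp, 1.0)


def init_monolayer(p: ModelParams) -> Occupancy:
    """Confluent strip y < y0 occupied, everything above vacant."""
    grid = np.zeros((p.n_rows, p.n_cols), dtype=np.uint8)
    grid[: p.y0_rows, :] = 1
    return Occupancy(grid=grid, delta=p.delta)


@njit(cache=True)
def _run_steps(grid, n_steps, pm, pp, record_steps, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    rows, cols = grid.shape
    cap = rows * cols
    ax = np.empty(cap, np.int32)
    ay = np.empty(cap, np.int32)
    z = 0
    for j in range(rows):
        for i in range(cols):
            if grid[j, i]:
                ay[z] = j
                ax[z] = i
                z += 1
    n_rec = record_steps.shape[0]
    snaps = np.zeros((n_rec, rows, cols), np.uint8)
    k = 0
    while k < n_rec and record_steps[k] == 0:
        snaps[k] = grid
        k += 1
    for s in range(1, n_steps + 1):
        z0 = z
        # Each phase makes z0 sequential selections with replacement, the
        # selected agent attempting its event with probability pm (resp.
        # pp).  Non-attempting selections are no-ops, so the number of
        # attempts is drawn as Binomial(z0, p) and each attempt's agent is
        # an independent uniform pick -- identical in distribution, far
        # fewer random draws.
        n_moves = np.random.binomial(z0, pm)
        for _ in range(n_moves):
            a = np.random.randint(z0)
            d = np.random.randint(4)
            x = ax[a]
            y = ay[a]
            if d == 0:
                x += 1
            elif d == 1:
                x -= 1
            elif d == 2:
                y += 1
            else:
                y -= 1
            if 0 <= x < cols and 0 <= y < rows and grid[y, x] == 0:
                grid[ay[a], ax[a]] = 0
                grid[y, x] = 1
                ax[a] = x
                ay[a] = y
        # proliferation attempts select among step-start agents only;
        # daughters become eligible from the next step
        n_births = np.random.binomial(z0, pp)
        for _ in range(n_births):
            a = np.random.randint(z0)
            d = np.random.randint(4)
            x = ax[a]
            y = ay[a]
            if d == 0:
                x += 1
            elif d == 1:
                x -= 1
            elif d == 2:
                y += 1
            else:
                y -= 1
            if 0 <= x < cols and 0 <= y < rows and grid[y, x] == 0:
                grid[y, x] = 1
                ax[z] = x
                ay[z] = y
                z += 1
        while k < n_rec and record_steps[k] == s:
            snaps[k] = grid
            k += 1
    return snaps


def _kernel_seed(*keys: int) -> int:
    """Deterministic sub-2^31 seed from an integer key tuple."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def step(occ: Occupancy, p: ModelParams, rng: np.random.Generator) -> Occupancy:
    """Advance one random-sequential-update time step.

    Agents are rebuilt from the grid in row-major order; randomness for the
    step is drawn from ``rng`` (one 31-bit seed feeding the compiled kernel).
    """
    if occ.grid.shape != (p.n_rows, p.n_cols):
        raise ValueError("occupancy shape inconsistent with params")
    grid = occ.grid.copy()
    seed = int(rng.integers(0, 2**31))
    snaps = _run_steps(grid, 1, p.pm, p.pp, np.array([1], dtype=np.int64), seed)
    return Occupancy(grid=snaps[0], delta=p.delta)


def record_steps_for_times(p: ModelParams, record_times: Sequence[float]) -> np.ndarray:
    """Map requested times (h) to the nearest step index, ties to the earlier step."""
    times = np.asarray(record_times, dtype=float)
    if np.any(times < 0) or np.any(times > p.t_end + 1e-9):
        raise ValueError("record times must lie within [0, t_end]")
    if np.any(np.diff(times) < 0):
        raise ValueError("record times must be sorted")
    steps = np.floor(times / p.tau + 0.5 - 1e-12).astype(np.int64)
    return np.minimum(steps, p.n_steps)


def simulate(p: ModelParams, record_times: Sequence[float]) -> list[Occupancy]:
    """Run one realization and return snapshots at the step nearest each time.

    Bit-for-bit reproducible for fixed ``(p, p.seed)``.
    """
    steps = record_steps_for_times(p, record_times)
    occ0 = init_monolayer(p)
    snaps = _run_steps(
        occ0.grid, p.n_steps, p.pm, p.pp, steps, _kernel_seed(p.seed)
    )
    return [Occupancy(grid=s, delta=p.delta) for s in snaps]
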