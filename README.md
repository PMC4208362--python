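# scratchcal

Estimating cell diffusivity *D* and cell proliferation rate *λ* from the
one measurement every scratch (wound-healing) assay provides for free: the
position of the leading edge over time.

`scratchcal` is for experimentalists and modellers who quantify collective
cell spreading. It bundles three pieces:

- a stochastic lattice-based exclusion-process simulator of migrating,
  proliferating cells in the scratched-monolayer geometry (at most one
  agent per site; per time step τ, each of Z(t) randomly selected agents
  moves with probability P_m, then Z(t) further selections each place a
  daughter with probability P_p; crowded events abort). The probabilities
  map to rates via **D = P_m Δ²/(4τ)** and **λ = P_p/τ** for lattice
  spacing Δ;
- an automated leading-edge detector (Canny edges → 7×7 dilation → hole
  fill → erosion → median smoothing) reducing each image to a front
  position via the enclosed-area estimator **Y = A / L_x**;
- grid-search calibration against the displacement series using the
  normalized L1 error **E = (1/(N·Y_max)) Σᵢ |⟨Yⁱ⟩ − Yⁱ|**, in two
  flavours: the naive whole-series scan, which demonstrates that
  short-time leading-edge data *cannot* identify (D, λ) jointly (a flat
  valley of equivalent parameter pairs), and the iterative
  separation-of-timescales estimator, which can: P_m from the
  motility-dominated window t < T, P_p from t > T, alternated to
  convergence, plus sub-grid refinement and ±1 s.d. uncertainty ranges.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate a 24 h in silico scratch assay at known parameters, observe it
through the edge pipeline, and recover the parameters from the
displacement series alone:

```python
import numpy as np
import scratchcal as sc
from scratchcal.fixtures import in_silico_sample_times, make_in_silico_experiment

truth = sc.ModelParams(pm=0.5, pp=5e-3)        # Δ=25 µm, τ=0.09191 h defaults
times = in_silico_sample_times(truth)
fx = make_in_silico_experiment(truth, times, seed=1)

pp_scan = sc.ModelParams(pm=0.5, pp=5e-3, lx=5000)  # desk-scaled 24 h ensembles
result = sc.iterative_estimate(fx.series, t_split=3.0, grid=sc.GridSpec(),
                               template=truth, pp_template=pp_scan, base_seed=5)
print(f"pm={result.pm_hat:.2f}  pp={result.pp_hat:.4f}  "
      f"D={result.d_hat:.0f} µm²/h  lam={result.lam_hat:.4f} /h  "
      f"iterations={result.iterations}")
```

which prints (in a few minutes on one CPU)

```
pm=0.52  pp=0.0044  D=884 µm²/h  lam=0.0479 /h  iterations=3
```

— the early-window scan lands one grid spacing from the generating
P_m = 0.5 (its step-1 value, `result.history[0]`, is (0.52, 0.0044)), the
late-window scan within three spacings of the generating P_p = 5×10⁻³
(the generating rates are D = 850 µm²/h, λ = 0.0544 h⁻¹), and the
alternation settles after orbiting one pair of adjacent grid points. The
same call on `make_in_vitro_like_series(seed=7)` (an assay-schedule
fixture: 6 time points, 4 fields of view of one scratch, generated at
P_m = 0.17, P_p = 2.7×10⁻³) with `t_split=9.0` returns (0.16, 4.8×10⁻³):
the motility estimate tracks the generating value to one grid spacing,
while the division probability is constrained only up to the
motility/proliferation trade-off at this data quality — with a single
early-window time point, ±1 spacing of P_m jitter moves the compensating
P_p by several spacings (see `docs/methods.md`, Known limitations).

For contrast, `grid_scan` on the same data produces a surface whose
{E ≤ 1.5·min E} sublevel set stretches across most of the P_m axis:
whole-series fitting cannot choose among those parameter pairs.

A command-line interface wraps these steps (`scratchcal simulate`,
`detect`, `calibrate-naive`, `calibrate-iterative`, `make-fixtures`); run
`scratchcal --help`.

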