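# Methods

## The problem

A scratch (wound-healing) assay clears a strip in a confluent cell
monolayer and images the re-closing front over a short period, usually no
more than 24 h. The cheapest quantity one can extract from such images is
the position of the leading edge over time. `scratchcal` asks, and answers,
the question of what that one curve can tell us about the two rates that
govern collective spreading: the cell diffusivity *D* (µm²/h, random
undirected motility) and the proliferation rate *λ* (1/h, per-cell
division rate, 1/λ being the mean time for an isolated cell to divide).

The answer is twofold. Naive calibration — matching the whole displacement
curve over a (D, λ) grid — is ill-posed: a long, flat valley of parameter
pairs reproduces short-time leading-edge data equally well, because over
&lt;24 h a deficit in motility can be traded against a surplus in
proliferation. But the two processes live on very different time scales
(minutes per movement event versus tens of hours per division), so the
early part of the curve is informative about *D* almost alone. Splitting
the series at a time *T* and estimating *D* from *t* &lt; *T* (with λ
pinned to 0) and λ from *t* &gt; *T* (with *D* pinned to its early-window
estimate), iterated to convergence, restores identifiability.

## Discrete model

Cells are agents on a 2-D square lattice with spacing Δ = 25 µm (a typical
cell diameter), at most one agent per site. Per time step of duration τ:

1. *Motility phase*: Z(t) agents are selected at random, one at a time,
   with replacement (Z(t) = agent count at the start of the step); each
   selected agent moves with probability P_m to one of its four nearest
   neighbours, chosen uniformly.
2. *Proliferation phase*: a further Z(t) selections; each selected agent
   places a daughter with probability P_p on a uniformly chosen neighbour.

Any event whose target site is occupied or outside the domain is aborted —
volume exclusion is what couples the two processes and caps the local
density. The discrete probabilities map to rates via

    D = P_m Δ² / (4τ),      λ = P_p / τ,

so with τ = 0.09191 h the in-vitro-typical pair (P_m, P_p) =
(0.17, 2.7×10⁻³) corresponds to (D, λ) ≈ (289 µm²/h, 0.029 h⁻¹), i.e.
≈ (300, 0.03) and a ~34 h division time. Averaged front data are
insensitive to the particular τ once (D, λ) are held fixed (a property
test checks this).

Geometry mimics the assay: domain [0, L_x]×[0, L_y], the strip y < Y₀
initially confluent (Y₀ = 750 µm), L_y = 3.75 mm tall enough that no agent
reaches the far boundary within 24 h. Boundaries are zero-flux,
implemented as aborted events; for the statistics of an exclusion process
with a confluent strip at the wall this is equivalent to mirror symmetry.
Daughters born within a step become eligible for selection only from the
next step. There is no death mechanism, so Z(t) is non-decreasing.

The sequential update is compiled with numba. One exact optimization is
applied: since non-attempting selections are no-ops, each phase draws the
number of attempts as Binomial(Z, p) and then assigns each attempt an
independent uniformly chosen agent — identical in distribution to Z
Bernoulli selections, at a fraction of the random-number cost. Each
realization's generator is seeded from a `numpy.random.SeedSequence` over
(base seed, scan phase, grid indices, replicate), making every surface and
estimate bit-reproducible from one integer.

## Edge detection

Both micrographs and rendered simulation snapshots (1 pixel per site,
occupied = 1) pass through the same fixed chain: Canny edge detection
(high threshold default 0.07, within the sensible 0.04–0.1 band; low
threshold 0.4× the high one), dilation with a 7×7 square structuring
element, hole filling, erosion with the same element, 3×3 median
smoothing, then selection of the largest connected region touching the
monolayer-side image border. The front position is the enclosed-area
estimator Y = A / L_x, and the displacement series is Y(t) − Y(0).

Two conventions had to be fixed where a standard imfill-style chain is
ambiguous:

- *Border closure.* Hole filling cannot close a region that is open at an
  image border; the monolayer-side and the two lateral borders are treated
  as foreground during the fill so that the area between the detected edge
  band and the monolayer wall counts as enclosed. The leading side stays
  open. Erosion uses a foreground border value so image edges are not
  shaved. On a noiseless straight edge the chain then recovers the true
  front height to within the structuring-element half-width (≤ 3 px).
- *Region choice.* Detached cell clusters ahead of the front form their
  own connected regions and are excluded from A; an isolated noise pixel
  can perturb Y by at most `dilation_size² · pixel_size² / L_x`.

Image polarity is auto-detected (the image is inverted when the
monolayer-side border row is darker than the leading-side row), and the
`origin` field says which image side is the monolayer. Experimental images
keep their native pixel size; simulation images use Δ per pixel.

## Series comparison

Averaged simulation data is the pointwise mean of M identically prepared
realizations. Discrepancy against an experimental series Y^i is

    E = (1 / (N·Y_max)) Σ_i |⟨Y^i⟩ − Y^i|,

summed over the N selected post-initial time indices, Y_max being the
largest experimental displacement among them. The t = 0 reference point is
excluded (it contributes nothing but would inflate N). N and Y_max are
recomputed per comparison window so that E stays dimensionless and O(1) on
the sub-windows the iterative method scores. Simulated series are
evaluated at the simulation step nearest each experimental time stamp
(τ ≈ 0.09 h ≪ the hours-scale sampling interval, so no interpolation).

## Calibration

*Naive grid scan*: E over P_m ∈ [0, 1] × P_p ∈ [0, 0.01] (51×51 values
and M = 10 in the reference protocol), scored on the full series. On
short-time data the surface has a long diagonal valley — a deficit in
P_m traded against a surplus in P_p — whose floor is set by the
reference realization's own noise, so a wide band of parameter pairs
fits a single realization to within Monte-Carlo error: the
non-identifiability result. The diagnostic `sublevel_pm_span` measures
the fraction of the P_m axis covered by {E ≤ factor·min E}; in measured
surfaces the valley's row minima stay within a few times min E over
roughly a quarter of the axis, while well-identified surfaces (the
early-window P_m scan) pin the minimum to one or two grid values.

*Iterative estimator*: Step 1 scans P_m with P_p = 0 against the window
t < T (strict); Step 2 scans P_p with P_m fixed against t > T (strict; a
sample exactly at T belongs to neither window); further passes repeat the
two scans with the latest values until consecutive passes agree to within
one grid spacing in each parameter — the natural tolerance on a discrete
grid, where demanding exact recurrence can fail to terminate (the
deterministic pass map may orbit a short limit cycle between adjacent
grid points rather than reach a fixed point; a revisited pair is likewise
accepted as converged). Ties at equal E break toward the smaller
parameter. Because the realization seeds attached to each scanned grid
point are deterministic, a pass that exactly reproduces the previous P_m
necessarily reproduces P_p too, so the P_p rescan is skipped in that
case; the iteration count tallies the (P_m, P_p) passes performed. A cap
(default 20) guards non-convergence.

*T* must sit well above the motility time scale (minutes) and well below
the division time scale (tens of hours); estimates are insensitive to T
within that band (checked for T ∈ {2, 3, 4} h on synthetic data and
{6, 9} h on the assay-schedule fixture). *Refinement* re-runs the
iteration on a denser sub-grid bracketing the first estimates with larger
M (the 10 → 50 escalation). *Uncertainty* re-runs the whole iteration on
the mean ± 1 sample s.d. series and reports the min/max of the three point
estimates per parameter.

The Fisher–Kolmogorov asymptotic wave speed 2√(λD) is provided as a
comparator only: 24 h of data is far short of the travelling-wave regime,
and the observed mean front speed undershoots it — the reason wave-speed
fitting is inappropriate for short assays.

## Synthetic data

Two generators define the study conditions:

- `make_in_silico_experiment`: one realization at known parameters,
  rendered to images and read back through the edge pipeline (so the
  fixture carries the same quantization a real stack would), with the
  truth recorded. The default observation cadence samples every 5th step
  (≈ 0.46 h) up to 4.5 h — enough points in the early window for any
  T ∈ {2, 3, 4} h — and every 20th step (≈ 1.8 h) thereafter.
- `make_in_vitro_like_series`: a stand-in for a real 3T3-fibroblast
  leading-edge dataset: four replicate fields of view (independent
  realizations, 2 mm wide — the microscope field) at (P_m, P_p) =
  (0.17, 2.7×10⁻³), imaged at t = 0, 3, 6, 9, 12, 24 h; the series
  carries the across-replicate mean and sample s.d. Displacements come
  out at a few hundred µm over 24 h, the magnitude real assays show.

What these fixtures do *not* emulate: optical texture inside the
monolayer (cell-interior gradients, illumination drift) — the rendered
snapshots are clean binary images, so the Canny stage is only lightly
stressed; uneven scratch edges at t = 0; and any drift or death processes
absent from the model. Passing recovery tests therefore demonstrate the
identifiability logic and the pipeline's internal consistency, not
robustness to microscope artefacts.

## Problem sizes and numerical choices

The assay geometry (Δ, τ, L_y, Y₀, 24 h) is never scaled. The lateral
width L_x only sets Monte-Carlo noise (the dynamics are effectively
one-dimensional in y), and is the one knob used to keep runs desk-sized:

- The recovery experiments keep the *data-generating* realization at the
  full 12.5 mm (500 columns) — the single-realization front noise is what
  limits the step-1 accuracy, and at ≤ 2.5 mm its standard deviation
  (~0.07 in P_m) exceeds the resolution the recovery claims are quoted
  at. The early-window P_m ensembles also run at full width (they only
  simulate the first ~3 h, so they stay cheap); the full-length
  late-window P_p ensembles run at 5 mm (200 columns), M = 10.
- The T-robustness trio reuses the same realization with 21-value grids;
  the naive-scan valley scores a full-width reference against 1.25 mm
  ensembles on a 17×41 grid (the P_p axis kept dense so each row's
  valley-bottom P_p is resolved).
- The in-vitro-like protocol calibrates the 2 mm field-of-view data
  against 5 mm ensembles with 26-value grids, and an 11-value bracketing
  sub-grid for refinement/uncertainty.

Numerical conventions: snapshot times map to the nearest step with ties
to the earlier step; parameter ties at equal E to the smaller value;
probabilities are validated into [0, 1] and rate-to-probability
conversion refuses (D, λ) that would imply a probability above 1 at the
given (Δ, τ). Degenerate inputs fail loudly: a blank image raises a
detection error, an all-zero reference series or an empty comparison
window raises before any simulation is spent.

## Known limitations

- The estimator inherits the trade-off structure of the model: an error
  of one grid spacing in the step-1 P_m propagates into a several-spacing
  error in P_p (the valley's slope), so P_p accuracy is bounded by P_m
  accuracy, exactly as the non-identifiability analysis predicts. This
  bites hardest on the sparse assay schedule: with samples at 0, 3, 6, 9,
  12, 24 h and strict windows, T = 6 h leaves a single early-window
  point, whose field-to-field scatter alone moves P_m by one or two grid
  spacings and hence P_p by several; T = 9 h (two early points) is
  better conditioned.
- Uncertainty ranges from ±1 s.d. displaced series are a sensitivity
  measure, not confidence intervals.
- The lattice model ignores cell-to-cell adhesion, death, nutrient
  limitation and curved well geometry; the continuum correspondence holds
  only for P_p ≪ P_m.
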