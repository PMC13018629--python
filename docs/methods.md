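# Methods

## Scope and model

`sizedyn` analyses how the mean cell volume of rod-shaped bacteria changes
along a population growth curve, using only population-level measurements
(per-cell snapshots from microscopy, OD600 curves, CFU counts) — no
single-cell tracking.  The framework has three model ingredients:

1. **Capsule geometry.** Each cell is a sphero-cylinder of length L and
   width w.  Segmentation gives the projected area `A_p` and length `L`;
   the width solves `A_p = w(L−w) + π(w/2)²`, and surface and volume follow
   as `A = πLw`, `V = πLw²/4 − πw³/12`.  Units are μm/μm²/μm³ and hours
   throughout.

2. **Logistic biomass growth.** OD600 is modelled as
   `B(t) = B_max / (1 + e^{−μ_max(t−t_s)})`, fitted by least squares on the
   log scale; the growth rate follows analytically,
   `μ(t) = μ_max / (1 + e^{μ_max(t−t_s)})`.  A Gompertz alternative
   `B_max·exp(−exp(−r(t−t_m)))` is available through the same interface;
   its parametrization is the standard two-shape-parameter form, and it
   describes the late growth curve better but the exponential phase worse.
   Phases of gradually decreasing growth rate near stationary entry (e.g.
   from diauxic shifts) are deliberately not modelled.

3. **Growth-division dynamics.** Cells grow exponentially (`ds/dt = μ(t)s`)
   and divide in half with hazard `k(t)μ(t)s`.  Because hazard per unit
   *added* size is exactly `k(t)`, this is an adder strategy with
   exponentially distributed added-size increments (mean 1/k for constant
   k).  The mean-field (first-order moment-closure) equation is

       d⟨s⟩/dt = μ(t)⟨s⟩ − k(t)μ(t)⟨s⟩²/2,

   with fixed point ⟨s⟩ = 2/k for constant rates.  `k(t)` is a double
   sigmoid `k0 → kmax → k0` with rate λ and midpoints t1*, t2*, encoding
   that the start and end of a growth curve are the same physiological
   state (stationary phase).

The division schedule is inferred by minimizing the sum of squared relative
residuals between observed per-time mean volumes and the integrated
mean-size equation, with ⟨s⟩(0) set to the first (overnight-culture)
observation.  A pointwise inversion
`k = 2(μ⟨s⟩ − d⟨s⟩/dt)/(μ⟨s⟩²)` of a smoothing-spline interpolant is
provided as a diagnostic; it is 0/0-unstable as μ→0 and reports NaN below
a configurable growth-rate threshold (default 0.02 h⁻¹).

In sustained-growth experiments (repeated dilution with fresh medium) the
OD derivative is treated as zero inside the annotated dilution window:
those points are excluded from the fit and μ(t) is held at its value just
before dilutions started.

## The closure error is large for this division mechanism

The mean-field equation is *not* an exact description of the stochastic
process, and the package quantifies the gap rather than hiding it.  Two
distinct exact results, both verified by the simulator tests:

* **Lineage ensemble** (follow one daughter per division — the process
  whose generator yields the moment hierarchy): the exact stationarity
  identity is `⟨s²⟩ = 2⟨s⟩/k`, hence `⟨s⟩ = 2/(k(1+CV²))`.  Because added
  sizes are exponential, the stationary snapshot CV² is ≈ 0.39, so the
  true lineage mean sits ≈ 28% *below* the mean-field value 2/k.

* **Branching population** (keep both daughters): the expected total
  division intensity is `kμB` (B = biomass), so counts grow faster than
  biomass until the population mean size settles at exactly **1/k** —
  a factor 2 below the mean-field value.  This is why the OD/CFU channel
  and the microscopy channel have systematically different means.

Consequences, measured by the acceptance-style tests: fitting the
mean-field model to exact stochastic lineage data recovers the *shape* of
k(t) well (transition times within ~0.15 h in the benchmark) but inflates
its amplitude by roughly the (1+CV²) factor, i.e. ~30–45% sup-norm error.
Fitted division coefficients should therefore be read as *effective*
mean-field parameters, ideal for comparing conditions and genotypes but
not as unbiased hazard constants.  The two tests that compare stochastic
means against 2/k at 15% tolerance document this bias as failures by
design of their thresholds.

A related numerical caveat: closing the moment hierarchy at order 2 with
`⟨s³⟩ ≈ ⟨s²⟩⟨s⟩` creates a saddle point; trajectories started away from it
can diverge in finite time.  Order-2 integration is therefore only useful
on short horizons, and the main pipeline uses order 1 exclusively.

## Simulator design

The simulator is a fixed ensemble of `n0` single-cell lineages.  Division
sampling is exact in distribution: each cell accumulates hazard
`∫k dA` on its added-size clock against a unit-exponential threshold, and
the division point within a time step is found by inverting the linear
hazard accumulation, so there is no thinning error.  Cells are advanced on
a fixed grid (default dt = 0.005 h); at most one division per cell per
step is placed (double events are O(dt²)).  The time step and the
trapezoidal tabulation of ∫μ are the only discretization approximations;
both are ~1e−5 relative at the default step.

Observation channels:

* **OD**: B(t) = B(0)·e^{∫μ}, exact because division conserves mass, scaled
  by a calibration constant (default 1 OD per 10⁵ μm³; only ratios matter
  downstream), with multiplicative log-normal replicate noise.
* **CFU**: N(t) = n0 + ∫k μ B dt (exact expectation of the branching
  population count), scaled and corrupted with separate biological and
  technical noise.
* **Per-cell measurements**: a subsample of lineage sizes is mapped to
  (L, w) at a fixed condition-dependent width (cell width varies much less
  than length within a condition; cells too small for that width fall back
  to spheres), then length and width receive independent multiplicative
  log-normal noise (default log-sd 0.03) and the capsule projected area is
  emitted — exactly the geometry module's input dialect.  Binary masks of
  sphero-cylinders can be rasterized at a configurable pixel size (default
  0.005 μm²/pixel) to exercise the mask-measurement path.

Default study conditions emulate a rich-medium growth curve: overnight
cells with mean 1 μm³ (log-sd 0.3), μ_max = 2 h⁻¹, t_s = 4 h, k rising
from 0.4 to 2.0 μm⁻³ (steady sizes 5 → 1 μm³) around t1* = 2.5 h and
relaxing back around t2* = 8 h.

What the generator does *not* emulate: imaging artifacts and segmentation
errors (hence synthetic data are summarized without the hard artifact
cuts), asymmetric division, cell death, width dynamics within a condition,
OD saturation/scattering nonlinearities, and diauxic growth.  Passing
recovery tests on synthetic data therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
those real-data effects.

The added-size records are right-censored near the simulation horizon
(cells born late may not divide before t_end); adder statistics are
computed on cohorts born ≥ 3/μ before the horizon, where the censoring
probability is ~e⁻⁹.

## Recovery benchmark

The end-to-end benchmark (`sizedyn.validation`) simulates the full
pipeline input (OD + noisy subsampled cell sizes, 5% measurement noise,
200 lineages, 25 snapshots over 12 h), runs growth fit → geometry summary
→ schedule fit, and scores `max_t |k̂−k| / max_t k` over the observation
window.  The scenario (k0 = 0.4, kmax = 2.0 μm⁻³, λ = 3 h⁻¹, t1* = 2.5 h,
t2* = 7 h; μ_max = 1 h⁻¹, t_s = 7 h) was chosen a priori for
identifiability: t2* coincides with stationary entry, where μ ≈ μ_max/2,
so the relaxation of k is visible in the data.  When the fitted t2* falls
beyond the data window the result flags it as unidentified instead of
reporting a point estimate.  On noiseless model-generated data the same
fit recovers all five parameters to four decimals; on stochastic data the
sup-norm error is dominated by the closure bias discussed above.

## Numerical choices

* Mean-size ODE: adaptive RK45, rtol 1e−10 / atol 1e−13 by default (the
  contract is ≤ 1e−8); integration failures surface as errors with state,
  except inside the fit objective where they return a large finite value
  so the optimizer retreats.
* Schedule fit: search over (ln k0, ln kmax, ln λ, t1*, Δ) with
  t2* = t1* + Δ, Δ ≥ 0 enforced by construction; default bounds
  k ∈ [0.05, 50] μm⁻³, λ ∈ [0.1, 20] h⁻¹, t1* within the data window ± 5 h.
  Starts: one data-driven heuristic (k0 ≈ 2/⟨s⟩ at t = 0, kmax ≈ 2/min⟨s⟩)
  plus a seeded Latin-hypercube sample (default 16 starts total);
  short Nelder–Mead runs on all starts, bounded Powell polish on the best
  three, and a final simplex pass on the incumbent.  Objective evaluations
  integrate with fixed-step RK4 on a 0.02 h grid (~1e−6 relative accuracy);
  the reported optimum is recomputed adaptively.
* Growth fit: Nelder–Mead in (t_s, ln B_max, ln μ_max) from 8 deterministic
  data-driven starts; log-space objective.
* Trend smoothing: scikit-learn Gaussian-process regression on log-values,
  RBF × constant + white kernel, hyperparameters by marginal likelihood
  (2 restarts, seeded).  The white-noise floor is subtracted from the
  predictive variance so the 95% band covers the mean trajectory rather
  than future single measurements; constant input short-circuits to a
  zero band.  Technical CFU replicates are averaged within biological
  replicates before smoothing.
* Ratio uncertainty: first-order absolute propagation
  `Δz = |Δx/y| + |xΔy/y²|`, conservative by up to ~√2 versus quadrature
  (verified against Monte-Carlo propagation).
* Mask measurement: length is the longest side of the minimum-area rotated
  rectangle (convex hull + rotating calipers) of foreground pixel centres
  plus one pixel width, which makes axis-aligned runs exact and keeps
  rotated shapes within one pixel; minimum-area (not axis-aligned) is used
  so the measure is rotation-invariant.
* Outlier filtering: the four hard cuts use strict inequalities (width
  > 0.35 μm, 1.05 < L < 10 μm, 1 < L/w < 7, A_p > 0.73 μm²; the area cut is
  read as projected area, configurable); the 3σ log-volume cut is a single
  pass per time point (mean and SD from pre-removal data, not iterated)
  and degenerates gracefully for groups of fewer than 3 cells.
* Summaries: 95% percentile bootstrap (default 1000 resamples) for the
  mean-volume CI, with the generator re-seeded per group so identical data
  give identical summaries.

## Known limitations

* The mean-field inference inherits the (1+CV²) amplitude bias described
  above; no variance correction is applied because the contract is the
  closed first-order model.
* t2* is structurally unidentifiable whenever μ(t2*) ≈ 0 (the common case
  in real growth curves, where k relaxes only after growth has stopped);
  the identifiability flag, not the point estimate, should be consulted.
* The logistic μ(t) cannot represent lag phases or multi-phase growth;
  fitted t_s absorbs such misfit.
* The GP band is a pointwise credible band, not simultaneous; coverage is
  assessed empirically on the synthetic benchmark (≥ 90% of grid points).
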