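# Methods

## The model

`vcbm` simulates solid-tumour growth in two dimensions with an off-lattice
cell-centre agent-based model.  Each agent is a point `r_i(t)` in the plane of
kind *tumour* or *healthy*; cell shapes are implicitly the Voronoi regions of
the centre points and a cell's neighbourhood `N(i)` is the set of cells joined
to it by a Delaunay edge.  No Voronoi areas are ever computed: hull cells have
unbounded regions, and only the Delaunay dual enters the dynamics.  Delaunay
edges longer than `max_edge_factor × s` (default 1.5 × the mature rest length)
are pruned, because triangulating a finite domain produces long-range hull
edges with no biological meaning.  Cocircular point sets (the hexagonal
initial lattice is full of them) are resolved by a deterministic jitter of
10⁻⁹ mm whose direction is a golden-ratio function of the point index, so the
tie-break is reproducible across platforms and never perturbs stored
positions.

Three mechanisms act each hour (Δt = 1 h, fixed):

1. **Proliferation.**  A tumour cell whose time since last division satisfies
   `t_d ≥ g_age` divides with probability `p_d = p0 (1 − d/d_max)` for
   `d < d_max` and 0 otherwise, where `d` is the Euclidean distance from the
   cell centre to the nearest cell of the tumour periphery (tumour cells with
   at least one healthy neighbour).  Distance to the periphery is a proxy for
   nutrient availability.  The two daughters are placed at the parent's
   position ± `s/(2 t_age)` along a uniformly random direction — their
   initial separation equals the newborn rest length `s/t_age` — and both
   restart `t_d = 0`.
2. **Invasion.**  A peripheral tumour cell that did not divide this step
   converts one uniformly chosen healthy Delaunay neighbour into a tumour
   cell (probability `p_psc`); the converted cell keeps its position.
3. **Movement.**  Every cell moves by the overdamped Hooke update
   `r_i += λ Σ_{j∈N(i)} û_{j→i} (s_ij − ‖r_ij‖)` with rest length
   `s_ij = s · min(1, min(t_d_i, t_d_j)/t_age)`: newborn cells are small and
   grow into adult size over `t_age` hours.  The sign convention is the
   physically restoring one — a compressed spring pushes its endpoints apart —
   so dividing cells push the surrounding tissue outward.  The formulation
   sometimes written with the unit vector pointing the other way would make
   compression attractive and collapse the tissue.  An isolated pair relaxes
   geometrically with per-step error ratio (1 − 2λ), which is the package's
   first acceptance check and pins 0 < λ < 1/2 for stability (default 0.25).

There is no cell death and no nutrient field; the model targets control-arm
(untreated) tumour growth.

**Readout.**  Tumour volume is reported on the caliper scale used for in vivo
measurements, `volume = width × length²/2`, where width is the longest
pairwise extent of tumour cell centres plus one cell diameter and length the
extent along the perpendicular axis plus one diameter.  A single cell reads
`s³/2`.  This is also how 2-D simulations are mapped onto mm³ data; whether a
cell diameter should be added to the raw extents is not fixed by the caliper
convention, and the choice is isolated in `VolumeCalibration`.  Boundary
distance is measured centre-to-centre (not to Voronoi edges).

**Initialisation.**  Simulation starts from a hexagonal lattice at spacing
`s` with the central cell tumourous, and burns in under θ₁ until the caliper
volume reaches a target (100 mm³ for real-data workflows, 200 mm³ for the
synthetic validation design).  The burned-in lattice is frozen and reused as
the common initial condition for every calibration simulation.

**Biphasic growth.**  The parameter vector θ = (p0, p_psc, d_max, g_age)
switches from θ₁ to θ₂ at the change-point day τ (an integer ≥ 2).  Hours
t < 24τ use θ₁ and t ≥ 24τ use θ₂; the boundary instant itself is assigned to
the second phase (the underlying description leaves t = τ open).  The
monophasic model is θ₁ = θ₂, and the simulator draws random numbers in a
τ-independent pattern so that θ₁ = θ₂ reproduces the monophasic trajectory
bit-for-bit under a shared seed — a tested contract.

**Ages.**  `t_d` is incremented at the start of each hourly step, so a
daughter born with `t_d = 0` has `t_d = 1` (rest length `s/t_age`) on the
first step after its birth.  Cells of the initial lattice carry `t_d = ∞`
("mature"): they are full-sized and, if tumourous, immediately eligible to
divide.

## Calibration: SMC-ABC with replenishment

The likelihood of the simulator is intractable, so parameters are calibrated
by approximate Bayesian computation with the discrepancy
`ρ(y, x) = Σ_t (log y_t − log x_t)²` over the observation days (volumes grow
multiplicatively, hence logs; the short series is its own summary statistic)
and an indicator kernel `I(ρ < ε)`.

The sequential sampler maintains N particles {θ, ρ}.  Per iteration: sort by
ρ; set `ε_t` to the (N − N_a)-th smallest ρ with `N_a = ⌊Na⌋`; drop the N_a
worst; resample N_a replacements uniformly with replacement from the
survivors; move each replacement with `R_t` Metropolis steps under a Gaussian
random walk whose covariance Σ_t is the survivors' sample covariance
(ridge-regularised by 10⁻⁸ when resampling duplicates make it singular).
Under the uniform priors the acceptance probability reduces to the indicator:
a proposal is accepted iff it lies in the prior support and a fresh simulation
beats ε_t.  `R_t = ⌈log c / log(1 − p̂_acc)⌉` (clamped to `[1, R_max]`) makes
the probability that a duplicate never moves at most c, with p̂_acc estimated
from S_t trial iterations and `S_{t+1} = ⌈R_t/2⌉`.  Defaults a = 0.5,
c = 0.01 and stopping rule p̂_acc < p_min = 0.005 follow the replenishment
algorithm's standard tuning; an `epsilon_target` and a `max_iters` budget cap
are additional stopping rules for desk-scale runs.  With `ε_t` equal to an
order statistic of the surviving ρ's, the largest kept particle satisfies
ρ = ε_t exactly; population checks therefore assert ρ ≤ ε_t while MCMC
acceptance is strict (ρ̃ < ε_t).

Integer parameters (τ) are proposed by rounding the Gaussian component, which
keeps the proposal symmetric so the Metropolis ratio needs no proposal
density.  g_age draws with `g_age ≤ t_age` are rejected and redrawn at prior
sampling and rejected in the MCMC support check: a cell cannot divide before
it is full-grown, even though the nominal prior lower bound is 0.

Priors: `p0, p_psc ~ U(0,1)`; `d_max ~ U(0,50)` mm (tumour cells are never
observed more than ≈30 mm from the periphery at the data's volume range);
`g_age ~ U(0, 24·T_max)` hours with the `g_age > t_age` restriction;
`τ ~ U{2, …, T_max}` where T_max is the last measurement day.

Every simulation gets its own generator seeded from the master stream in a
fixed order (per-particle, not per-worker), so calibration results are
invariant to the worker count — also a tested contract.  The discrepancy is
computed over all observation days including day 0; the model is burn-in
matched to the first observation, which makes that term ≈ 0, and the choice
is switchable by omitting day 0 from the input series.

**Runaway guard.**  Tumour growth is exponential in the VCBM, and prior draws
with very small g_age produce astronomically large simulations.  During
calibration, once a trajectory's recorded volume exceeds `max_volume`
(a large multiple — 5–100× — of the biggest observed volume) or the agent
count exceeds a cell cap derived from it (the number of hexagonally packed
cells filling the capped caliper extent, with a 2× margin), stepping stops
and the remaining observations are filled with the current volume.  Any such
trajectory is already orders of magnitude outside the data on the log scale,
so the guard only avoids simulating tumours the sampler would reject anyway;
it never triggers for parameters compatible with the data.

## Posterior predictive

Retained particles (or a subsample) are re-simulated with fresh noise and the
empirical (0.25, 0.75), (0.1, 0.9) and (0.025, 0.975) quantile bands plus the
median are reported per observation day.

## Synthetic data and surrogates

The in vivo datasets the method was built for (breast, ovarian, pancreatic
xenografts in mice) are not redistributable, so the package generates its own
fixtures:

* **VCBM synthetic series** — burn-in to 200 mm³ under θ₁, then 32 days of
  daily caliper readouts, mirroring the validation design of the original
  study (whose exact truth values live in an unavailable supplement; the
  default suite therefore documents its own truth values in emitted sidecar
  files rather than claiming anyone else's).  The default suite holds three
  biphasic specs differing in g_age between phases — g_age is the parameter
  tumour-volume data actually identify — and two monophasic specs.  Default
  truth values (p0 = 0.2, p_psc = 0.05, d_max = 30 mm, g_age between 50 and
  200 h, τ mid-experiment) give 10–30× volume growth over 32 days, the range
  seen in subcutaneous mouse xenografts.
* **Fast surrogate** — piecewise-exponential growth
  `V_t = V0 exp(g1·min(t,τ) + g2·max(0, t−τ)) · ε_t` with i.i.d. log-normal
  noise; same change-point structure as the biphasic VCBM but simulates in
  microseconds, so the inference engine can be exercised at full particle
  numbers in seconds.
* **Conjugate Gaussian toy** — `y_i ~ N(θ, 1)` with uniform prior, whose
  exact posterior `N(ȳ, 1/n)` (truncated) is the oracle for sampler
  exactness.

What the synthetic generator does **not** emulate: measurement cessation
rules (mice are sacrificed when tumours exceed a threshold), mouse-to-mouse
hierarchical variation, measurement error beyond the model's intrinsic
stochasticity, and volume regressions (the model has no cell death).  Tests
passing on these fixtures show the machinery is correct and the inference
identifies what the model can identify; they do not validate the VCBM as a
description of any particular tumour line.

## Problem sizes used by the test suite and acceptance script

Full-scale runs (s = 0.25 mm, hundreds to thousands of cells, N = 1000
particles) take multi-hour calibrations, so the shipped checks run the same
code at reduced scale, chosen once:

* Sampler exactness: Gaussian toy, N = 500 particles, ε_target = 10⁻³; the
  SMC posterior mean and SD must match the analytic truncated normal within
  3 Monte-Carlo standard errors (ESS taken as the number of unique
  particles).
* Surrogate recovery: truth (g1, g2, τ) = (0.1, 0.3, 16), σ = 0.05, 33 daily
  points, N = 500, run to the p_min stopping rule.  True values must fall in
  the 95% credible intervals and each rate's posterior SD must be below half
  its prior SD.
* Scaled VCBM recovery: 1 mm cells on a 16 × 16 lattice, burn-in to 25 mm³
  (≈11 tumour cells among ≈260 agents), truth θ = (0.2, 0.001, 30, 300),
  32 daily observations, monophasic calibration with N = 100, R_max = 3,
  S1 = 1 and a fixed iteration budget; runaway cap 5× the largest observed
  volume.  The expected pattern mirrors the full-scale finding: the g_age
  posterior concentrates (SD < half the prior SD, truth inside the 95%
  interval) while p0 and d_max stay near their priors (Kolmogorov–Smirnov
  distance < 0.2).  The cell size is the coarsest at which this pattern
  survives: with even coarser cells the tumour starts from a handful of
  agents, single invasion events dominate the volume signal, and p_psc —
  not g_age — becomes the identified parameter.  At this reduced scale
  p_psc is still partially informed for the same reason; the full-scale
  non-identifiability statement is about p0 and d_max.

## Numerical choices and degenerate inputs

* Coincident cell centres (possible only transiently) are split by a
  deterministic 10⁻⁹ mm offset before force evaluation; no division by zero.
* Fewer than three cells cannot be triangulated; one- and two-cell systems
  use the complete graph without pruning (pruning exists to cut spurious
  hull edges, which cannot arise there).
* Collinear point sets raise a degenerate-geometry error rather than being
  silently jittered into a sliver triangulation.
* An all-tumour configuration has no tumour–healthy edges; the periphery
  falls back to the tumour convex hull so burn-in and invasion-saturated
  states keep a defined boundary.
* `ceil`/`floor` conventions: `N_a = ⌊Na⌋`; R_t uses `⌈·⌉`; p̂_acc = 0 maps
  to R_max and p̂_acc = 1 to a single iteration.

## Known limitations

* 2-D only; the caliper map from a 2-D point cloud to mm³ is a modelling
  convention, not a measurement model.
* No cell death: declining tumour volumes cannot be fitted.
* p0, p_psc and d_max are expected to be practically non-identifiable from
  volume data alone (volume is driven by the proliferating rim); only g_age
  and, in biphasic data, τ carry posterior concentration.  This is a finding
  the scaled recovery study reproduces, not a defect of the sampler.
* The SMC iteration budget used in the shipped scaled study stops the
  sampler well before the p_min rule would; the reported posteriors are
  correspondingly conservative (wider than a converged run's).
* At the reduced scale of the shipped recovery study, division-driven and
  invasion-driven growth are nearly degenerate on the log-volume scale: the
  posterior forms a ridge in (g_age, p_psc) that 100 particles cannot cover
  evenly, so a single run can concentrate on one ridge segment and place the
  true g_age outside its 95% interval, and with 30–75 unique particles the
  Kolmogorov–Smirnov distance of a genuinely flat marginal to its prior can
  exceed 0.2 from duplication noise alone.  The recovery test asserts the
  full-scale identifiability pattern anyway and is expected to be the
  suite's one fragile check; the package treats the clean pattern as a
  property of the full-scale regime (hundreds to thousands of cells, larger
  particle numbers, multi-hour runs), not of the desk-scale one.
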