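# vcbm — Voronoi cell-based tumour growth model with SMC-ABC calibration

`vcbm` simulates monophasic and biphasic solid-tumour growth with a 2-D
off-lattice agent-based model and calibrates it to tumour-volume time series
by likelihood-free Bayesian inference.  It is aimed at modellers working with
in vivo caliper measurements (mouse xenograft studies) who want posterior
distributions — not point fits — for the cell-level parameters driving the
growth curve.

## The model in brief

Cells are centre points `r_i ∈ ℝ²` of kind tumour or healthy; neighbourhoods
are Delaunay edges (cell shapes are the dual Voronoi regions, never computed
explicitly).  Every hour:

* a tumour cell at distance `d` from the tumour periphery divides with
  probability `p_d = p0 (1 − d/d_max)` for `d < d_max`, provided at least
  `g_age` hours have passed since its last division;
* a peripheral tumour cell that did not divide converts a healthy neighbour
  with probability `p_psc`;
* all cells move by the overdamped spring update
  `r_i ← r_i + λ Σ_{j∈N(i)} û_{j→i}(s_ij − ‖r_ij‖)`, with rest lengths that
  mature from `s/t_age` to `s` as newborn cells grow.

Tumour volume is read out on the caliper scale, `width × length²/2` (mm³).
A biphasic variant switches the behavioural parameters
θ = (p0, p_psc, d_max, g_age) from θ₁ to θ₂ at a change-point day τ.

Calibration uses the SMC-ABC replenishment sampler: N parameter particles are
filtered through a shrinking tolerance `ε_t` on the discrepancy
`ρ(y, x) = Σ_t (log y_t − log x_t)²`, with dropped particles replenished by
resampling and diversified by `R_t = ⌈log c / log(1 − p̂_acc)⌉` Metropolis
moves (uniform priors reduce acceptance to "in support and ρ̃ < ε_t").
Posterior-predictive quantile bands are produced from the retained particles.

## Worked example

Calibrate the fast biphasic surrogate (a piecewise-exponential growth model
with the same change-point structure as the full simulator) on data it
generated, then inspect the posterior:

```python
import numpy as np
import vcbm

days = np.arange(0.0, 33.0)
rng = np.random.default_rng(31)
y = vcbm.surrogate_biphasic((0.1, 0.3, 16, 0.05), days, 200.0, rng)

model = vcbm.surrogate_model(days, v0=200.0, sigma=0.05)
prior = vcbm.surrogate_prior(t_max_days=32)
cfg = vcbm.SMCConfig(N=500)
particles, trace = vcbm.smc_abc(model, prior, y, cfg, rng)

for k, name in enumerate(prior.names):
    lo, hi = np.quantile(particles.thetas[:, k], [0.025, 0.975])
    print(f"{name}: mean {particles.thetas[:, k].mean():.3f} "
          f"95% CI ({lo:.3f}, {hi:.3f})")
print(f"final tolerance {trace.epsilon[-1]:.3f} "
      f"after {trace.n_simulations} simulations")
```

Output:

```
g1: mean 0.100 95% CI (0.097, 0.103)
g2: mean 0.298 95% CI (0.291, 0.302)
tau: mean 16.000 95% CI (16.000, 16.000)
final tolerance 0.073 after 238808 simulations
```

The true growth rates (0.1 and 0.3 per day) and change-point (day 16) sit
inside tight 95% credible intervals; the final tolerance is at the scale of
the measurement noise (σ = 0.05 on the log volumes).

The full simulator plugs into the same machinery:

```python
mech = vcbm.MechanicsConfig(s=2.0)              # coarse cells for a quick run
calib = vcbm.VolumeCalibration(cell_diameter=2.0)
truth = vcbm.PhaseParams(p0=0.2, p_psc=0.001, d_max=30.0, g_age=300.0)
spec = vcbm.SyntheticSpec(params=truth, horizon_days=32,
                          initial_volume=25.0, seed=42)
res = vcbm.make_vcbm_synthetic(spec, mech, calib, lattice_shape=(12, 12))
model = vcbm.make_model(res.series.days, res.initial_state, mech, calib,
                        "monophasic", max_volume=5 * res.series.volumes.max())
```

## Command line

A thin CLI wraps the library for shell pipelines (`vcbm --help`):

```sh
vcbm synth     --out data/      --seed 1                  # synthetic suite + truth sidecars
vcbm simulate  --out run/       --seed 1 --set p0=0.3     # one series from given parameters
vcbm calibrate --series data/monophasic_1.csv --out fit/ --seed 1
vcbm predict   --series data/monophasic_1.csv --particles fit/particles.csv --out bands/
```

All inputs and outputs are plain delimited text (`day,volume_mm3` series,
particle tables, traces, quantile bands); configuration is a flat
`key = value` file overridable with `--set`, and every run writes its full
configuration to a log so results are auditable.

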