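"""Synthetic tumour-volume data and fast surrogate models.

The in vivo mouse datasets the method was designed for are not distributable,
so every workflow here is exercised end-to-end on synthetic data:

* :func:`make_vcbm_synthetic` generates ground-truth VCBM series — burn-in to
  a starting volume, then daily caliper readouts over a fixed horizon — with a
  documented truth record, for parameter-recovery studies;
* :func:`surrogate_biphasic` is a piecewise-exponential growth model with
  log-normal measurement noise, a stand-in with the same change-point
  structure that simulates in microseconds, used to exercise the SMC-ABC
  engine at scale;
* :func:`gaussian_toy` is a conjugate normal model whose exact posterior is
  known, used as an exactness oracle for the sampler.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .simulator import (
    BiphasicParams,
    MechanicsConfig,
    PhaseParams,
    TissueState,
    TumourSeries,
    VolumeCalibration,
    burn_in,
    init_tissue,
    simulate,
)
from .smc_abc import Prior

DEFAULT_HORIZON_DAYS = 32
DEFAULT_INITIAL_VOLUME = 200.0  # mm^3


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic VCBM dataset.

    Defaults mirror the validation design: 32 days of daily observations
    starting from a tumour grown to 200 mm³.
    """

    params: PhaseParams | BiphasicParams
    horizon_days: int = DEFAULT_HORIZON_DAYS
    cadence_days: float = 1.0
    initial_volume: float = DEFAULT_INITIAL_VOLUME
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.horizon_days < 2:
            raise ValueError("horizon must be at least 2 days")
        if self.initial_volume <= 0:
            raise ValueError("initial volume must be positive")
        if self.cadence_days <= 0:
            raise ValueError("cadence must be positive")

    def obs_days(self) -> np.ndarray:
        return np.arange(0.0, self.horizon_days + 1e-9, self.cadence_days)


@dataclass
class SyntheticResult:
    """A generated series, its truth record, and the frozen burn-in lattice."""

    series: TumourSeries
    truth: dict
    initial_state: TissueState


def _theta1(params: PhaseParams | BiphasicParams) -> PhaseParams:
    return params.theta1 if isinstance(params, BiphasicParams) else params


def _truth_record(spec: SyntheticSpec, mech: MechanicsConfig) -> dict:
    p = spec.params
    rec: dict = {"name": spec.name, "seed": spec.seed,
                 "horizon_days": spec.horizon_days,
                 "initial_volume_mm3": spec.initial_volume,
                 "s_mm": mech.s, "t_age_h": mech.t_age, "lambda": mech.lam}
    if isinstance(p, BiphasicParams):
        rec["model"] = "biphasic"
        for tag, ph in (("1", p.theta1), ("2", p.theta2)):
            for k, v in asdict(ph).items():
                rec[f"{k}_{tag}"] = v
        rec["tau_days"] = p.tau
    else:
        rec["model"] = "monophasic"
        rec.update(asdict(p))
    return rec


def default_lattice_shape(
    spec: SyntheticSpec, mech: MechanicsConfig, margin: float = 2.5
) -> tuple[int, int]:
    """Square hexagonal-lattice shape large enough to host the grown tumour.

    Sized from the caliper extent implied by the initial volume
    (V = extent³/2 for a round tumour) with a multiplicative healthy-tissue
    margin to leave room for growth over the horizon.
    """
    extent = (2.0 * spec.initial_volume) ** (1.0 / 3.0)
    n = max(int(math.ceil(margin * extent / mech.s)), 15)
    return n, n


def make_vcbm_synthetic(
    spec: SyntheticSpec,
    mech: MechanicsConfig,
    calib: VolumeCalibration,
    lattice_shape: tuple[int, int] | None = None,
    max_burn_steps: int = 100_000,
) -> SyntheticResult:
    """Generate one ground-truth VCBM series.

    Burn-in runs under θ₁ until the caliper volume reaches the spec's initial
    volume; the frozen lattice is then simulated to the horizon with daily
    readouts.  Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    if lattice_shape is None:
        lattice_shape = default_lattice_shape(spec, mech)
    state = init_tissue(*lattice_shape, mech)
    state = burn_in(
        state, _theta1(spec.params), mech, calib, spec.initial_volume, rng,
        max_steps=max_burn_steps,
    )
    frozen = state.copy()
    series = simulate(spec.params, spec.obs_days(), frozen, mech, calib, rng)
    return SyntheticResult(
        series=series, truth=_truth_record(spec, mech), initial_state=frozen
    )


def default_suite(seed: int = 20240101) -> list[SyntheticSpec]:
    """The standard validation suite: 3 biphasic + 2 monophasic specs.

    The biphasic specs differ in g_age between the two phases (the parameter
    the data actually identify); all truth values are this package's own and
    are written into the emitted sidecar files.
    """
    base = dict(p0=0.2, p_psc=0.05, d_max=30.0)
    bi = [
        (150.0, 50.0, 16),
        (200.0, 75.0, 14),
        (120.0, 60.0, 18),
    ]
    specs: list[SyntheticSpec] = []
    for k, (g1, g2, tau) in enumerate(bi):
        params = BiphasicParams(
            theta1=PhaseParams(g_age=g1, **base),
            theta2=PhaseParams(g_age=g2, **base),
            tau=tau,
        )
        specs.append(
            SyntheticSpec(params=params, seed=seed + k, name=f"biphasic_{k + 1}")
        )
    for k, g in enumerate((100.0, 150.0)):
        specs.append(
            SyntheticSpec(
                params=PhaseParams(g_age=g, **base),
                seed=seed + 10 + k,
                name=f"monophasic_{k + 1}",
            )
        )
    return specs


# ---------------------------------------------------------------------------
# fast surrogate: piecewise-exponential biphasic growth
# ---------------------------------------------------------------------------


def surrogate_biphasic(
    theta: np.ndarray,
    days: np.ndarray,
    v0: float,
    rng: np.random.Generator,
) -> TumourSeries:
    """Piecewise-exponential biphasic growth with log-normal noise.

    θ = (g1, g2, τ, σ):  V_t = V0 · exp(g1·min(t, τ) + g2·max(0, t − τ)) · ε_t
    with ε_t i.i.d. log-normal(0, σ²).  Strictly positive; exact closed form
    at σ = 0.
    """
    g1, g2, tau, sigma = (float(v) for v in theta)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if v0 <= 0:
        raise ValueError("V0 must be positive")
    t = np.asarray(days, dtype=float)
    log_v = np.log(v0) + g1 * np.minimum(t, tau) + g2 * np.maximum(0.0, t - tau)
    if sigma > 0:
        log_v = log_v + sigma * rng.standard_normal(len(t))
    return TumourSeries(days=t, volumes=np.exp(log_v))


def surrogate_model(days: np.ndarray, v0: float, sigma: float):
    """Closure mapping θ = (g1, g2, τ) to a noisy surrogate series (σ fixed)."""

    days = np.asarray(days, dtype=float)

    def model(theta: np.ndarray, rng: np.random.Generator) -> TumourSeries:
        g1, g2, tau = (float(v) for v in theta)
        return surrogate_biphasic((g1, g2, tau, sigma), days, v0, rng)

    return model


def surrogate_prior(t_max_days: float, g_max: float = 1.0) -> Prior:
    """Vague priors for the surrogate: g1, g2 ~ U(0, g_max); τ ~ U{2,…,T_max}."""
    return Prior(
        names=("g1", "g2", "tau"),
        lows=np.array([0.0, 0.0, 2.0]),
        highs=np.array([g_max, g_max, float(t_max_days)]),
        integer=np.array([False, False, True]),
    )


# ---------------------------------------------------------------------------
# conjugate Gaussian toy: exactness oracle for the sampler
# ---------------------------------------------------------------------------


def gaussian_toy(theta: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. Normal(θ, 1) draws."""
    if n < 2:
        raise ValueError("n must be at least 2")
    return theta + rng.standard_normal(n)


def analytic_posterior(
    y: np.ndarray, lo: float, hi: float
) -> tuple[float, float]:
    """Exact posterior (mean, sd) for θ ~ U(lo, hi), y_i ~ N(θ, 1).

    The posterior is Normal(ȳ, 1/n) truncated to the prior interval.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    mu, scale = float(y.mean()), 1.0 / math.sqrt(n)
    a, b = (lo - mu) / scale, (hi - mu) / scale
    dist = stats.truncnorm(a, b, loc=mu, scale=scale)
    return float(dist.mean()), float(dist.std())
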