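"""Likelihood-free calibration by SMC-ABC with particle replenishment.

The sampler targets the ABC posterior P(θ|y) ∝ P(θ) ∫ I(ρ(y,x) < ε) P(x|θ) dx
through a sequence of shrinking tolerances.  Each iteration sorts the N
particles by discrepancy, sets the next tolerance to the (N − N_a)-th order
statistic with N_a = ⌊Na⌋, drops the N_a worst particles, replenishes by
resampling uniformly with replacement from the survivors, and diversifies the
duplicates with R_t iterations of an MCMC kernel whose Gaussian random-walk
covariance Σ_t is tuned from the surviving particles.  R_t is chosen
adaptively as ⌈log c / log(1 − p̂_acc)⌉ so each duplicate moves at least once
with probability 1 − c, with p̂_acc estimated from S_t trial iterations.
The run stops when the overall MCMC acceptance rate falls below p_min, when a
target tolerance is reached, or at an iteration cap.

Under the uniform priors used here, the Metropolis–Hastings ratio reduces to
the prior support indicator times I(ρ(y, x̃) < ε_t): a proposal is accepted
exactly when it is in support and its fresh simulation beats the tolerance.

Particle simulations are independent: every simulation gets its own generator
seeded from the master stream in a fixed order, so results are invariant to
the number of workers executing them.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class SMCError(RuntimeError):
    """Raised when the sampler cannot proceed (e.g. too many model failures)."""


# ---------------------------------------------------------------------------
# discrepancy
# ---------------------------------------------------------------------------


def discrepancy(y, x) -> float:
    """ρ(y, x) = Σ_t (log y_t − log x_t)²  over matched observation days.

    The raw series are their own summary statistics (tumour series are short);
    logs are compared because volumes grow quickly.
    """
    yv = np.asarray(getattr(y, "volumes", y), dtype=float)
    xv = np.asarray(getattr(x, "volumes", x), dtype=float)
    ydays = getattr(y, "days", None)
    xdays = getattr(x, "days", None)
    if ydays is not None and xdays is not None and not np.array_equal(ydays, xdays):
        raise ValueError("observed and simulated series are on different days")
    if yv.shape != xv.shape:
        raise ValueError("series length mismatch")
    if np.any(yv <= 0) or np.any(xv <= 0):
        raise ValueError("volumes must be positive to take logs")
    r = np.log(yv) - np.log(xv)
    return float(r @ r)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Prior:
    """Independent uniform priors, with optional integrality and open lower bounds.

    ``integer`` marks components drawn (and proposed) on the integers of
    [low, high].  ``min_exclusive`` imposes a strict lower support restriction
    on top of the box (used for g_age > t_age); draws violating it are
    rejected and redrawn.
    """

    names: tuple[str, ...]
    lows: np.ndarray
    highs: np.ndarray
    integer: np.ndarray
    min_exclusive: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lows", np.asarray(self.lows, dtype=float))
        object.__setattr__(self, "highs", np.asarray(self.highs, dtype=float))
        object.__setattr__(self, "integer", np.asarray(self.integer, dtype=bool))
        me = self.min_exclusive
        if me is None:
            me = np.full(len(self.lows), -np.inf)
        object.__setattr__(self, "min_exclusive", np.asarray(me, dtype=float))
        if not np.all(self.lows < self.highs):
            raise ValueError("each prior lower bound must be below its upper bound")
        if not np.all(np.maximum(self.lows, self.min_exclusive) < self.highs):
            raise ValueError(
                "a support restriction leaves an empty prior (is the series "
                "long enough that 24*T_max exceeds t_age?)"
            )

    @property
    def dim(self) -> int:
        return len(self.lows)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.empty(self.dim)
        for k in range(self.dim):
            while True:
                if self.integer[k]:
                    v = float(rng.integers(int(self.lows[k]), int(self.highs[k]) + 1))
                else:
                    v = rng.uniform(self.lows[k], self.highs[k])
                if v > self.min_exclusive[k]:
                    theta[k] = v
                    break
        return theta

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        if np.any(theta < self.lows) or np.any(theta > self.highs):
            return False
        if np.any(theta <= self.min_exclusive):
            return False
        if np.any(self.integer & (np.rint(theta) != theta)):
            return False
        return True

    def sd(self) -> np.ndarray:
        """Prior standard deviations on the effective (restricted) support."""
        lo = np.maximum(self.lows, self.min_exclusive)
        out = (self.highs - lo) / math.sqrt(12.0)
        disc = self.integer
        if np.any(disc):
            width = self.highs[disc] - np.maximum(
                self.lows[disc], self.min_exclusive[disc]
            )
            n = width + 1
            out[disc] = np.sqrt((n * n - 1.0) / 12.0)
        return out


def sample_prior(prior: Prior, rng: np.random.Generator) -> np.ndarray:
    return prior.sample(rng)


def prior_density_ratio(prior: Prior, theta_new, theta_old) -> float:
    """P(θ_new)/P(θ_old) for uniform priors: 1 inside support, 0 outside."""
    return 1.0 if prior.contains(np.asarray(theta_new)) else 0.0


def monophasic_prior(t_max_days: float, t_age: float = 24.0) -> Prior:
    """Vague priors for θ = (p0, p_psc, d_max, g_age).

    p0, p_psc ~ U(0,1); d_max ~ U(0,50) mm; g_age ~ U(0, 24·T_max) h with the
    structural restriction g_age > t_age applied on top.
    """
    return Prior(
        names=("p0", "p_psc", "d_max", "g_age"),
        lows=np.array([0.0, 0.0, 0.0, 0.0]),
        highs=np.array([1.0, 1.0, 50.0, 24.0 * t_max_days]),
        integer=np.array([False, False, False, False]),
        min_exclusive=np.array([-np.inf, -np.inf, 0.0, t_age]),
    )


def biphasic_prior(t_max_days: float, t_age: float = 24.0) -> Prior:
    """Priors for (θ₁, θ₂, τ): two phase blocks plus integer τ ~ U{2,…,T_max}."""
    m = monophasic_prior(t_max_days, t_age)
    return Prior(
        names=tuple(f"{n}_1" for n in m.names)
        + tuple(f"{n}_2" for n in m.names)
        + ("tau",),
        lows=np.concatenate([m.lows, m.lows, [2.0]]),
        highs=np.concatenate([m.highs, m.highs, [float(t_max_days)]]),
        integer=np.concatenate([m.integer, m.integer, [True]]),
        min_exclusive=np.concatenate([m.min_exclusive, m.min_exclusive, [-np.inf]]),
    )


# ---------------------------------------------------------------------------
# configuration, particles, trace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SMCConfig:
    """Tuning constants of the replenishment sampler.

    a is the fraction of particles dropped per iteration, c the admissible
    probability that a resampled particle is never moved, p_min the
    acceptance-rate stopping threshold.  ``max_iters`` is an optional hard
    budget cap on SMC iterations.
    """

    N: int
    a: float = 0.5
    c: float = 0.01
    p_min: float = 0.005
    epsilon_target: float | None = None
    R_max: int = 100
    S1: int = 5
    max_iters: int | None = None
    n_workers: int = 1
    failure_budget: int = 1000

    def __post_init__(self) -> None:
        if self.N < 20:
            raise ValueError("N must be at least 20")
        if not 0 < self.a < 1:
            raise ValueError("a must lie in (0, 1)")
        if not 0 < self.c < 1:
            raise ValueError("c must lie in (0, 1)")
        if self.R_max < 1 or self.S1 < 1:
            raise ValueError("R_max and S1 must be positive")


@dataclass
class ParticleSet:
    """N particles {θ, ρ}, kept sorted ascending by discrepancy ρ."""

    thetas: np.ndarray  # (N, d)
    rhos: np.ndarray  # (N,)

    def sort(self) -> None:
        order = np.argsort(self.rhos, kind="stable")
        self.thetas = self.thetas[order]
        self.rhos = self.rhos[order]

    @property
    def n(self) -> int:
        return len(self.rhos)

    def n_unique(self) -> int:
        return len(np.unique(self.thetas, axis=0))


@dataclass
class SMCTrace:
    """Per-iteration diagnostics of one SMC-ABC run."""

    epsilon_init: float = float("nan")  # ε₁, the largest initial discrepancy
    epsilon: list[float] = field(default_factory=list)
    p_acc: list[float] = field(default_factory=list)
    p_trial: list[float] = field(default_factory=list)
    R: list[int] = field(default_factory=list)
    S: list[int] = field(default_factory=list)
    sigma_cond: list[float] = field(default_factory=list)
    n_unique: list[int] = field(default_factory=list)
    n_simulations: int = 0
    n_failures: int = 0
    stopped_by: str = ""


# ---------------------------------------------------------------------------
# MCMC move kernel
# ---------------------------------------------------------------------------


def compute_num_mcmc_iters(c: float, p_acc_hat: float, R_max: int) -> int:
    """R_t = ⌈log c / log(1 − p̂_acc)⌉ clamped to [1, R_max]."""
    if not 0.0 <= p_acc_hat <= 1.0:
        raise ValueError("p_acc_hat must lie in [0, 1]")
    if p_acc_hat <= 0.0:
        return R_max
    if p_acc_hat >= 1.0:
        return 1
    r = math.ceil(math.log(c) / math.log(1.0 - p_acc_hat))
    return int(min(max(r, 1), R_max))


def _propose(theta, chol, prior: Prior, rng) -> np.ndarray:
    step = chol @ rng.standard_normal(len(theta))
    prop = theta + step
    prop[prior.integer] = np.rint(prop[prior.integer])
    return prop


def mcmc_move(
    theta: np.ndarray,
    rho: float,
    epsilon: float,
    chol_sigma: np.ndarray,
    prior: Prior,
    model,
    y,
    rng: np.random.Generator,
    distance=discrepancy,
) -> tuple[np.ndarray, float, bool, int, int]:
    """One Metropolis move of a particle under the ABC indicator kernel.

    Proposes θ̃ ~ N(θ, Σ_t) (integer components rounded, preserving proposal
    symmetry); rejects without simulating when θ̃ leaves the prior support;
    otherwise simulates x̃ ~ P(·|θ̃) and accepts iff ρ(y, x̃) < ε_t.  Returns
    (θ, ρ, accepted, n_sims, n_failures); a simulation failure rejects the
    proposal and is logged.
    """
    prop = _propose(theta, chol_sigma, prior, rng)
    if not prior.contains(prop):
        return theta, rho, False, 0, 0
    try:
        x = model(prop, rng)
    except Exception as exc:  # model failure: reject, count
        logger.warning("model simulation failed at theta=%s: %s", prop, exc)
        return theta, rho, False, 1, 1
    rho_new = distance(y, x)
    if rho_new < epsilon:
        return prop, rho_new, True, 1, 0
    return theta, rho, False, 1, 0


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def _tuned_cholesky(thetas: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor of the kept-particle sample covariance, ridge-regularised
    (duplicated particles after resampling can make it near-singular)."""
    sigma = np.atleast_2d(np.cov(thetas, rowvar=False))
    d = sigma.shape[0]
    ridge = 1e-8
    for _ in range(12):
        try:
            chol = np.linalg.cholesky(sigma + ridge * np.eye(d))
            cond = float(np.linalg.cond(sigma + ridge * np.eye(d)))
            return chol, cond
        except np.linalg.LinAlgError:
            ridge *= 10.0
    raise SMCError("particle covariance is irreparably singular")


def _parallel_map(fn, tasks, n_workers: int):
    if n_workers <= 1:
        return [fn(t) for t in tasks]
    with ThreadPoolExecutor(max_workers=n_workers) as ex:
        return list(ex.map(fn, tasks))


def smc_abc(
    model,
    prior: Prior,
    y,
    config: SMCConfig,
    rng: np.random.Generator,
    distance=discrepancy,
) -> tuple[ParticleSet, SMCTrace]:
    """Run the SMC-ABC replenishment sampler.

    ``model(theta, rng)`` must simulate a dataset comparable to ``y`` under
    ``distance``.  Returns the final particle set (sorted by ρ) and the trace.
    Every simulation draws from its own generator seeded from the master
    ``rng`` in a fixed order, so results do not depend on ``n_workers``.
    """
    trace = SMCTrace()
    N = config.N
    n_a = int(math.floor(N * config.a))
    if n_a < 1 or N - n_a < prior.dim + 2:
        raise SMCError("N too small for the drop fraction and covariance tuning")

    def child_rngs(k: int) -> list[np.random.Generator]:
        seeds = rng.integers(0, 2**63 - 1, size=k, dtype=np.int64)
        return [np.random.default_rng(int(s)) for s in seeds]

    # --- initialisation: N prior draws with simulated discrepancies
    thetas = np.array([prior.sample(rng) for _ in range(N)])
    init_rngs = child_rngs(N)

    def _init_one(i: int) -> float:
        try:
            x = model(thetas[i], init_rngs[i])
        except Exception as exc:  # failed draw: infinite discrepancy, budgeted
            logger.warning("initial simulation failed at theta=%s: %s",
                           thetas[i], exc)
            return np.inf
        return distance(y, x)

    rhos = np.array(_parallel_map(_init_one, range(N), config.n_workers))
    trace.n_simulations += N
    trace.n_failures += int(np.sum(np.isinf(rhos)))
    if trace.n_failures > config.failure_budget:
        raise SMCError(
            f"{trace.n_failures} model failures during initialisation exceed "
            f"the budget ({config.failure_budget})"
        )
    particles = ParticleSet(thetas=thetas, rhos=rhos)
    particles.sort()
    epsilon = float(particles.rhos[-1])  # ε₁ = largest initial discrepancy
    trace.epsilon_init = epsilon
    logger.info("SMC-ABC init: N=%d, eps_1=%.6g", N, epsilon)

    s_t = config.S1
    iteration = 1
    while True:
        iteration += 1
        if config.max_iters is not None and iteration - 1 > config.max_iters:
            trace.stopped_by = "max_iters"
            break

        particles.sort()
        epsilon = float(particles.rhos[N - n_a - 1])  # (N−N_a)-th smallest
        kept_thetas = particles.thetas[: N - n_a]
        kept_rhos = particles.rhos[: N - n_a]
        chol, cond = _tuned_cholesky(kept_thetas)

        resample_idx = rng.integers(0, N - n_a, size=n_a)
        move_thetas = kept_thetas[resample_idx].copy()
        move_rhos = kept_rhos[resample_idx].copy()
        move_rngs = child_rngs(n_a)

        accepts = np.zeros(n_a, dtype=np.int64)
        sims = np.zeros(n_a, dtype=np.int64)
        fails = np.zeros(n_a, dtype=np.int64)

        def _run_iters(j: int, k: int) -> None:
            th, rh = move_thetas[j], move_rhos[j]
            for _ in range(k):
                th, rh, acc, ns, nf = mcmc_move(
                    th, rh, epsilon, chol, prior, model, y, move_rngs[j], distance
                )
                accepts[j] += acc
                sims[j] += ns
                fails[j] += nf
            move_thetas[j], move_rhos[j] = th, rh

        # trial phase: S_t iterations per resampled particle
        _parallel_map(lambda j: _run_iters(j, s_t), range(n_a), config.n_workers)
        p_trial = float(accepts.sum()) / (s_t * n_a)
        r_t = compute_num_mcmc_iters(config.c, p_trial, config.R_max)
        extra = max(r_t - s_t, 0)
        if extra > 0:
            _parallel_map(
                lambda j: _run_iters(j, extra), range(n_a), config.n_workers
            )
        total_iters = max(r_t, s_t)
        p_acc_hat = float(accepts.sum()) / (total_iters * n_a)

        trace.n_simulations += int(sims.sum())
        trace.n_failures += int(fails.sum())
        if trace.n_failures > config.failure_budget:
            raise SMCError(
                f"{trace.n_failures} model failures exceed the budget "
                f"({config.failure_budget})"
            )

        particles.thetas = np.vstack([kept_thetas, move_thetas])
        particles.rhos = np.concatenate([kept_rhos, move_rhos])
        particles.sort()

        trace.epsilon.append(epsilon)
        trace.p_acc.append(p_acc_hat)
        trace.p_trial.append(p_trial)
        trace.R.append(r_t)
        trace.S.append(s_t)
        trace.sigma_cond.append(cond)
        trace.n_unique.append(particles.n_unique())
        logger.info(
            "SMC-ABC iter %d: eps=%.6g p_acc=%.4f R=%d unique=%d sims=%d",
            iteration - 1, epsilon, p_acc_hat, r_t,
            trace.n_unique[-1], trace.n_simulations,
        )

        s_t = max(int(math.ceil(r_t / 2)), 1)
        if p_acc_hat < config.p_min:
            trace.stopped_by = "p_min"
            break
        if config.epsilon_target is not None and epsilon <= config.epsilon_target:
            trace.stopped_by = "epsilon_target"
            break
    particles.sort()
    return particles, trace


# ---------------------------------------------------------------------------
# posterior predictive
# ---------------------------------------------------------------------------

DEFAULT_QUANTILE_PAIRS = ((0.25, 0.75), (0.1, 0.9), (0.025, 0.975))


@dataclass
class PredictiveBands:
    """Empirical posterior-predictive quantile bands per observation day."""

    days: np.ndarray
    levels: np.ndarray  # sorted quantile levels, includes 0.5
    quantiles: np.ndarray  # (len(levels), len(days))

    def band(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        i = int(np.argmin(np.abs(self.levels - lo)))
        j = int(np.argmin(np.abs(self.levels - hi)))
        return self.quantiles[i], self.quantiles[j]


def posterior_predictive(
    particles: ParticleSet,
    model,
    obs_days: np.ndarray,
    rng: np.random.Generator,
    quantile_pairs=DEFAULT_QUANTILE_PAIRS,
    draws_per_particle: int = 1,
    max_particles: int | None = None,
) -> PredictiveBands:
    """Simulate fresh series from retained particles and summarise as bands.

    Each retained θ (or a random subsample of ``max_particles`` of them) is
    simulated ``draws_per_particle`` times; the bands are empirical quantiles
    of the simulated volumes at each observation day, at the requested pairs
    plus the median.
    """
    if particles.n == 0:
        raise ValueError("particle set is empty")
    obs_days = np.asarray(obs_days, dtype=float)
    thetas = particles.thetas
    if max_particles is not None and particles.n > max_particles:
        pick = rng.choice(particles.n, size=max_particles, replace=False)
        thetas = thetas[pick]
    levels = np.array(sorted({q for pair in quantile_pairs for q in pair} | {0.5}))

    sims = []
    for theta in thetas:
        for _ in range(draws_per_particle):
            x = model(theta, rng)
            sims.append(np.asarray(getattr(x, "volumes", x), dtype=float))
    mat = np.array(sims)  # (n_sims, T)
    if mat.shape[1] != len(obs_days):
        raise ValueError("model output length does not match obs_days")
    q = np.quantile(mat, levels, axis=0)
    return PredictiveBands(days=obs_days, levels=levels, quantiles=q)
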