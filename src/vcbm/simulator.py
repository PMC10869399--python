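"""The 2-D off-lattice Voronoi cell-based model (VCBM) of tumour growth.

Agents are cell centre points of kind tumour or healthy, connected by the
Delaunay adjacency of the point set.  Three mechanisms drive the dynamics,
applied in this order every one-hour step:

1. proliferation — a tumour cell that has waited at least ``g_age`` hours
   since its last division divides with probability p_d = p0 (1 - d/d_max),
   where d is its distance to the tumour periphery (a proxy for nutrient);
2. invasion — a peripheral tumour cell that did not divide this step converts
   one adjacent healthy cell into a tumour cell with probability p_psc;
3. movement — every cell is displaced by overdamped Hooke spring forces from
   its Delaunay neighbours, with growing daughter cells carrying a rest
   length that matures linearly from s/t_age to s over t_age hours.

There is no cell death: healthy cells are pushed outward by the multiplying
tumour.  Tumour volume is read out on the caliper scale used for in vivo
measurements, volume = width × length² / 2 (width the longest extent, length
the perpendicular extent, both in mm), so 2-D simulations are compared with
mm³ data directly.

A biphasic variant switches the whole behavioural parameter vector θ from θ₁
to θ₂ at a change-point day τ; the monophasic model is the special case
θ₁ = θ₂, and the random-number consumption is independent of τ so that the
two coincide bit-for-bit under a shared seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .geometry import (
    HEALTHY,
    TUMOUR,
    Adjacency,
    PointConfiguration,
    _delaunay_adjacency,
    boundary_distances,
    build_adjacency,
    find_boundary,
)

#: sentinel age (hours since last division) for cells that never divided
MATURE = np.inf


class SimulationError(RuntimeError):
    """Raised for invalid model states or non-converging burn-in."""


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MechanicsConfig:
    """Mechanical constants of the overdamped spring model.

    Parameters
    ----------
    s : float
        Mature rest spring length (mm); also the nominal cell diameter.
    t_age : float
        Hours for a daughter cell's rest length to mature to ``s``.
    lam : float
        Dimensionless mobility per step (the factor multiplying the spring
        sum in the position update; absorbs dt/damping).  Must lie in
        (0, 0.5) for pairwise stability — an isolated pair relaxes with
        per-step error ratio (1 - 2 lam).
    dt : float
        Step size in hours; the model is defined at dt = 1.
    max_edge_factor : float
        Delaunay edges longer than ``max_edge_factor * s`` are pruned.
    """

    s: float = 0.25
    t_age: float = 24.0
    lam: float = 0.25
    dt: float = 1.0
    max_edge_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.t_age < 1:
            raise ValueError("t_age must be >= 1 hour")
        if not 0 < self.lam < 0.5:
            raise ValueError("lam must lie in (0, 0.5) for pairwise stability")
        if self.dt != 1.0:
            raise ValueError("the model is defined at dt = 1 hour")


@dataclass(frozen=True)
class PhaseParams:
    """Behavioural parameters θ = (p0, p_psc, d_max, g_age) of one growth phase."""

    p0: float
    p_psc: float
    d_max: float
    g_age: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if not 0.0 <= self.p_psc <= 1.0:
            raise ValueError(f"p_psc must be in [0, 1], got {self.p_psc}")
        if self.d_max <= 0:
            raise ValueError(f"d_max must be positive, got {self.d_max}")
        if self.g_age <= 0:
            raise ValueError(f"g_age must be positive, got {self.g_age}")


@dataclass(frozen=True)
class BiphasicParams:
    """(θ₁, θ₂, τ): phase parameters before/after the change-point day τ.

    θ₁ governs hours t < τ·24 and θ₂ governs t ≥ τ·24 (the model time t is
    hours since the start of observation).
    """

    theta1: PhaseParams
    theta2: PhaseParams
    tau: int

    def __post_init__(self) -> None:
        if int(self.tau) != self.tau or self.tau < 2:
            raise ValueError(f"tau must be an integer >= 2 days, got {self.tau}")


@dataclass(frozen=True)
class VolumeCalibration:
    """Maps the 2-D model extent to the mm³ caliper scale.

    ``cell_diameter`` (mm, normally equal to the mature rest length s) is
    added to both caliper extents so a single cell reads as one cell diameter.
    """

    cell_diameter: float = 0.25

    def __post_init__(self) -> None:
        if self.cell_diameter <= 0:
            raise ValueError("cell_diameter must be positive")


@dataclass
class TissueState:
    """All agents at one time point: positions, kinds, division ages, adjacency."""

    positions: np.ndarray  # (n, 2) mm
    kinds: np.ndarray  # (n,) int8, TUMOUR / HEALTHY
    t_d: np.ndarray  # (n,) hours since last division (MATURE if never)
    adjacency: Adjacency
    t: float = 0.0  # hours since observation start
    divided_mask: np.ndarray | None = field(default=None, repr=False)

    def copy(self) -> "TissueState":
        return TissueState(
            positions=self.positions.copy(),
            kinds=self.kinds.copy(),
            t_d=self.t_d.copy(),
            adjacency=self.adjacency,  # rebuilt on any mutation
            t=self.t,
            divided_mask=None,
        )

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def n_tumour(self) -> int:
        return int(np.sum(self.kinds == TUMOUR))

    @property
    def n_healthy(self) -> int:
        return int(np.sum(self.kinds == HEALTHY))

    def config(self) -> PointConfiguration:
        return PointConfiguration(points=self.positions, kinds=self.kinds)


@dataclass
class TumourSeries:
    """Observation days and tumour volumes (mm³); both data y and simulations x."""

    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.shape != self.volumes.shape or self.days.ndim != 1:
            raise ValueError("days and volumes must be 1-D arrays of equal length")
        if np.any(self.days < 0) or np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing and non-negative")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")

    def __len__(self) -> int:
        return len(self.days)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def init_tissue(n_rows: int, n_cols: int, mech: MechanicsConfig) -> TissueState:
    """Hexagonal lattice of cells at spacing s with one central tumour cell.

    Every cell starts mature (t_d = MATURE); the cell nearest the domain
    centre is the seed tumour cell.
    """
    if n_rows < 3 or n_cols < 3:
        raise SimulationError("lattice must be at least 3x3")
    s = mech.s
    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    xx = (cols[None, :] + 0.5 * (rows[:, None] % 2)) * s
    yy = np.broadcast_to(rows[:, None] * (s * np.sqrt(3.0) / 2.0), xx.shape)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    centre = pts.mean(axis=0)
    seed = int(np.argmin(np.linalg.norm(pts - centre, axis=1)))
    kinds = np.full(len(pts), HEALTHY, dtype=np.int8)
    kinds[seed] = TUMOUR
    t_d = np.full(len(pts), MATURE)
    adj = build_adjacency(
        PointConfiguration(pts, kinds), mech.max_edge_factor, mech.s
    )
    return TissueState(positions=pts, kinds=kinds, t_d=t_d, adjacency=adj, t=0.0)


def _complete_adjacency(n: int) -> Adjacency:
    """All-pairs adjacency for 1–2 cells, where triangulation is undefined.

    An isolated pair is always treated as spring-connected (no pruning): the
    pruning rule exists to cut spurious long hull edges of a triangulation,
    which cannot arise here.
    """
    from .geometry import _csr_from_edges

    if n < 2:
        edges = np.empty((0, 2), dtype=np.int64)
    else:
        edges = np.array([[0, 1]], dtype=np.int64)
    indptr, indices = _csr_from_edges(n, edges)
    return Adjacency(n=n, edges=edges, indptr=indptr, indices=indices)


def _rebuild_adjacency(state: TissueState, mech: MechanicsConfig) -> None:
    if state.n_cells < 3:
        state.adjacency = _complete_adjacency(state.n_cells)
        return
    # hot path: positions are validated at construction and stay finite under
    # the bounded spring update, so skip re-validation every step
    state.adjacency = _delaunay_adjacency(
        state.positions, mech.max_edge_factor, mech.s
    )


# ---------------------------------------------------------------------------
# behavioural rules
# ---------------------------------------------------------------------------


def proliferation_probability(d: float, params: PhaseParams) -> float:
    """p_d = p0 (1 - d/d_max) for d < d_max, else 0 (distance as nutrient proxy)."""
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if d >= params.d_max:
        return 0.0
    return params.p0 * (1.0 - d / params.d_max)


def edge_rest_length(t_d_i: float, t_d_j: float, mech: MechanicsConfig) -> float:
    """Rest length s_ij = s · min(1, min(t_d_i, t_d_j)/t_age).

    A daughter pair one hour after division gets s/t_age, maturing linearly
    to s at t_d = t_age; an edge is as short as its youngest endpoint.
    """
    if t_d_i < 0 or t_d_j < 0:
        raise ValueError("division ages must be non-negative")
    young = min(t_d_i, t_d_j)
    return mech.s * min(1.0, young / mech.t_age)


def _edge_rest_lengths(state: TissueState, mech: MechanicsConfig) -> np.ndarray:
    e = state.adjacency.edges
    young = np.minimum(state.t_d[e[:, 0]], state.t_d[e[:, 1]])
    return mech.s * np.minimum(1.0, young / mech.t_age)


def movement_step(state: TissueState, mech: MechanicsConfig) -> TissueState:
    """Overdamped Hooke update: r_i += λ Σ_j û_{j→i} (s_ij − ‖r_ij‖).

    Compressed springs repel and stretched springs attract (restoring
    convention), so proliferation pushes the surrounding tissue outward.
    All cells move; the adjacency is rebuilt afterwards.  Coincident points
    are separated by a deterministic 1e-9 mm split before the force
    evaluation so the unit vector is always defined.
    """
    e = state.adjacency.edges
    if len(e) > 0:
        pos = state.positions
        n = len(pos)
        i, j = e[:, 0], e[:, 1]
        rij = pos[i] - pos[j]  # vector j -> i
        dist = np.sqrt(rij[:, 0] ** 2 + rij[:, 1] ** 2)
        zero = dist == 0.0
        if np.any(zero):
            # deterministic split direction from the edge's smaller index
            k = i[zero].astype(float)
            ang = 2.0 * np.pi * ((k * 0.6180339887498949) % 1.0)
            rij[zero] = 1e-9 * np.column_stack([np.cos(ang), np.sin(ang)])
            dist[zero] = 1e-9
        rest = _edge_rest_lengths(state, mech)
        w = mech.lam * (rest - dist) / dist
        fx, fy = w * rij[:, 0], w * rij[:, 1]
        disp = np.empty_like(pos)
        disp[:, 0] = np.bincount(i, weights=fx, minlength=n) - np.bincount(
            j, weights=fx, minlength=n
        )
        disp[:, 1] = np.bincount(i, weights=fy, minlength=n) - np.bincount(
            j, weights=fy, minlength=n
        )
        state.positions = pos + disp
        _rebuild_adjacency(state, mech)
    return state


def division_step(
    state: TissueState,
    params: PhaseParams,
    mech: MechanicsConfig,
    rng: np.random.Generator,
) -> TissueState:
    """Divide eligible tumour cells.

    A tumour cell is eligible when t_d ≥ g_age and its distance d to the
    tumour periphery is below d_max; it then divides with probability
    p_d = p0 (1 − d/d_max).  The two daughters are placed at the parent's
    position ± s/(2 t_age) along a uniformly random direction (initial
    separation equal to the initial rest length s/t_age) and both restart
    t_d = 0.  Divided cells are flagged so they skip invasion this step.
    """
    n0 = state.n_cells
    divided = np.zeros(n0, dtype=bool)
    candidates = np.flatnonzero((state.kinds == TUMOUR) & (state.t_d >= params.g_age))
    new_pos: list[np.ndarray] = []
    if len(candidates) > 0:
        config = state.config()
        boundary = find_boundary(config, state.adjacency)
        d = boundary_distances(config, boundary, candidates)
        p_d = np.where(d < params.d_max, params.p0 * (1.0 - d / params.d_max), 0.0)
        u = rng.random(len(candidates))
        dividing = candidates[u < p_d]
        if len(dividing) > 0:
            ang = rng.random(len(dividing)) * 2.0 * np.pi
            offset = (mech.s / (2.0 * mech.t_age)) * np.column_stack(
                [np.cos(ang), np.sin(ang)]
            )
            parent_pos = state.positions[dividing]
            state.positions[dividing] = parent_pos + offset
            state.t_d[dividing] = 0.0
            divided[dividing] = True
            new_pos = list(parent_pos - offset)

    if new_pos:
        k = len(new_pos)
        state.positions = np.vstack([state.positions, np.array(new_pos)])
        state.kinds = np.concatenate([state.kinds, np.full(k, TUMOUR, dtype=np.int8)])
        state.t_d = np.concatenate([state.t_d, np.zeros(k)])
        divided = np.concatenate([divided, np.ones(k, dtype=bool)])
        _rebuild_adjacency(state, mech)
    state.divided_mask = divided
    return state


def invasion_step(
    state: TissueState, params: PhaseParams, rng: np.random.Generator
) -> TissueState:
    """Peripheral tumour cells that did not divide this step invade.

    Each such cell, with probability p_psc, converts one uniformly chosen
    healthy Delaunay neighbour into a tumour cell with t_d = 0 (the converted
    cell keeps its position, so the adjacency is unchanged).  Cells with no
    healthy neighbour do nothing.
    """
    config = state.config()
    boundary = find_boundary(config, state.adjacency)
    divided = state.divided_mask
    if divided is not None:
        boundary = boundary[~divided[boundary]]
    if len(boundary) > 0:
        u = rng.random(len(boundary))
        actors = boundary[u < params.p_psc]
        for i in actors:
            nbrs = state.adjacency.neighbors(int(i))
            healthy = nbrs[state.kinds[nbrs] == HEALTHY]
            if len(healthy) == 0:
                continue
            victim = healthy[rng.integers(len(healthy))]
            state.kinds[victim] = TUMOUR
            state.t_d[victim] = 0.0
    state.divided_mask = None
    return state


# ---------------------------------------------------------------------------
# volume readout (caliper convention)
# ---------------------------------------------------------------------------


def _principal_extents(pts: np.ndarray) -> tuple[float, float]:
    """(longest pairwise extent, extent along the perpendicular axis)."""
    if len(pts) == 1:
        return 0.0, 0.0
    cand = pts
    if len(pts) >= 3:
        try:
            cand = pts[ConvexHull(pts).vertices]
        except QhullError:
            cand = pts  # collinear: brute force below still works
    dmat = cdist(cand, cand)
    a, b = np.unravel_index(np.argmax(dmat), dmat.shape)
    width = float(dmat[a, b])
    if width == 0.0:
        return 0.0, 0.0
    u = (cand[b] - cand[a]) / width
    perp = np.array([-u[1], u[0]])
    proj = cand @ perp
    return width, float(proj.max() - proj.min())


def measure_volume(state: TissueState, calib: VolumeCalibration) -> float:
    """Caliper tumour volume: width × length²/2 (mm³).

    width is the longest pairwise extent of tumour-cell centres plus one cell
    diameter; length is the extent along the perpendicular axis plus one cell
    diameter.  A single tumour cell reads width = length = cell_diameter.
    """
    tpts = state.positions[state.kinds == TUMOUR]
    if len(tpts) == 0:
        raise SimulationError("no tumour cells: volume undefined")
    w, l = _principal_extents(tpts)
    width = w + calib.cell_diameter
    length = l + calib.cell_diameter
    return width * length * length / 2.0


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------


def _hourly_step(
    state: TissueState,
    params: PhaseParams,
    mech: MechanicsConfig,
    rng: np.random.Generator,
) -> None:
    state.t_d += mech.dt
    division_step(state, params, mech, rng)
    invasion_step(state, params, rng)
    movement_step(state, mech)
    state.t += mech.dt


def burn_in(
    state: TissueState,
    params: PhaseParams,
    mech: MechanicsConfig,
    calib: VolumeCalibration,
    target_volume: float,
    rng: np.random.Generator,
    max_steps: int = 100_000,
) -> TissueState:
    """Grow the tissue until the caliper volume reaches ``target_volume`` mm³.

    The returned (frozen) lattice is the common initial condition for all
    subsequent simulations.  Raises if the cap is exceeded, which means the
    parameters provide no route to the target volume.
    """
    _validate_phase(params, mech)
    for _ in range(max_steps):
        if measure_volume(state, calib) >= target_volume:
            state.t = 0.0
            return state
        _hourly_step(state, params, mech, rng)
    raise SimulationError(
        f"burn-in did not reach {target_volume} mm^3 within {max_steps} steps"
    )


def _validate_phase(params: PhaseParams, mech: MechanicsConfig) -> None:
    if params.g_age <= mech.t_age:
        raise ValueError(
            f"g_age ({params.g_age} h) must exceed t_age ({mech.t_age} h)"
        )


def _as_biphasic(params: PhaseParams | BiphasicParams) -> BiphasicParams:
    if isinstance(params, PhaseParams):
        return BiphasicParams(theta1=params, theta2=params, tau=2)
    return params


def simulate(
    params: PhaseParams | BiphasicParams,
    obs_days: np.ndarray,
    init: TissueState,
    mech: MechanicsConfig,
    calib: VolumeCalibration,
    rng: np.random.Generator,
    max_volume: float | None = None,
    max_cells: int = 200_000,
) -> TumourSeries:
    """Run the hourly VCBM loop and record caliper volume at each observation day.

    θ₁ is active while t < τ·24 h and θ₂ from t ≥ τ·24 h.  A monophasic
    ``PhaseParams`` input is treated as biphasic with θ₁ = θ₂; the RNG
    consumption does not depend on τ, so θ₁ = θ₂ reproduces the monophasic
    trajectory exactly under the same seed, whatever τ.

    ``max_volume`` and ``max_cells`` are runaway guards for calibration, where
    prior draws with very small g_age grow exponentially: once the recorded
    volume passes ``max_volume`` (checked at observation days) or the agent
    count passes ``max_cells``, stepping stops and the remaining observations
    are filled with the current volume.  Such trajectories are already far
    outside any data they are compared against, so the frozen tail only saves
    the cost of simulating an astronomically large tumour.
    """
    bp = _as_biphasic(params)
    _validate_phase(bp.theta1, mech)
    _validate_phase(bp.theta2, mech)
    obs_days = np.asarray(obs_days, dtype=float)
    if obs_days.ndim != 1 or len(obs_days) == 0:
        raise ValueError("obs_days must be a non-empty 1-D array")
    if np.any(obs_days < 0) or np.any(np.diff(obs_days) <= 0):
        raise ValueError("obs_days must be strictly increasing and non-negative")

    obs_hours = np.rint(obs_days * 24.0).astype(int)
    switch_hour = bp.tau * 24
    state = init.copy()
    state.t = 0.0

    volumes = np.empty(len(obs_days))
    pos = 0
    if obs_hours[0] == 0:
        volumes[0] = measure_volume(state, calib)
        pos = 1
    for h in range(1, int(obs_hours[-1]) + 1):
        active = bp.theta1 if (h - 1) < switch_hour else bp.theta2
        _hourly_step(state, active, mech, rng)
        recorded = False
        if pos < len(obs_hours) and h == obs_hours[pos]:
            volumes[pos] = measure_volume(state, calib)
            pos += 1
            recorded = True
        if state.n_cells > max_cells or (
            recorded and max_volume is not None and volumes[pos - 1] >= max_volume
        ):
            volumes[pos:] = measure_volume(state, calib)
            break
    return TumourSeries(days=obs_days, volumes=volumes)


# ---------------------------------------------------------------------------
# parameter-vector bridge for calibration
# ---------------------------------------------------------------------------


def theta_to_params(theta: np.ndarray, kind: str) -> PhaseParams | BiphasicParams:
    """Map a flat calibration vector to model parameters.

    ``kind='monophasic'``: θ = (p0, p_psc, d_max, g_age).
    ``kind='biphasic'``: θ = (p0¹, p_psc¹, d_max¹, g_age¹,
    p0², p_psc², d_max², g_age², τ).
    """
    theta = np.asarray(theta, dtype=float)
    if kind == "monophasic":
        if len(theta) != 4:
            raise ValueError("monophasic theta must have 4 components")
        return PhaseParams(*theta)
    if kind == "biphasic":
        if len(theta) != 9:
            raise ValueError("biphasic theta must have 9 components")
        return BiphasicParams(
            theta1=PhaseParams(*theta[:4]),
            theta2=PhaseParams(*theta[4:8]),
            tau=int(round(theta[8])),
        )
    raise ValueError(f"unknown model kind: {kind!r}")


def make_model(
    obs_days: np.ndarray,
    init: TissueState,
    mech: MechanicsConfig,
    calib: VolumeCalibration,
    kind: str = "monophasic",
    max_volume: float | None = None,
    max_cells: int | None = None,
):
    """Closure θ ↦ TumourSeries on ``obs_days``, starting every simulation from
    the same frozen burn-in lattice (the common initial condition).

    ``max_volume`` caps runaway trajectories during calibration (see
    :func:`simulate`); a natural choice is a large multiple of the biggest
    observed volume, far beyond any acceptable discrepancy.  When a volume cap
    is given and ``max_cells`` is not, the cell cap is derived from it as the
    number of hexagonally packed cells that could fill the capped caliper
    extent (with a 2x margin plus the initial lattice) — this also catches
    runaway parameter draws that pile up thousands of compressed cells whose
    caliper volume grows only slowly.
    """
    obs_days = np.asarray(obs_days, dtype=float)
    if max_cells is None:
        if max_volume is not None:
            extent = (2.0 * max_volume) ** (1.0 / 3.0)
            max_cells = init.n_cells + int(math.ceil(2.0 * extent**2 / mech.s**2))
        else:
            max_cells = 200_000

    def model(theta: np.ndarray, rng: np.random.Generator) -> TumourSeries:
        return simulate(
            theta_to_params(theta, kind), obs_days, init, mech, calib, rng,
            max_volume=max_volume, max_cells=max_cells,
        )

    return model
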