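"""Overdamped particle dynamics of the nuclear array on the spheroid.

Each nucleus is a particle constrained to the prolate-spheroid surface. In
the overdamped (inertia-free) regime the velocity of nucleus i is set by the
sum of pair forces from its Voronoi neighbors divided by the effective
friction coefficient:

    v_i = (1 / gamma_tilde) * sum_{j in n(i)} F_ij e_ij

The position update is an explicit Euler step followed by re-projection onto
the surface; the velocity is projected into the local tangent plane first,
which is equivalent (to the order of the time step) to integrating the
surface equations of motion in spheroidal coordinates.

Mitosis: every nucleus carries an age tau (nuclear-cycle units). Ages are
assigned at initialization so that an age front — the mitotic wave — sweeps
from the configured origins (both poles by default) toward the embryo
middle. When a nucleus reaches the cycle time it is replaced by two
daughters of age zero, placed with a small random angular offset mirrored
about the mother's position (random division orientation, daughter
separation below ``division_max_separation`` so the daughters start inside
the repulsive core and are pushed apart by the core force alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .forcefields import ForceFieldParams, distance_factor, pair_force_magnitude
from .geometry import (
    Spheroid,
    hull_edges,
    hull_triangulation,
    tangent_project,
)

log = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run.

    Times are in nuclear-cycle (NC) units, lengths in um. ``wave_origins``
    are EL fractions of the mitotic-wave start points and
    ``wave_start_offsets`` per-origin delays (NC); the wavefront crosses
    half the embryo length in ``wave_duration_frac`` NC.
    """

    spheroid: Spheroid = field(default_factory=Spheroid)
    n_initial: int = 400
    force: ForceFieldParams | None = field(default_factory=ForceFieldParams)
    gamma_tilde: float = 1.0
    dt: float = 2e-4
    n_cycles: int = 1
    sim_time: float = 1.2
    wave_duration_frac: float = 0.15
    wave_origins: tuple = (0.0, 1.0)
    wave_start_offsets: tuple = (0.0, 0.0)
    pre_wave_delay: float = 0.15
    theta_sigma: float = 0.5
    division_jitter: float = 5e-4
    division_max_separation: float = 0.1
    seed: int = 0
    relax_steps: int = 500
    log_every: int = 25
    neighbor_update_every: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_initial < 4:
            raise ValueError("need at least 4 nuclei")
        if not 0 < self.wave_duration_frac < 1:
            raise ValueError("wave_duration_frac must lie in (0, 1)")
        if len(self.wave_origins) != len(self.wave_start_offsets):
            raise ValueError("one start offset per wave origin required")
        if any(not 0.0 <= off < 1.0 for off in self.wave_start_offsets):
            raise ValueError("wave start offsets must lie in [0, 1) cycles")


@dataclass
class SimState:
    """Mutable per-nucleus state: positions on the surface, ages, identity."""

    time: float
    positions: np.ndarray  # (N, 3)
    ages: np.ndarray  # (N,)
    ids: np.ndarray  # (N,) int
    parents: np.ndarray  # (N,) int, -1 for founders
    generation: np.ndarray  # (N,) int, division rounds completed
    next_id: int

    def copy(self) -> "SimState":
        return SimState(
            self.time,
            self.positions.copy(),
            self.ages.copy(),
            self.ids.copy(),
            self.parents.copy(),
            self.generation.copy(),
            self.next_id,
        )


@dataclass
class Trajectory:
    """Logged frames of a run plus the division event log."""

    spheroid: Spheroid
    times: list = field(default_factory=list)
    frames: list = field(default_factory=list)  # list of SimState snapshots
    divisions: list = field(default_factory=list)  # (time, mother_id, d1, d2)

    def log(self, state: SimState):
        if self.times and state.time <= self.times[-1]:
            raise SimulationError("frame times must strictly increase")
        self.times.append(state.time)
        self.frames.append(state.copy())

    def __len__(self):
        return len(self.frames)


# -- wave schedule ----------------------------------------------------------


def wave_delays(el: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-nucleus delay (NC) between the earliest division anywhere and the
    division at this AP position: distance to the nearest wave origin (the
    front covers half the embryo length in ``wave_duration_frac`` NC) plus
    that origin's start offset."""
    el = np.asarray(el, float)
    delays = np.full(el.shape, np.inf)
    for origin, offset in zip(config.wave_origins, config.wave_start_offsets):
        d = np.abs(el - origin) / 0.5 * config.wave_duration_frac + offset
        delays = np.minimum(delays, d)
    return delays - delays.min()


def assign_initial_ages(positions: np.ndarray, config: SimConfig) -> np.ndarray:
    from .geometry import ap_fraction

    el = ap_fraction(positions, config.spheroid, check=False)
    cycle = config.force.cycle_time if config.force else 1.0
    ages = cycle - config.pre_wave_delay - wave_delays(el, config)
    if np.any(ages < 0):
        raise ValueError(
            "wave schedule yields negative initial ages; reduce offsets or "
            "pre_wave_delay"
        )
    return ages


# -- forces -----------------------------------------------------------------


def neighbor_edges(positions: np.ndarray) -> np.ndarray:
    return hull_edges(hull_triangulation(positions).simplices)


def pair_force_vectors(state: SimState, params: ForceFieldParams,
                       edges: np.ndarray, age_dependent: bool = True
                       ) -> np.ndarray:
    """Net force vector on every nucleus from its neighbor list.

    With ``age_dependent=False`` only the distance factor B(r) acts (used
    for the initial relaxation where ages are frozen/meaningless).
    """
    i, j = edges[:, 0], edges[:, 1]
    sep = state.positions[i] - state.positions[j]
    dist = np.linalg.norm(sep, axis=1)
    if np.any(dist <= 0):
        raise SimulationError("coincident nuclei")
    if age_dependent:
        tau_bar = 0.5 * (state.ages[i] + state.ages[j])
        mag = pair_force_magnitude(tau_bar, dist, params)
    else:
        mag = distance_factor(dist, params)
    vec = (mag / dist)[:, None] * sep
    out = np.zeros_like(state.positions)
    np.add.at(out, i, vec)
    np.add.at(out, j, -vec)
    return out


def step(state: SimState, config: SimConfig, edges: np.ndarray | None = None,
         age_dependent: bool = True, advance_age: bool = True) -> SimState:
    """One explicit Euler step of the overdamped dynamics.

    Velocities are the tangent-projected net forces divided by gamma_tilde;
    positions are re-projected onto the surface afterwards.
    """
    sph = config.spheroid
    new = state.copy()
    if config.force is not None:
        if edges is None:
            edges = neighbor_edges(state.positions)
        try:
            f = pair_force_vectors(state, config.force, edges, age_dependent)
        except Exception as exc:  # degenerate cloud: dump frame for debugging
            raise SimulationError(
                f"force evaluation failed at t={state.time:.5f} "
                f"(N={len(state.ids)}): {exc}"
            ) from exc
        v = tangent_project(state.positions, f / config.gamma_tilde, sph)
        new.positions = sph.project(state.positions + v * config.dt)
    new.time = state.time + config.dt
    if advance_age:
        new.ages = state.ages + config.dt
    return new


def maybe_divide(state: SimState, config: SimConfig,
                 rng: np.random.Generator,
                 events: list | None = None) -> SimState:
    """Replace every nucleus that completed its cycle by two daughters.

    Daughters get mirrored angular offsets (+/- delta_theta, +/- delta_phi)
    drawn uniformly from the jitter interval, rescaled if necessary so their
    chord separation stays below ``division_max_separation``; their angular
    mass center is exactly the mother's position. Mothers are processed in
    id order and new ids appended monotonically.
    """
    cycle = config.force.cycle_time if config.force else 1.0
    due = (state.ages >= cycle) & (state.generation < config.n_cycles)
    if not np.any(due):
        return state
    sph = config.spheroid
    order = np.argsort(state.ids[due])
    idx = np.flatnonzero(due)[order]
    theta, phi = sph.to_angles(state.positions[idx])

    jit = config.division_jitter
    dth = rng.uniform(-jit, jit, size=len(idx))
    dph = rng.uniform(-jit, jit, size=len(idx))
    for _ in range(4):  # rescale until the chord bound holds (1 pass typical)
        p1 = sph.from_angles(theta + dth, phi + dph)
        p2 = sph.from_angles(theta - dth, phi - dph)
        d = np.linalg.norm(p1 - p2, axis=1)
        over = d >= config.division_max_separation
        if not np.any(over):
            break
        scale = 0.99 * config.division_max_separation / d[over]
        dth[over] *= scale
        dph[over] *= scale

    keep = ~due
    n_new = len(idx)
    new_ids = state.next_id + np.arange(2 * n_new)
    mothers = state.ids[idx]
    out = SimState(
        time=state.time,
        positions=np.concatenate([state.positions[keep], p1, p2]),
        ages=np.concatenate([state.ages[keep], np.zeros(2 * n_new)]),
        ids=np.concatenate([state.ids[keep],
                            new_ids[:n_new], new_ids[n_new:]]),
        parents=np.concatenate([state.parents[keep], mothers, mothers]),
        generation=np.concatenate(
            [state.generation[keep],
             np.repeat(state.generation[idx] + 1, 2)]
        ),
        next_id=state.next_id + 2 * n_new,
    )
    if events is not None:
        for k in range(n_new):
            events.append(
                (state.time, int(mothers[k]), int(new_ids[k]),
                 int(new_ids[n_new + k]))
            )
    return out


# -- initialization ---------------------------------------------------------


def initialize(config: SimConfig, rng: np.random.Generator | None = None
               ) -> SimState:
    """Seed the array and relax it into a regular initial configuration.

    theta is Gaussian about the equator (the post-yolk-migration density is
    higher in the embryo middle than at the poles), phi uniform. The random
    cloud is then relaxed for ``relax_steps`` overdamped steps under the
    distance factor B(r) alone (ages frozen), after which ages are assigned
    from the AP position so the mitotic wave starts at the configured
    origins.

    The relaxation must stay short: the distance-only tension network has
    no pole-populated equilibrium (left alone it slowly contracts the
    whole array into an equatorial band), so rearrangement serves only to
    regularize spacing locally. The default, 0.1 time units of overdamped
    motion, moves nuclei by a few um -- on the order of the force range --
    without eroding the global profile set by the theta distribution.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sph = config.spheroid
    n = config.n_initial
    theta = np.empty(0)
    while len(theta) < n:  # rejection-sample into the open interval (0, pi)
        cand = rng.normal(np.pi / 2, config.theta_sigma, size=2 * n)
        theta = np.concatenate([theta, cand[(cand > 1e-3) & (cand < np.pi - 1e-3)]])
    theta = theta[:n]
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    positions = sph.from_angles(theta, phi)

    state = SimState(
        time=0.0,
        positions=positions,
        ages=np.zeros(n),
        ids=np.arange(n),
        parents=np.full(n, -1),
        generation=np.zeros(n, dtype=int),
        next_id=n,
    )
    if config.force is not None:
        edges = None
        for k in range(config.relax_steps):
            if edges is None or k % config.neighbor_update_every == 0:
                edges = neighbor_edges(state.positions)
            state = step(state, config, edges, age_dependent=False,
                         advance_age=False)
        state.time = 0.0
    state.ages = assign_initial_ages(state.positions, config)
    return state


def run(config: SimConfig) -> Trajectory:
    """Integrate the model over ``sim_time`` NC, dividing nuclei as their
    ages complete a cycle; frames are logged every ``log_every`` steps."""
    rng = np.random.default_rng(config.seed)
    state = initialize(config, rng)
    traj = Trajectory(spheroid=config.spheroid)
    traj.log(state)
    n_steps = int(round(config.sim_time / config.dt))
    edges = None
    last_n = len(state.ids)
    next_cycle_report = 0.1
    for k in range(n_steps):
        divided = maybe_divide(state, config, rng, traj.divisions)
        if divided is not state:
            state = divided
            edges = None
        if edges is None or k % config.neighbor_update_every == 0:
            edges = neighbor_edges(state.positions)
        state = step(state, config, edges)
        if (k + 1) % config.log_every == 0:
            traj.log(state)
        if state.time >= next_cycle_report:
            if len(state.ids) != last_n:
                log.info("t=%.3f N=%d", state.time, len(state.ids))
                last_n = len(state.ids)
            next_cycle_report += 0.1
    return traj
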