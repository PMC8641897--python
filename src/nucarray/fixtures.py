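"""Deterministic small datasets exercising every module without a full
simulation: a quasi-planar hexagonal patch (order parameters, Voronoi
densities), an analytic standing-wave trajectory (kymograph and wave
statistics), a two-nucleus dumbbell (pair forces and integration), and a
100-nucleus mini embryo configuration (end-to-end smoke runs)."""

from __future__ import annotations

import numpy as np

from .forcefields import ForceFieldParams
from .geometry import Spheroid
from .simulator import SimConfig, SimState, Trajectory

FIXTURE_KINDS = ("hex_patch", "standing_wave", "two_nuclei", "mini_embryo")


def hex_patch(rows: int = 9, cols: int = 9, spacing: float = 10.0,
              radius_scale: float = 40.0, seed: int = 0, jitter: float = 0.0):
    """Hexagonal lattice patch on a near-planar region of a large spheroid.

    Returns (points, spheroid, interior_mask). The spheroid is large enough
    relative to the patch that curvature is negligible; interior nodes have
    a full hexagonal neighborhood.
    """
    sph = Spheroid(radius_scale * spacing * max(rows, cols),
                   0.4 * radius_scale * spacing * max(rows, cols))
    rng = np.random.default_rng(seed)
    pts = []
    interior = []
    for r in range(rows):
        for c in range(cols):
            u = (c + 0.5 * (r % 2)) * spacing
            w = r * spacing * np.sqrt(3) / 2
            pts.append((u - 0.5 * cols * spacing, w - 0.5 * rows * spacing))
            interior.append(0 < r < rows - 1 and 0 < c < cols - 1)
    pts = np.array(pts) + jitter * rng.standard_normal((len(pts), 2)) * spacing
    # wrap the planar patch onto the spheroid near the equator (x ~ 0):
    # u -> AP arc, w -> azimuthal arc
    theta = np.pi / 2 + pts[:, 0] / sph.semi_minor * (sph.semi_minor / sph.semi_major)
    phi = pts[:, 1] / sph.semi_minor
    return sph.from_angles(theta, phi), sph, np.array(interior)


def standing_wave(n_bins: int = 40, n_per_bin: int = 6, n_frames: int = 81,
                  period: float = 1.0, amplitude: float = 2.0,
                  damping: float = 1.0, seed: int = 0) -> Trajectory:
    """Analytic 3-node standing-wave trajectory on the default spheroid.

    AP velocity v(el, t) = amplitude * sin(2 pi el) * sin(2 pi t / period),
    with the second half period scaled by ``damping``; nodes at el = 0,
    1/2 and 1. Positions are advanced by explicit integration of the
    velocity field so backward differences recover it.
    """
    sph = Spheroid()
    rng = np.random.default_rng(seed)
    el0 = np.repeat((np.arange(n_bins) + 0.5) / n_bins, n_per_bin)
    el0 = el0 + rng.uniform(-0.4, 0.4, size=len(el0)) / n_bins
    phi = rng.uniform(0, 2 * np.pi, size=len(el0))
    n = len(el0)
    times = np.linspace(0.0, period, n_frames)
    dt = times[1] - times[0]
    traj = Trajectory(spheroid=sph)
    el = el0.copy()
    for k, t in enumerate(times):
        theta = np.arccos(np.clip(2 * el - 1, -1, 1))
        # place by AP coordinate: x = a cos(theta) = a (2 el - 1)
        state = SimState(
            time=float(t), positions=sph.from_angles(theta, phi),
            ages=np.full(n, t), ids=np.arange(n),
            parents=np.full(n, -1), generation=np.zeros(n, int), next_id=n,
        )
        traj.log(state)
        damp = 1.0 if t < period / 2 else damping
        v_el = amplitude * np.sin(2 * np.pi * el) * np.sin(2 * np.pi * t / period) * damp
        el = el + v_el * dt / (2 * sph.semi_major)  # v is in um per time
    return traj


def two_nuclei(separation: float, sph: Spheroid | None = None,
               ages: tuple = (0.5, 0.5)) -> SimState:
    """Two nuclei near the equator at a given chord separation (um)."""
    sph = sph or Spheroid()
    dphi = separation / sph.semi_minor  # chord ~ arc for small angles
    # refine until the chord distance matches the request
    for _ in range(50):
        p = sph.from_angles([np.pi / 2, np.pi / 2], [0.0, dphi])
        actual = np.linalg.norm(p[0] - p[1])
        if abs(actual - separation) <= 1e-10 * separation:
            break
        dphi *= separation / actual
    return SimState(
        time=0.0, positions=p, ages=np.asarray(ages, float),
        ids=np.arange(2), parents=np.full(2, -1),
        generation=np.zeros(2, int), next_id=2,
    )


def mini_embryo(seed: int = 0, n_initial: int = 100,
                sim_time: float = 1.0, **overrides) -> SimConfig:
    """Small, fast end-to-end configuration (scaled-down nucleus count on a
    proportionally scaled-down spheroid so spacings stay realistic)."""
    defaults = dict(
        spheroid=Spheroid(125.0, 37.5),
        n_initial=n_initial,
        force=ForceFieldParams(),
        sim_time=sim_time,
        relax_steps=500,
        seed=seed,
        log_every=50,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def make_fixtures(kind: str, seed: int = 0):
    """Dispatch by fixture kind; raises on unknown kinds."""
    if kind == "hex_patch":
        return hex_patch(seed=seed)
    if kind == "standing_wave":
        return standing_wave(seed=seed)
    if kind == "two_nuclei":
        return two_nuclei(12.0), Spheroid()
    if kind == "mini_embryo":
        return mini_embryo(seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"choose from {FIXTURE_KINDS}")
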