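"""Closed-form pairwise internuclear force fields.

The pair force between neighboring nuclei factorises into an age pulse
``A(tau_bar)`` and a distance factor ``B(r_bar)``, with ``tau_bar`` the mean
age of the pair and ``r_bar`` the internuclear (chord) distance:

    F(tau_bar, r_bar) = B(r_bar)                 r_bar <  r0   (repulsive core)
                      = A(tau_bar) * B(r_bar)    r_bar >= r0   (age-modulated)

    A(tau) = F1 - (cos(pi tau / t1) + 1) (F1 - F2) / 2   for 0 <= tau < 2 t1
           = F2                                          for tau >= 2 t1

    B(r)   = F0 (1 - r / r0)          (attr_linear, the default)

Sign convention: positive magnitude pushes the nuclei apart, negative pulls
them together. ``B`` is positive (repulsive) inside the core ``r < r0`` and
negative (attractive, growing with distance) beyond it; ``A`` is a single
positive pulse peaking at ``tau = t1`` that modulates only the attractive
border region.

Two variants are provided for model comparison:

* ``attr_quadratic`` — same sign structure, quadratic distance dependence
  ``B(r) = F0 (1 - (r/r0)^2)``.
* ``repulsive`` — a purely repulsive field that decreases with distance in
  both core and border, ``B_r(r) = F0 max(0, 1 - r / (2 r0))``, with the
  border portion (r >= r0) modulated by the same age pulse.

All forces are in arbitrary force units; times in nuclear-cycle (NC) units;
lengths in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class FieldKind(str, Enum):
    attr_linear = "attr_linear"
    attr_quadratic = "attr_quadratic"
    repulsive = "repulsive"


@dataclass(frozen=True)
class ForceFieldParams:
    """Parameters of the pair force; the five free model parameters plus the
    field variant and the nuclear cycle time (time unit)."""

    t1: float = 0.23
    F1: float = 1.0
    F2: float = 0.2
    r0: float = 8.5
    F0: float = 15.0
    kind: FieldKind = FieldKind.attr_linear
    cycle_time: float = 1.0

    def __post_init__(self):
        if self.t1 <= 0 or self.r0 <= 0 or self.F0 <= 0:
            raise ValueError("t1, r0, F0 must be positive")
        if not (self.F1 >= self.F2 >= 0):
            raise ValueError("require F1 >= F2 >= 0")
        object.__setattr__(self, "kind", FieldKind(self.kind))


def age_factor(tau_bar, params: ForceFieldParams):
    """Age pulse A(tau_bar): F2 at tau=0, peak F1 at tau=t1, constant F2 for
    tau >= 2 t1; continuous everywhere."""
    tau = np.asarray(tau_bar, float)
    if np.any(tau < 0):
        raise ValueError("negative age reached the force law")
    t1, F1, F2 = params.t1, params.F1, params.F2
    pulse = F1 - (np.cos(np.pi * tau / t1) + 1.0) * (F1 - F2) / 2.0
    out = np.where(tau < 2 * t1, pulse, F2)
    return out if out.ndim else float(out)


def distance_factor(r_bar, params: ForceFieldParams):
    """Distance factor B(r_bar) for the configured field kind."""
    r = np.asarray(r_bar, float)
    if np.any(r <= 0):
        raise ValueError("internuclear distance must be positive")
    F0, r0 = params.F0, params.r0
    if params.kind == FieldKind.attr_linear:
        out = F0 * (1.0 - r / r0)
    elif params.kind == FieldKind.attr_quadratic:
        out = F0 * (1.0 - (r / r0) ** 2)
    else:  # repulsive, decreasing with distance, cut off at 2 r0
        out = F0 * np.maximum(0.0, 1.0 - r / (2.0 * r0))
    return out if out.ndim else float(out)


def pair_force_magnitude(tau_bar, r_bar, params: ForceFieldParams):
    """Signed pair-force magnitude (positive = repulsive).

    Core region (r < r0): age-independent B(r). Border (r >= r0): A * B.
    The repulsive variant keeps B positive everywhere; its border region is
    still modulated by the age pulse.
    """
    r = np.asarray(r_bar, float)
    B = np.asarray(distance_factor(r, params), float)
    A = np.asarray(age_factor(tau_bar, params), float)
    out = np.where(r < params.r0, B, A * B)
    return out if out.ndim else float(out)


def pair_force(tau_i, tau_j, r_i, r_j, params: ForceFieldParams
               ) -> tuple[float, np.ndarray]:
    """Force exerted on nucleus i by nucleus j.

    Returns ``(signed_magnitude, force_vector_on_i)``. The vector is the
    magnitude times the unit vector from j to i, so a positive magnitude
    pushes i away from j; swapping i and j negates the vector (Newton's
    third law) while the magnitude is symmetric.
    """
    r_i = np.asarray(r_i, float)
    r_j = np.asarray(r_j, float)
    sep = r_i - r_j
    dist = float(np.linalg.norm(sep))
    if dist <= 0:
        raise ValueError("coincident nuclei")
    tau_bar = 0.5 * (tau_i + tau_j)
    mag = pair_force_magnitude(tau_bar, dist, params)
    return float(mag), mag * sep / dist


def field_grid(params: ForceFieldParams, tau_grid, r_grid) -> np.ndarray:
    """Matrix F(T, r) of the pair force over an age x distance grid
    (rows = ages, columns = distances); for plotting and for comparison with
    learned fields."""
    tg = np.asarray(tau_grid, float)[:, None]
    rg = np.asarray(r_grid, float)[None, :]
    return pair_force_magnitude(np.broadcast_to(tg, (len(tau_grid), rg.size)),
                                np.broadcast_to(rg, (tg.size, rg.size)),
                                params)
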