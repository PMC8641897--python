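"""Prolate-spheroid surface geometry.

The embryo surface is modelled as a prolate spheroid with the
anterior-posterior (AP) axis along cartesian ``x``::

    x^2 / a^2 + (y^2 + z^2) / b^2 = 1,   a = semi_major > b = semi_minor.

The anterior pole sits at ``x = -a`` and positions along the axis are
reported as fractions of embryo length (EL), ``(x + a) / (2a)``.

Surface points carry both cartesian coordinates and prolate-spheroidal
angles ``(nu, theta, phi)``: with focal distance ``c = sqrt(a^2 - b^2)``,

    x = c cosh(nu) cos(theta)
    y = c sinh(nu) sin(theta) cos(phi)
    z = c sinh(nu) sin(theta) sin(phi)

``nu`` is constant on the surface (``cosh(nu) = a / c``); ``theta`` runs
from 0 at the posterior pole to pi at the anterior pole and ``phi`` is the
azimuth about the AP axis.

Local density is measured through a surface Voronoi construction: the point
cloud is triangulated by its 3D convex hull (valid because the spheroid is
convex), each triangle is split into three quadrangles through its
circumcenter and edge midpoints, and each vertex collects its incident
quadrangle areas as the Voronoi area ``s``; density is ``rho = 1/s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull


class GeometryError(ValueError):
    """Point not on the surface, or degenerate point cloud."""


@dataclass(frozen=True, eq=False)
class Spheroid:
    """Prolate spheroid with AP axis along x, centred at ``center``.

    Lengths are micrometres. Default semi-axes 250 x 75 um give the 5:1.5
    major:minor axis ratio of the early fly embryo.
    """

    semi_major: float = 250.0
    semi_minor: float = 75.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if not self.semi_major > self.semi_minor > 0:
            raise GeometryError(
                f"require semi_major > semi_minor > 0, got "
                f"{self.semi_major}, {self.semi_minor}"
            )
        object.__setattr__(self, "center", np.asarray(self.center, float))

    def __eq__(self, other):
        if not isinstance(other, Spheroid):
            return NotImplemented
        return (self.semi_major == other.semi_major
                and self.semi_minor == other.semi_minor
                and np.array_equal(self.center, other.center))

    def __hash__(self):
        return hash((self.semi_major, self.semi_minor,
                     tuple(np.asarray(self.center).ravel().tolist())))

    @property
    def focal_distance(self) -> float:
        return float(np.sqrt(self.semi_major**2 - self.semi_minor**2))

    @property
    def nu_surface(self) -> float:
        """Radial prolate-spheroidal coordinate held constant on the surface."""
        return float(np.arccosh(self.semi_major / self.focal_distance))

    # -- implicit function -------------------------------------------------

    def implicit(self, p: np.ndarray) -> np.ndarray:
        """x^2/a^2 + (y^2+z^2)/b^2 - 1, vectorised over trailing axis 3."""
        q = np.asarray(p, float) - self.center
        return (
            q[..., 0] ** 2 / self.semi_major**2
            + (q[..., 1] ** 2 + q[..., 2] ** 2) / self.semi_minor**2
            - 1.0
        )

    def contains(self, p: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        return np.abs(self.implicit(p)) <= rtol

    def normal(self, p: np.ndarray) -> np.ndarray:
        """Outward unit normal(s): normalised gradient of the implicit function."""
        q = np.asarray(p, float) - self.center
        g = np.empty_like(q)
        g[..., 0] = 2.0 * q[..., 0] / self.semi_major**2
        g[..., 1] = 2.0 * q[..., 1] / self.semi_minor**2
        g[..., 2] = 2.0 * q[..., 2] / self.semi_minor**2
        return g / np.linalg.norm(g, axis=-1, keepdims=True)

    # -- coordinate transforms ---------------------------------------------

    def from_angles(self, theta, phi) -> np.ndarray:
        """Surface cartesian point(s) from (theta, phi); nu is implicit."""
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        x = self.semi_major * np.cos(theta)
        rho = self.semi_minor * np.sin(theta)
        out = np.stack([x, rho * np.cos(phi), rho * np.sin(phi)], axis=-1)
        return out + self.center

    def to_angles(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`from_angles` for on-surface points."""
        q = np.asarray(p, float) - self.center
        st = np.hypot(q[..., 1], q[..., 2]) / self.semi_minor
        ct = q[..., 0] / self.semi_major
        theta = np.arctan2(st, ct)
        phi = np.mod(np.arctan2(q[..., 2], q[..., 1]), 2 * np.pi)
        return theta, phi

    def project(self, p: np.ndarray) -> np.ndarray:
        """Centrally project point(s) onto the surface (exact for the
        spheroid's own radial scaling; second-order accurate as a
        closest-point projection for small off-surface displacements)."""
        q = np.asarray(p, float) - self.center
        scale = np.sqrt(
            q[..., 0] ** 2 / self.semi_major**2
            + (q[..., 1] ** 2 + q[..., 2] ** 2) / self.semi_minor**2
        )
        return q / scale[..., None] + self.center

    def surface_area(self) -> float:
        """Closed-form prolate spheroid surface area (um^2)."""
        a, b = self.semi_major, self.semi_minor
        e = np.sqrt(1.0 - b**2 / a**2)
        return float(2 * np.pi * b**2 * (1 + (a / (b * e)) * np.arcsin(e)))


def ap_fraction(p: np.ndarray, sph: Spheroid, check: bool = True) -> np.ndarray:
    """Fraction of embryo length: 0 at the anterior pole (x = -a), 1 at the
    posterior pole, linear in the AP cartesian coordinate."""
    p = np.asarray(p, float)
    if check and not np.all(sph.contains(p, rtol=1e-6)):
        raise GeometryError("point not on the spheroid surface")
    x = p[..., 0] - sph.center[0]
    return (x + sph.semi_major) / (2.0 * sph.semi_major)


def tangent_project(p: np.ndarray, v: np.ndarray, sph: Spheroid) -> np.ndarray:
    """Remove the surface-normal component of ``v`` at surface point ``p``.

    A linear, idempotent map: returns ``v - (v . n) n`` with ``n`` the unit
    outward normal.
    """
    n = sph.normal(p)
    v = np.asarray(v, float)
    return v - np.sum(v * n, axis=-1, keepdims=True) * n


# -- Voronoi density on the triangulated surface ----------------------------


@dataclass
class NeighborGraph:
    """Nearest-neighbor structure of a surface point cloud.

    ``edges`` is an (E, 2) int array of undirected hull edges, ``areas`` the
    per-node Voronoi area s (um^2) and ``density`` rho = 1/s (um^-2).
    ``neighbors`` maps node id -> sorted array of neighbor ids.
    """

    n_nodes: int
    edges: np.ndarray
    areas: np.ndarray
    density: np.ndarray
    simplices: np.ndarray
    total_area: float

    _neighbors: list | None = None

    @property
    def neighbors(self) -> list:
        if self._neighbors is None:
            nbrs = [[] for _ in range(self.n_nodes)]
            for i, j in self.edges:
                nbrs[i].append(j)
                nbrs[j].append(i)
            self._neighbors = [np.array(sorted(x), dtype=int) for x in nbrs]
        return self._neighbors


def hull_triangulation(points: np.ndarray) -> ConvexHull:
    """Convex hull of the cloud, retrying with joggled input if a point ends
    up off the hull (near-coincident daughter nuclei can do this)."""
    points = np.asarray(points, float)
    hull = ConvexHull(points)
    if len(hull.vertices) != len(points):
        hull = ConvexHull(points, qhull_options="QJ")
        if len(hull.vertices) != len(points):
            raise GeometryError(
                "degenerate point cloud: some points are not hull vertices"
            )
    return hull


def hull_edges(simplices: np.ndarray) -> np.ndarray:
    """Unique undirected edges of a triangulation."""
    e = np.concatenate(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
    )
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def _triangle_circumcenters(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                            clamp: bool = True) -> np.ndarray:
    """Circumcenters of 3D triangles, vectorised.

    With ``clamp`` the barycentric coordinates are clipped to the triangle so
    the subsequent quadrangle split always partitions the triangle (obtuse
    triangles put the true circumcenter outside).
    """
    ab = b - a
    ac = c - a
    ab2 = np.sum(ab * ab, axis=1)
    ac2 = np.sum(ac * ac, axis=1)
    abac = np.sum(ab * ac, axis=1)
    denom = 2.0 * (ab2 * ac2 - abac**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (ac2 * (ab2 - abac)) / denom
        t = (ab2 * (ac2 - abac)) / denom
    bad = ~np.isfinite(s) | ~np.isfinite(t)
    s[bad] = 1.0 / 3.0
    t[bad] = 1.0 / 3.0
    if clamp:
        # clip barycentrics (u, s, t) with u = 1 - s - t into the triangle
        s = np.clip(s, 0.0, 1.0)
        t = np.clip(t, 0.0, 1.0)
        over = s + t > 1.0
        tot = s[over] + t[over]
        s[over] /= tot
        t[over] /= tot
    return a + s[:, None] * ab + t[:, None] * ac


def _tri_area(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(np.cross(q - p, r - p), axis=1)


def triangle_quadrangle_areas(points: np.ndarray, simplices: np.ndarray
                              ) -> np.ndarray:
    """Per-triangle, per-vertex quadrangle areas.

    Each triangle is divided into three quadrangles by joining the (clamped)
    circumcenter to the three edge midpoints; the quadrangle containing
    vertex k of simplex f has area ``out[f, k]``. The three areas of a
    triangle always sum to the triangle area (exact partition).
    """
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    o = _triangle_circumcenters(a, b, c)
    mab = 0.5 * (a + b)
    mbc = 0.5 * (b + c)
    mca = 0.5 * (c + a)
    qa = _tri_area(a, mab, o) + _tri_area(a, o, mca)
    qb = _tri_area(b, mbc, o) + _tri_area(b, o, mab)
    qc = _tri_area(c, mca, o) + _tri_area(c, o, mbc)
    return np.stack([qa, qb, qc], axis=1)


def voronoi_density(points: np.ndarray, sph: Spheroid | None = None,
                    min_separation: float = 1e-9) -> NeighborGraph:
    """Surface Voronoi areas and densities of a convex-position point cloud.

    Parameters
    ----------
    points : (N, 3) array
        Cloud on (or very near) the spheroid surface, N >= 4, no duplicates.
    sph : Spheroid, optional
        Unused for the construction itself (the hull works on the raw
        cloud); accepted for interface symmetry with the other operations.

    Returns
    -------
    NeighborGraph with per-node Voronoi area ``s`` and density ``rho = 1/s``.
    """
    points = np.asarray(points, float)
    if len(points) < 4:
        raise GeometryError("need at least 4 points")
    hull = hull_triangulation(points)
    simplices = hull.simplices
    quads = triangle_quadrangle_areas(points, simplices)
    areas = np.zeros(len(points))
    np.add.at(areas, simplices.ravel(), quads.ravel())
    if np.any(areas <= 0):
        raise GeometryError("degenerate (collinear or duplicate) points")
    edges = hull_edges(simplices)
    # duplicate guard only on actual neighbor pairs (cheap)
    d = np.linalg.norm(points[edges[:, 0]] - points[edges[:, 1]], axis=1)
    if np.any(d <= min_separation):
        raise GeometryError("duplicate points (pairwise distance <= 1e-9)")
    return NeighborGraph(
        n_nodes=len(points),
        edges=edges,
        areas=areas,
        density=1.0 / areas,
        simplices=simplices,
        total_area=float(quads.sum()),
    )


def meridian_frame(p: np.ndarray, sph: Spheroid) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent frame at surface point(s) ``p``.

    ``e1`` is the tangent of the AP meridian through the point (the
    reference direction for bond angles) and ``e2 = n x e1`` completes the
    right-handed frame. Undefined at the poles.
    """
    theta, phi = sph.to_angles(p)
    # at the poles the parallel circle degenerates and phi is arbitrary,
    # so no unique meridian direction exists
    if np.any(np.abs(np.sin(theta)) < 1e-9):
        raise GeometryError("meridian frame undefined at the poles")
    # d/dtheta of from_angles, normalised
    e1 = np.stack(
        [
            -sph.semi_major * np.sin(theta),
            sph.semi_minor * np.cos(theta) * np.cos(phi),
            sph.semi_minor * np.cos(theta) * np.sin(phi),
        ],
        axis=-1,
    )
    norm = np.linalg.norm(e1, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise GeometryError("meridian frame undefined at the poles")
    e1 = e1 / norm
    e2 = np.cross(sph.normal(p), e1)
    return e1, e2


def pole_flags(points: np.ndarray, sph: Spheroid, frac: float = 0.02
               ) -> np.ndarray:
    """Boolean mask of points within ``frac`` EL of either pole (these join
    the triangulation but are excluded from pole-sensitive metrics)."""
    el = ap_fraction(points, sph, check=False)
    return (el < frac) | (el > 1.0 - frac)


def reynolds_number(speed_um_s: float = 0.13, length_um: float = 150.0,
                    kinematic_viscosity_um2_s: float = 3e6) -> float:
    """Reynolds number U L / nu for nuclear motion in the embryo.

    Defaults: typical nuclear speed 0.13 um/s, embryo minor axis 150 um,
    kinematic viscosity of water 3e6 um^2/s, giving ~6.5e-6 — firmly in the
    overdamped regime where inertia is negligible.
    """
    return speed_um_s * length_um / kinematic_viscosity_um2_s
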