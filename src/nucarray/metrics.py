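"""Collective-behavior statistics of the nuclear array.

Implements the analysis layer shared by experimental-style trajectory
tables and simulator output: AP-projected speeds, density and speed
kymographs (AP bin x time heat maps), the hexatic bond-orientational order
parameter phi_array, the collective-motion order parameter phi_speed, the
pole/middle density ratio, the standing-wave damping statistic (wave peak
ratio), the middle-node position, anaphase-onset detection from the density
gradient, and relative Voronoi-area (cell deformation) maps.

Conventions: AP positions are EL fractions in [0, 1] with half-open bins
covering the axis; speeds are backward differences, positive toward the
posterior pole; the two 5%-EL end bins never enter the pole density
regions (pole-cell confound), and standing-wave crest statistics are
restricted to the 15-85% EL band where the wave's antinodes live (the
pole-adjacent strips carry the monotone contraction flux instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .geometry import Spheroid, ap_fraction, meridian_frame, voronoi_density
from .simulator import Trajectory


@dataclass
class HeatMap:
    """(AP bin x time) matrix with bin metadata. ``values[b, k]`` is the
    per-bin mean at ``times[k]``; NaN where the bin is empty."""

    values: np.ndarray
    bin_edges: np.ndarray
    times: np.ndarray
    quantity: str

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def time_slice(self, t0: float | None = None, t1: float | None = None
                   ) -> "HeatMap":
        t = self.times
        mask = np.ones(len(t), bool)
        if t0 is not None:
            mask &= t >= t0
        if t1 is not None:
            mask &= t <= t1
        return HeatMap(self.values[:, mask], self.bin_edges, t[mask],
                       self.quantity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.bin_centers,
                            columns=self.times)


def el_bins(width: float) -> np.ndarray:
    n = int(round(1.0 / width))
    return np.linspace(0.0, 1.0, n + 1)


def _bin_index(el: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [lo, hi) bin index; the last bin also takes el == 1."""
    idx = np.searchsorted(edges, el, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def binned_mean(el: np.ndarray, values: np.ndarray, edges: np.ndarray
                ) -> np.ndarray:
    idx = _bin_index(el, edges)
    n = len(edges) - 1
    sums = np.bincount(idx, weights=values, minlength=n)
    counts = np.bincount(idx, minlength=n)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


# -- speeds -----------------------------------------------------------------


def ap_speed(traj: Trajectory, dt_obs: float | None = None) -> pd.DataFrame:
    """Backward-difference AP speed per nucleus, v(t) = (x(t) - x(t-dt))/dt.

    ``dt_obs`` must match an integer number of logged frame strides
    (default: one stride). Newly divided nuclei are missing at t - dt and
    yield no row. Columns: t, id, el, v (um per time unit), plus the raw
    AP coordinate x.
    """
    times = np.asarray(traj.times)
    if len(times) < 2:
        raise ValueError("need at least two frames")
    frame_dt = times[1] - times[0]
    stride = 1 if dt_obs is None else int(round(dt_obs / frame_dt))
    if dt_obs is not None and abs(stride * frame_dt - dt_obs) > 1e-9 * max(
            1.0, abs(dt_obs)):
        raise ValueError("dt_obs must be an integer number of frame strides")
    if stride < 1:
        raise ValueError("dt_obs smaller than the frame interval")
    sph = traj.spheroid
    chunks = []
    for k in range(stride, len(times)):
        cur, prev = traj.frames[k], traj.frames[k - stride]
        dt = times[k] - times[k - stride]
        common, ic, ip = np.intersect1d(cur.ids, prev.ids,
                                        return_indices=True)
        if len(common) == 0:
            continue
        x = cur.positions[ic, 0]
        el = ap_fraction(cur.positions[ic], sph, check=False)
        v = (x - prev.positions[ip, 0]) / dt
        chunks.append(pd.DataFrame(
            {"t": times[k], "id": common, "el": el, "x": x, "v": v}
        ))
    if not chunks:
        raise ValueError("no nucleus persists across any frame pair")
    return pd.concat(chunks, ignore_index=True)


# -- heat maps --------------------------------------------------------------


def heatmaps(traj: Trajectory, density_bin: float = 0.10,
             speed_bin: float = 0.05, speed_dt: float | None = None
             ) -> dict[str, HeatMap]:
    """Density and AP-speed kymographs.

    Density uses the surface Voronoi areas (rho = 1/s) averaged in
    ``density_bin``-wide EL bins; speed averages the per-nucleus backward
    difference in ``speed_bin``-wide bins.
    """
    sph = traj.spheroid
    times = np.asarray(traj.times)
    d_edges = el_bins(density_bin)
    dens = np.full((len(d_edges) - 1, len(times)), np.nan)
    for k, frame in enumerate(traj.frames):
        graph = voronoi_density(frame.positions)
        el = ap_fraction(frame.positions, sph, check=False)
        dens[:, k] = binned_mean(el, graph.density, d_edges)
    out = {"density": HeatMap(dens, d_edges, times, "density")}

    tab = ap_speed(traj, speed_dt)
    s_edges = el_bins(speed_bin)
    s_times = np.unique(tab["t"].to_numpy())
    speed = np.full((len(s_edges) - 1, len(s_times)), np.nan)
    for k, t in enumerate(s_times):
        sub = tab[tab["t"] == t]
        speed[:, k] = binned_mean(sub["el"].to_numpy(), sub["v"].to_numpy(),
                                  s_edges)
    out["ap_speed"] = HeatMap(speed, s_edges, s_times, "ap_speed")
    return out


# -- order parameters -------------------------------------------------------


def phi_array(points: np.ndarray, sph: Spheroid, graph=None,
              return_per_nucleus: bool = False):
    """Hexatic bond-orientational order parameter.

    Per nucleus j, the magnitude of the mean 6-fold phase of the bond
    angles to its Voronoi neighbors, measured in the local tangent plane
    against the AP-meridian tangent; phi_array is the average over nuclei.
    The per-nucleus magnitude is invariant to the reference direction.
    Nuclei with fewer than 2 neighbors and nuclei at the poles (where the
    meridian frame is undefined) are excluded.
    """
    points = np.asarray(points, float)
    n = len(points)
    if n < 7:
        raise ValueError("need at least 7 points")
    if graph is None:
        graph = voronoi_density(points)
    theta, _ = sph.to_angles(points)
    ok = np.sin(theta) > 1e-6
    e1 = np.zeros_like(points)
    e2 = np.zeros_like(points)
    if np.any(ok):
        e1[ok], e2[ok] = meridian_frame(points[ok], sph)
    edges = graph.edges
    directed = np.concatenate([edges, edges[:, ::-1]])
    j, i = directed[:, 0], directed[:, 1]
    bond = points[i] - points[j]
    ang = np.arctan2(np.sum(bond * e2[j], axis=1),
                     np.sum(bond * e1[j], axis=1))
    acc = np.zeros(n, complex)
    np.add.at(acc, j, np.exp(6j * ang))
    cnt = np.bincount(j, minlength=n)
    include = ok & (cnt >= 2)
    per = np.full(n, np.nan)
    per[include] = np.abs(acc[include]) / cnt[include]
    value = float(np.nanmean(per[include])) if np.any(include) else np.nan
    if return_per_nucleus:
        return value, per
    return value


def phi_speed(velocities: np.ndarray, v_max: float | None = None
              ) -> tuple[float, float]:
    """Collective-motion order parameters (phi_speed, phi_speed_prime).

    phi_speed_prime = |sum v_i| / (N v0) with v0 the mean speed;
    phi_speed rescales by v0 / v_max so it compares magnitudes against the
    maximal speed over all nuclei and times (pass ``v_max`` for a global
    maximum; defaults to this sample's maximum). Both are 0 for balanced or
    all-zero velocity sets.
    """
    v = np.atleast_2d(np.asarray(velocities, float))
    n = len(v)
    mags = np.linalg.norm(v, axis=1)
    v0 = mags.mean()
    if v0 == 0:
        return 0.0, 0.0
    vm = float(v_max) if v_max is not None else float(mags.max())
    total = float(np.linalg.norm(v.sum(axis=0)))
    prime = total / (n * v0)
    return total / (n * vm), prime


# -- density ratio and standing-wave statistics ------------------------------


def _region_bins(edges: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indices of bins entirely inside [lo, hi]."""
    return np.flatnonzero((edges[:-1] >= lo - 1e-9) & (edges[1:] <= hi + 1e-9))


def stable_interphase_window(speed_hm: HeatMap, half_cycle: float = 0.5,
                             trim: float = 0.10) -> tuple[float, float]:
    """Half-cycle window minimizing the mean |AP speed| (the stable
    interphase), trimmed by ``trim`` at both ends."""
    t = speed_hm.times
    mean_abs = np.nanmean(np.abs(speed_hm.values), axis=0)
    width = half_cycle
    best, best_t0 = np.inf, t[0]
    for t0 in t:
        if t0 + width > t[-1] + 1e-9:
            break
        sel = (t >= t0) & (t <= t0 + width)
        m = float(np.nanmean(mean_abs[sel]))
        if m < best:
            best, best_t0 = m, t0
    pad = trim * width
    return best_t0 + pad, best_t0 + width - pad


def density_ratio(density_hm: HeatMap, window: tuple[float, float],
                  pole_lo: tuple[float, float] = (0.05, 0.15),
                  pole_hi: tuple[float, float] = (0.85, 0.95),
                  middle: tuple[float, float] = (0.15, 0.85)
                  ) -> tuple[float, float]:
    """(anterior, posterior) pole-to-middle density ratios.

    Mean pole-region density divided by the maximal middle-region density,
    computed on the time-averaged profile over the interphase window. The
    0-5% and 95-100% EL bins never enter the pole regions.
    """
    hm = density_hm.time_slice(*window)
    profile = np.nanmean(hm.values, axis=1)
    edges = hm.bin_edges
    ant = _region_bins(edges, *pole_lo)
    post = _region_bins(edges, *pole_hi)
    mid = _region_bins(edges, *middle)
    if len(ant) == 0 or len(post) == 0 or np.all(np.isnan(profile[ant])) \
            or np.all(np.isnan(profile[post])):
        raise ValueError("empty pole bins")
    mid_max = np.nanmax(profile[mid])
    return (float(np.nanmean(profile[ant]) / mid_max),
            float(np.nanmean(profile[post]) / mid_max))


def _band_mask(hm: HeatMap, band: tuple[float, float]) -> np.ndarray:
    """Mask of bins whose centers fall strictly inside an EL band."""
    c = hm.bin_centers
    return (c > band[0]) & (c < band[1])


#: EL band used for standing-wave crest statistics. The standing wave has
#: nodes at the poles and the middle, so its antinodes sit near 25% and
#: 75% EL; the pole-adjacent strips instead carry the monotone pole-ward
#: contraction flux (which never reverses sign) and must not be mistaken
#: for a crest.
WAVE_BAND = (0.15, 0.85)


@dataclass
class Crest:
    """Standing-wave crest analysis of one bin's speed series: the peak of
    the first lobe, the zero crossing after it, and the maximal |speed| of
    the first opposite-sign lobe. ``score`` is the smaller lobe amplitude —
    a genuine crest oscillates, so both lobes must be substantial."""

    bin: int
    sign: int           # sign of the first lobe
    k_peak: int
    k_cross: int        # first frame of the opposite-sign lobe
    first: float        # |peak| of the first lobe
    second: float       # max |speed| of the opposite-sign lobe
    score: float


def _crest_analysis(vals: np.ndarray) -> list:
    """Per-bin crest analysis of a (bins x times) speed matrix. Bins whose
    series never reverses sign after its peak (e.g. the monotone pole-ward
    contraction flux) yield no crest."""
    out = []
    for b, s in enumerate(vals):
        if np.all(np.isnan(s)):
            continue
        k = int(np.nanargmax(np.abs(s)))
        peak = float(s[k])
        sgn = np.sign(peak)
        if sgn == 0:
            continue
        rest_sign = np.sign(s[k + 1:])
        opp = np.flatnonzero(rest_sign == -sgn)
        if len(opp) == 0:
            continue
        i0 = opp[0]
        back = np.flatnonzero(rest_sign[i0:] == sgn)
        i1 = i0 + back[0] if len(back) else len(rest_sign)
        lobe2 = float(np.nanmax(np.abs(s[k + 1 + i0:k + 1 + i1])))
        out.append(Crest(bin=b, sign=int(sgn), k_peak=k, k_cross=k + 1 + i0,
                         first=abs(peak), second=lobe2,
                         score=min(abs(peak), lobe2)))
    return out


def wave_peak_ratio(speed_hm: HeatMap, t_start: float | None = None,
                    band: tuple[float, float] = WAVE_BAND) -> float:
    """Maximal wave crest of the second half period of the AP-speed
    standing wave divided by that of the first half period.

    A standing-wave crest oscillates: its speed series peaks (first half
    period, motion toward the pole), crosses zero, and peaks with the
    opposite sign (second half period, motion back). The dominant crest is
    the bin in the wave band with the largest two-lobe score; bins
    carrying the monotone pole-ward contraction flux have no genuine
    second lobe and score ~0, so they never win even when their |speed| is
    larger than the wave's. Returns second-lobe over first-lobe amplitude
    of the dominant crest.
    """
    hm = speed_hm if t_start is None else speed_hm.time_slice(t0=t_start)
    vals = np.where(_band_mask(hm, band)[:, None], hm.values, np.nan)
    if np.all(np.isnan(vals)):
        raise ValueError("empty speed map")
    crests = _crest_analysis(vals)
    if not crests:
        raise ValueError("no standing wave: no crest in the band reverses")
    best = max(crests, key=lambda c: c.score)
    return best.second / best.first


def node_position(speed_hm: HeatMap, window: tuple[float, float] | None = None,
                  band: tuple[float, float] = WAVE_BAND) -> float:
    """EL position of the middle node of the standing wave.

    The two antinodes are the dominant oscillating crests with opposite
    first-lobe signs (the two AP domains move in counter-phase). The node
    is the sign change of the AP displacement integrated over the first
    half period between the two antinode bins; restricting the
    integration to the first half period and the search to the
    inter-antinode segment keeps the monotone contraction flux out of the
    estimate."""
    hm = speed_hm if window is None else speed_hm.time_slice(*window)
    vals = np.where(_band_mask(hm, band)[:, None], hm.values, np.nan)
    crests = _crest_analysis(vals)
    neg = [c for c in crests if c.sign < 0]
    pos = [c for c in crests if c.sign > 0]
    if not neg or not pos:
        raise ValueError("fewer than 2 counter-moving domains")
    c_neg = max(neg, key=lambda c: c.score)
    c_pos = max(pos, key=lambda c: c.score)
    if c_neg.bin == c_pos.bin:
        raise ValueError("fewer than 2 counter-moving domains")
    b_lo, b_hi = sorted((c_neg.bin, c_pos.bin))
    k_end = min(c_neg.k_cross, c_pos.k_cross)
    t = hm.times
    disp = np.nansum(vals[:, :k_end - 1] * np.diff(t[:k_end])[None, :],
                     axis=1)
    seg = disp[b_lo:b_hi + 1]
    segc = hm.bin_centers[b_lo:b_hi + 1]
    s_lo = np.sign(seg[0])
    if s_lo == 0:
        raise ValueError("vanishing displacement at the antinode")
    idx = np.flatnonzero((np.sign(seg[:-1]) == s_lo)
                         & (np.sign(seg[1:]) == -s_lo))
    if len(idx) == 0:
        raise ValueError("no sign change between the domains")
    a = idx[-1]  # crossing adjacent to the far domain
    f = -seg[a] / (seg[a + 1] - seg[a])
    return float(segc[a] + f * (segc[a + 1] - segc[a]))


def onset_times(density_hm: HeatMap, window: tuple[float, float] | None = None,
                smooth: bool = True) -> pd.DataFrame:
    """Per-AP-bin anaphase-onset times from the density gradient.

    Division doubles the local density, so the time of maximal temporal
    density gradient marks the metaphase-anaphase transition in each bin;
    the onsets are then smoothed along AP with a (generalized
    cross-validated) smoothing spline. Columns: bin_center, t_raw, t_onset.
    """
    hm = density_hm if window is None else density_hm.time_slice(*window)
    t = hm.times
    if len(t) < 3:
        raise ValueError("density map spans too few frames")
    grad = np.gradient(hm.values, t, axis=1)
    valid = np.any(np.isfinite(grad), axis=1)
    if not valid.any() or not np.any(
            np.nanmax(grad[valid], axis=1) > 0):
        raise ValueError("no division detected in range")
    centers = hm.bin_centers
    raw = np.full(len(centers), np.nan)
    masked = np.where(np.isnan(grad[valid]), -np.inf, grad[valid])
    raw[valid] = t[np.argmax(masked, axis=1)]
    if smooth and valid.sum() >= 5 and np.ptp(raw[valid]) > 0:
        # fit along AP on the bins with data; evaluating the spline at all
        # centers also fills bins where no division was observable
        spl = make_smoothing_spline(centers[valid], raw[valid])
        fitted = spl(centers)
    else:
        fitted = raw.copy()
    return pd.DataFrame(
        {"bin_center": centers, "t_raw": raw, "t_onset": fitted}
    )


def area_variation(traj: Trajectory, ref_time: float,
                   bin_width: float = 0.10) -> HeatMap:
    """Relative Voronoi-area change (s(t) - s_ref) / s_ref per AP bin.

    Each nucleus's reference area is taken at the first logged frame at or
    after ``ref_time`` in which it exists (newly divided nuclei are
    referenced to their own first appearance); nuclei absent at the
    reference are excluded until they appear.
    """
    sph = traj.spheroid
    times = np.asarray(traj.times)
    start = int(np.searchsorted(times, ref_time - 1e-12))
    if start >= len(times):
        raise ValueError("reference time beyond the trajectory")
    edges = el_bins(bin_width)
    ref: dict[int, float] = {}
    cols = []
    for k in range(start, len(times)):
        frame = traj.frames[k]
        graph = voronoi_density(frame.positions)
        el = ap_fraction(frame.positions, sph, check=False)
        rel = np.full(len(frame.ids), np.nan)
        for m, nid in enumerate(frame.ids.tolist()):
            s0 = ref.setdefault(nid, float(graph.areas[m]))
            rel[m] = (graph.areas[m] - s0) / s0
        cols.append(binned_mean(el, rel, edges))
    return HeatMap(np.array(cols).T, edges, times[start:], "area_variation")
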