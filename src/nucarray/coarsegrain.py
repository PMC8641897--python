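"""1D coarse-graining of the nuclear array into "array units".

Collective motion and packing are predominantly along the AP axis, so the
3D per-nucleus data are reduced to a 1D chain of nuclear array units: all
nuclei inside a ~5% EL bin form one unit carrying the mean density rho
(um^-2, inverse Voronoi area), mean age tau, mean AP velocity V, and the
AP mass-center position. The per-bin means are smoothed along AP with a
generalized-cross-validated smoothing spline. The two pole units are
flagged as fixed and excluded from model fitting.

Ages for training are measured relative to the local anaphase onset: the
bins the mitotic wave has not yet reached carry *negative* ages (time
until T = 0) rather than the accumulated age of the old cycle, so the
pair-mean age stays continuous across the wavefront.

Features destined for the network are rescaled by x * n / (max - min)
with n = 100, which gives the density and age inputs comparable ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .geometry import ap_fraction, voronoi_density
from .metrics import ap_speed, el_bins, _bin_index
from .simulator import Trajectory

UNIT_COLUMNS = ["t", "bin", "x_el", "x_um", "rho", "tau", "V", "n", "circ",
                "excluded"]


@dataclass
class Dataset1D:
    """Coarse-grained unit table plus the feature normalization spec.

    ``units`` has one row per (time, AP bin); ``scales`` maps feature name
    to the multiplicative factor n / (max - min) applied before training.
    """

    units: pd.DataFrame
    n: float = 100.0
    scales: dict = field(default_factory=dict)

    def interior(self) -> pd.DataFrame:
        return self.units[~self.units["excluded"]]


def bin_units(positions: np.ndarray, density: np.ndarray, ages: np.ndarray,
              speeds: np.ndarray, sph, t: float = 0.0,
              bin_width: float = 0.05, smooth: bool = True,
              strict: bool = True) -> pd.DataFrame:
    """Coarse-grain one frame into ordered AP array units.

    ``density``/``ages``/``speeds`` are per-nucleus; speeds may contain NaN
    (e.g. newly divided nuclei) which are ignored in the per-bin mean.
    Raises if an interior bin is empty unless ``strict`` is off, in which
    case the gap is recorded as an excluded unit (small arrays can leave
    near-pole bins transiently unpopulated).
    """
    edges = el_bins(bin_width)
    nbins = len(edges) - 1
    el = ap_fraction(positions, sph, check=False)
    idx = _bin_index(el, edges)
    a, bb = sph.semi_major, sph.semi_minor

    def circumference(x_um):
        # latitude circle length at AP position x (transverse section)
        return float(2 * np.pi * bb
                     * np.sqrt(max(1.0 - (x_um / a) ** 2, 0.0)))

    rows = []
    for b in range(nbins):
        sel = idx == b
        if not np.any(sel):
            if strict and 0 < b < nbins - 1:
                raise ValueError(f"empty interior bin {b}")
            rows.append((t, b, np.nan, np.nan, np.nan, np.nan, np.nan,
                         0, np.nan, True))
            continue
        v = speeds[sel]
        v = v[np.isfinite(v)]
        x_um = float(positions[sel, 0].mean())
        rows.append((
            t, b, float(el[sel].mean()), x_um,
            float(density[sel].mean()), float(ages[sel].mean()),
            float(v.mean()) if len(v) else np.nan,
            int(sel.sum()), circumference(x_um),
            b in (0, nbins - 1),
        ))
    df = pd.DataFrame(rows, columns=UNIT_COLUMNS)
    if smooth:
        ok = df["x_el"].notna()
        x = df.loc[ok, "x_el"].to_numpy()
        if len(x) >= 5:
            for col in ("rho", "tau", "V"):
                y = df.loc[ok, col].to_numpy()
                good = np.isfinite(y)
                if good.sum() >= 5 and np.ptp(y[good]) > 0:
                    spl = make_smoothing_spline(x[good], y[good])
                    df.loc[ok, col] = spl(x)
    return df


def coarse_grain(traj: Trajectory, bin_width: float = 0.05,
                 smooth: bool = True, speed_dt: float | None = None,
                 t_min: float | None = None, t_max: float | None = None
                 ) -> Dataset1D:
    """Coarse-grain a trajectory into a :class:`Dataset1D`.

    Unit velocity is the mean of the member nuclei's backward-difference AP
    speeds; the first logged frame therefore yields no units. Ages are the
    raw simulation ages; call :func:`assign_ages` to re-reference them to
    the local anaphase onset before training. Interior bins left empty in
    a frame (possible in scaled-down runs) become excluded gap units.
    """
    sph = traj.spheroid
    speeds = ap_speed(traj, speed_dt)
    by_t = dict(tuple(speeds.groupby("t")))
    tables = []
    for k, t in enumerate(traj.times):
        if t not in by_t:
            continue
        if t_min is not None and t < t_min:
            continue
        if t_max is not None and t > t_max:
            continue
        frame = traj.frames[k]
        graph = voronoi_density(frame.positions)
        sub = by_t[t].set_index("id")["v"]
        v = sub.reindex(frame.ids).to_numpy()
        tables.append(bin_units(frame.positions, graph.density, frame.ages,
                                v, sph, t=t, bin_width=bin_width,
                                smooth=smooth, strict=False))
    if not tables:
        raise ValueError("no frames to coarse-grain")
    return Dataset1D(units=pd.concat(tables, ignore_index=True))


def normalize(values: np.ndarray, n: float = 100.0
              ) -> tuple[np.ndarray, float]:
    """Rescale a feature by n / (max - min); returns (scaled, scale).

    Invertible given the scale; raises on a constant feature.
    """
    values = np.asarray(values, float)
    span = np.nanmax(values) - np.nanmin(values)
    if span == 0:
        raise ValueError("constant feature cannot be normalized")
    scale = n / span
    return values * scale, float(scale)


def normalize_dataset(ds: Dataset1D, features: tuple = ("rho", "tau"),
                      n: float = 100.0) -> Dataset1D:
    """Attach normalization scales for the given features (the raw columns
    are kept; scaling is applied when building network inputs)."""
    scales = {}
    for col in features:
        _, scales[col] = normalize(ds.units[col].to_numpy(), n)
    return Dataset1D(units=ds.units, n=n, scales=scales)


def assign_ages(ds: Dataset1D, onsets: pd.DataFrame) -> Dataset1D:
    """Re-reference unit ages to the local anaphase onset.

    tau = t - t_onset(bin); bins ahead of the mitotic wavefront get
    negative ages so that neighboring-unit age means stay continuous
    across the front. ``onsets`` must cover every non-excluded bin
    (columns ``bin_center`` ordered like the unit bins, ``t_onset``).
    """
    units = ds.units.copy()
    edges = el_bins(1.0 / (units["bin"].max() + 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    lookup = {}
    for _, row in onsets.iterrows():
        b = int(np.argmin(np.abs(centers - row["bin_center"])))
        lookup[b] = row["t_onset"]
    missing = set(units.loc[~units["excluded"], "bin"]) - set(lookup)
    if missing:
        raise ValueError(f"onset missing for bins {sorted(missing)}")
    onset_col = units["bin"].map(lookup)
    units["tau"] = units["t"] - onset_col
    return Dataset1D(units=units, n=ds.n, scales=ds.scales)
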