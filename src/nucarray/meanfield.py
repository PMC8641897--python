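"""Deterministic 1D mean-field cross-check: effective pressure profile.

The overdamped momentum balance along the AP axis,

    gamma_tilde v(x, t) = - dp/dx,

is integrated in x at each time to an effective pressure profile (defined
up to an additive constant per time, fixed here by a zero-spatial-mean
convention). Co-registered (p, rho, tau) samples are then binned on a
(rho, tau) grid, yielding an empirical equation of state p(rho, tau) and
its marginal p-tau curve. On data generated by the age-pulsed attractive
field, pressure depends predominantly on age — a single negative pulse —
while the density dependence is subtle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid


@dataclass
class PressureProfile:
    x: np.ndarray        # regular AP grid (um or EL)
    times: np.ndarray
    p: np.ndarray        # (len(x), len(times)), zero spatial mean per time


def pressure_profile(v: np.ndarray, x: np.ndarray, times: np.ndarray,
                     gamma_tilde: float = 1.0) -> PressureProfile:
    """Integrate -gamma_tilde * v along a regular AP grid (trapezoid rule).

    ``v`` is (len(x), len(times)). The additive constant is fixed per time
    by removing the spatial mean.
    """
    x = np.asarray(x, float)
    v = np.asarray(v, float)
    dx = np.diff(x)
    if len(x) < 2 or not np.allclose(dx, dx[0], rtol=1e-6):
        raise ValueError("AP grid must be regular")
    p = -gamma_tilde * cumulative_trapezoid(v, x, axis=0, initial=0.0)
    p = p - p.mean(axis=0, keepdims=True)
    return PressureProfile(x=x, times=np.asarray(times, float), p=p)


@dataclass
class EquationOfState:
    rho_edges: np.ndarray
    tau_edges: np.ndarray
    p_surface: np.ndarray       # (n_rho, n_tau) mean p, NaN where empty
    counts: np.ndarray
    tau_centers: np.ndarray
    p_tau: np.ndarray           # marginal mean p per tau bin
    p_tau_sd: np.ndarray


def equation_of_state(p: np.ndarray, rho: np.ndarray, tau: np.ndarray,
                      n_bins: int = 20) -> EquationOfState:
    """Bin co-registered (p, rho, tau) samples on a (rho, tau) grid.

    Returns the binned pressure surface (empty bins masked as NaN) and the
    marginal p-tau curve with per-bin standard deviations.
    """
    p = np.asarray(p, float).ravel()
    rho = np.asarray(rho, float).ravel()
    tau = np.asarray(tau, float).ravel()
    ok = np.isfinite(p) & np.isfinite(rho) & np.isfinite(tau)
    p, rho, tau = p[ok], rho[ok], tau[ok]
    r_edges = np.linspace(rho.min(), rho.max() * (1 + 1e-12), n_bins + 1)
    t_edges = np.linspace(tau.min(), tau.max() * (1 + 1e-12), n_bins + 1)
    ri = np.clip(np.searchsorted(r_edges, rho, side="right") - 1, 0, n_bins - 1)
    ti = np.clip(np.searchsorted(t_edges, tau, side="right") - 1, 0, n_bins - 1)
    flat = ri * n_bins + ti
    sums = np.bincount(flat, weights=p, minlength=n_bins * n_bins)
    cnt = np.bincount(flat, minlength=n_bins * n_bins)
    with np.errstate(invalid="ignore"):
        surf = (sums / cnt).reshape(n_bins, n_bins)
    surf[cnt.reshape(n_bins, n_bins) == 0] = np.nan

    t_sums = np.bincount(ti, weights=p, minlength=n_bins)
    t_sq = np.bincount(ti, weights=p * p, minlength=n_bins)
    t_cnt = np.bincount(ti, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = t_sums / t_cnt
        sd = np.sqrt(np.maximum(t_sq / t_cnt - mean**2, 0.0))
    mean[t_cnt == 0] = np.nan
    sd[t_cnt == 0] = np.nan
    return EquationOfState(
        rho_edges=r_edges, tau_edges=t_edges, p_surface=surf,
        counts=cnt.reshape(n_bins, n_bins),
        tau_centers=0.5 * (t_edges[:-1] + t_edges[1:]),
        p_tau=mean, p_tau_sd=sd,
    )


def variance_explained(eos: EquationOfState) -> tuple[float, float]:
    """Between-bin variance of the binned pressure along tau vs along rho
    (marginal means weighted by counts). On age-pulse-driven data the tau
    component dominates."""
    surf, cnt = eos.p_surface, eos.counts
    w = cnt.astype(float)
    tot = np.nansum(w)

    def axis_var(axis):
        with np.errstate(invalid="ignore"):
            m = np.nansum(np.where(np.isnan(surf), 0, surf) * w, axis=axis) \
                / np.maximum(w.sum(axis=axis), 1e-12)
        wax = w.sum(axis=axis)
        grand = np.nansum(m * wax) / tot
        return float(np.nansum(wax * (m - grand) ** 2) / tot)

    return axis_var(0), axis_var(1)  # (along tau, along rho)
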