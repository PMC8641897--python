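"""End-to-end protocols tying the modules together.

These are the canonical study conditions: an ensemble of seeded runs of
the particle-based model on the 5:1.5 prolate spheroid with the default
age-pulsed attractive force field and synchronous two-pole mitotic waves,
from which the headline collective statistics (pole density ratios, wave
peak ratio) and the closed-loop force-field recovery are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import metrics as mx
from .coarsegrain import Dataset1D, assign_ages, coarse_grain, normalize_dataset
from .forcefields import FieldKind, ForceFieldParams, pair_force_magnitude
from .forcelearn import (
    MLFNNSpec,
    Orientation,
    RecoveryReport,
    compare_to_truth,
    train,
)
from .simulator import SimConfig, Trajectory, run


def headline_config(n_initial: int = 400, seed: int = 0, **overrides
                    ) -> SimConfig:
    """The reference simulation protocol: default force parameters, one
    division round (N doubles), two synchronous pole waves."""
    cfg = SimConfig(n_initial=n_initial, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class RunStats:
    anterior: float
    posterior: float
    wave_peak_ratio: float
    node_position: float | None
    first_division: float
    traj: Trajectory


def collective_stats(config: SimConfig, keep_traj: bool = False) -> RunStats:
    """Run one simulation and measure the headline collective statistics."""
    traj = run(config)
    dens5 = mx.heatmaps(traj, density_bin=0.05)["density"]
    speed = mx.heatmaps(traj)["ap_speed"]
    t_div = traj.divisions[0][0] if traj.divisions else None
    window = mx.stable_interphase_window(speed.time_slice(t0=t_div))
    ant, post = mx.density_ratio(dens5, window)
    wpr = mx.wave_peak_ratio(speed, t_start=t_div)
    try:
        node = mx.node_position(speed.time_slice(t0=t_div, t1=window[0]))
    except ValueError:
        node = None
    return RunStats(
        anterior=ant, posterior=post, wave_peak_ratio=wpr,
        node_position=node, first_division=t_div if t_div is not None else np.nan,
        traj=traj if keep_traj else None,
    )


def ensemble_stats(n_initial: int, seeds, **overrides) -> dict:
    """Medians of the collective statistics over seeded replicate runs."""
    ant, post, wpr = [], [], []
    for s in seeds:
        stats = collective_stats(headline_config(n_initial=n_initial,
                                                 seed=int(s), **overrides))
        ant.append(stats.anterior)
        post.append(stats.posterior)
        wpr.append(stats.wave_peak_ratio)
    med_a, med_p = float(np.median(ant)), float(np.median(post))
    return {
        "anterior_median": med_a,
        "posterior_median": med_p,
        "smaller_pole_median": min(med_a, med_p),
        "larger_pole_median": max(med_a, med_p),
        "wave_peak_ratio_median": float(np.median(wpr)),
        "anterior": ant, "posterior": post, "wave_peak_ratio": wpr,
    }


def training_dataset(traj: Trajectory, t_min: float | None = None,
                     t_max: float | None = None) -> Dataset1D:
    """Coarse-grain a run into the normalized training substrate with
    onset-referenced (negative-beyond-the-wavefront) ages."""
    dens5 = mx.heatmaps(traj, density_bin=0.05)["density"]
    onsets = mx.onset_times(dens5)
    ds = coarse_grain(traj, t_min=t_min, t_max=t_max)
    ds = assign_ages(ds, onsets)
    # clip ages below one cycle before the local onset (pre-relaxation tail)
    ds.units.loc[ds.units["tau"] < -1.0, "tau"] = -1.0
    return normalize_dataset(ds)


def recovery_test(seed: int = 0, kind: str | FieldKind = FieldKind.attr_linear,
                  spec: MLFNNSpec = MLFNNSpec(), n_steps: int = 3000,
                  config: SimConfig | None = None,
                  net_seed: int | None = None) -> RecoveryReport:
    """Closed-loop ground-truth recovery on a simulated array.

    Simulates with a known force field, coarse-grains, trains the network
    under the matching orientation convention (Fa for attractive truth,
    Fr for repulsive truth) and compares the learned F(T, r) grid with the
    generating field: grid Pearson correlation, pulse-peak age offset,
    distance-slope sign and pointwise sign agreement.

    The default ``config`` is a full-size 400-nucleus run; pass a smaller
    configuration (e.g. :func:`nucarray.fixtures.mini_embryo`) for faster,
    noisier checks. ``net_seed`` controls the training initialization
    independently of the simulation seed (defaults to ``seed``).
    """
    kind = FieldKind(kind)
    params = ForceFieldParams(kind=kind)
    if config is None:
        config = SimConfig(seed=seed, n_initial=400, sim_time=1.15,
                           force=params)
    traj = run(config)
    ds = training_dataset(traj, t_min=0.05)
    conv = (Orientation.Fr if kind == FieldKind.repulsive else Orientation.Fa)
    field = train(ds, spec=spec, convention=conv, n_steps=n_steps,
                  seed=seed if net_seed is None else net_seed)
    params = config.force
    tau_lo = max(0.0, float(field.support_tau.min()))
    tau_hi = min(2 * params.t1 * 2.0, float(field.support_tau.max()))
    r_lo = 1.0 / np.sqrt(field.support_rho.max())
    r_hi = 1.0 / np.sqrt(field.support_rho.min())
    tau_grid = np.linspace(tau_lo, tau_hi, 30)
    r_grid = np.linspace(r_lo, r_hi, 30)
    return compare_to_truth(
        field, lambda T, R: pair_force_magnitude(np.maximum(T, 0.0), R, params),
        tau_grid, r_grid,
    )
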