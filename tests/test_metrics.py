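import numpy as np
import pytest

from nucarray.fixtures import hex_patch, standing_wave
from nucarray.geometry import Spheroid, meridian_frame, voronoi_density
from nucarray import metrics as mx


@pytest.fixture(scope="module")
def wave_traj():
    return standing_wave(damping=0.5)


@pytest.fixture(scope="module")
def wave_maps(wave_traj):
    return mx.heatmaps(wave_traj, speed_bin=0.05)


class TestApSpeed:
    def test_recovers_analytic_velocity_field(self, wave_traj):
        tab = mx.ap_speed(wave_traj)
        # v(el, t) = 2 sin(2 pi el) sin(2 pi t) in the first half period
        sub = tab[(tab["t"] > 0.2) & (tab["t"] < 0.3)]
        expect = 2.0 * np.sin(2 * np.pi * sub["el"]) * np.sin(
            2 * np.pi * (sub["t"] - 0.00625))  # backward-difference midpoint
        assert np.corrcoef(sub["v"], expect)[0, 1] > 0.99
        assert np.max(np.abs(sub["v"])) == pytest.approx(2.0, rel=0.1)

    def test_multi_stride_speed(self, wave_traj):
        dt = wave_traj.times[1] - wave_traj.times[0]
        tab = mx.ap_speed(wave_traj, dt_obs=2 * dt)
        assert len(tab) > 0
        with pytest.raises(ValueError):
            mx.ap_speed(wave_traj, dt_obs=2.5 * dt)
        with pytest.raises(ValueError):
            mx.ap_speed(wave_traj, dt_obs=0.1 * dt)


class TestHeatMaps:
    def test_shapes_and_bins(self, wave_maps):
        dens = wave_maps["density"]
        speed = wave_maps["ap_speed"]
        assert dens.values.shape[0] == 10
        assert speed.values.shape[0] == 20
        assert speed.values.shape[1] == len(speed.times)
        assert np.allclose(np.diff(dens.bin_edges), 0.1)

    def test_time_slice(self, wave_maps):
        hm = wave_maps["ap_speed"]
        sl = hm.time_slice(t0=0.3, t1=0.6)
        assert sl.times.min() >= 0.3 and sl.times.max() <= 0.6
        assert sl.values.shape == (hm.values.shape[0], len(sl.times))

    def test_binned_mean_marks_empty_bins(self):
        edges = mx.el_bins(0.25)
        out = mx.binned_mean(np.array([0.1, 0.6]), np.array([2.0, 4.0]),
                             edges)
        assert out[0] == 2.0 and out[2] == 4.0
        assert np.isnan(out[1]) and np.isnan(out[3])


class TestPhiArray:
    def test_perfect_hex_lattice_is_fully_ordered(self):
        pts, sph, interior = hex_patch()
        graph = voronoi_density(pts)
        _, per = mx.phi_array(pts, sph, graph=graph, return_per_nucleus=True)
        assert np.nanmin(per[interior]) > 0.999

    def test_matches_brute_force_oracle(self):
        pts, sph, _ = hex_patch(jitter=0.1, seed=4)
        graph = voronoi_density(pts)
        value, per = mx.phi_array(pts, sph, graph=graph,
                                  return_per_nucleus=True)
        # independent per-nucleus reference computation
        e1, e2 = meridian_frame(pts, sph)
        ref = np.full(len(pts), np.nan)
        for j in range(len(pts)):
            nbrs = graph.neighbors[j]
            if len(nbrs) < 2:
                continue
            acc = 0.0
            for i in nbrs:
                bond = pts[i] - pts[j]
                ang = np.arctan2(bond @ e2[j], bond @ e1[j])
                acc += np.exp(6j * ang)
            ref[j] = abs(acc) / len(nbrs)
        ok = ~np.isnan(per)
        assert np.allclose(per[ok], ref[ok], atol=1e-12)
        assert value == pytest.approx(np.nanmean(ref[ok]), abs=1e-12)

    def test_jitter_reduces_order(self):
        pts0, sph, _ = hex_patch(seed=1)
        pts1, _, _ = hex_patch(jitter=0.15, seed=1)
        assert mx.phi_array(pts1, sph) < mx.phi_array(pts0, sph)

    def test_too_few_points_rejected(self):
        sph = Spheroid()
        pts = sph.from_angles(np.linspace(1, 2, 5), np.zeros(5))
        with pytest.raises(ValueError):
            mx.phi_array(pts, sph)


class TestPhiSpeed:
    def test_aligned_motion_is_fully_ordered(self):
        v = np.tile([1.0, 0.0, 0.0], (10, 1))
        phi, prime = mx.phi_speed(v)
        assert phi == pytest.approx(1.0)
        assert prime == pytest.approx(1.0)

    def test_balanced_motion_has_zero_order(self):
        v = np.array([[1.0, 0, 0], [-1.0, 0, 0]] * 5)
        phi, prime = mx.phi_speed(v)
        assert phi == pytest.approx(0.0)
        assert prime == pytest.approx(0.0)

    def test_vmax_rescaling(self):
        v = np.tile([0.5, 0.0, 0.0], (4, 1))
        phi, prime = mx.phi_speed(v, v_max=1.0)
        assert prime == pytest.approx(1.0)
        assert phi == pytest.approx(0.5)


class TestWaveStatistics:
    def test_peak_ratio_recovers_imposed_damping(self, wave_maps):
        ratio = mx.wave_peak_ratio(wave_maps["ap_speed"])
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_undamped_wave_has_unit_ratio(self):
        traj = standing_wave(damping=1.0)
        hm = mx.heatmaps(traj, speed_bin=0.05)["ap_speed"]
        assert mx.wave_peak_ratio(hm) == pytest.approx(1.0, abs=0.05)

    def test_node_at_the_middle(self, wave_maps):
        node = mx.node_position(wave_maps["ap_speed"])
        assert node == pytest.approx(0.5, abs=0.03)

    def test_monotone_flux_is_not_a_wave(self):
        # uniform drift: no crest ever reverses
        values = np.ones((20, 30))
        hm = mx.HeatMap(values, mx.el_bins(0.05), np.linspace(0, 1, 30),
                        "ap_speed")
        with pytest.raises(ValueError):
            mx.wave_peak_ratio(hm)

    def test_stable_window_finds_the_quiet_interval(self):
        t = np.linspace(0, 2, 201)
        # noisy early, quiet in [1.0, 1.6], noisy late
        amp = np.where((t > 1.0) & (t < 1.6), 0.01, 1.0)
        values = np.outer(np.ones(18), amp)
        hm = mx.HeatMap(values, mx.el_bins(1 / 18), t, "ap_speed")
        lo, hi = mx.stable_interphase_window(hm)
        assert 1.0 <= lo < hi <= 1.6


class TestDensityRatio:
    def test_known_profile(self):
        # density 2 at poles bands, 10 in the middle, constant in time
        centers = np.linspace(0.025, 0.975, 20)
        prof = np.where((centers < 0.15) | (centers > 0.85), 2.0, 10.0)
        values = np.tile(prof[:, None], (1, 5))
        hm = mx.HeatMap(values, mx.el_bins(0.05), np.linspace(0, 1, 5),
                        "density")
        ant, post = mx.density_ratio(hm, (0.0, 1.0))
        assert ant == pytest.approx(0.2)
        assert post == pytest.approx(0.2)

    def test_empty_pole_bins_rejected(self):
        values = np.full((20, 5), np.nan)
        values[8:12] = 1.0
        hm = mx.HeatMap(values, mx.el_bins(0.05), np.linspace(0, 1, 5),
                        "density")
        with pytest.raises(ValueError):
            mx.density_ratio(hm, (0.0, 1.0))


class TestOnsetTimes:
    def test_recovers_known_onset_ramp(self):
        t = np.linspace(0, 1, 101)
        centers = np.linspace(0.05, 0.95, 10)
        onset = 0.2 + 0.5 * np.abs(centers - 0.5)  # wave from the middle
        values = np.empty((10, 101))
        for b in range(10):
            values[b] = 1.0 + 1.0 / (1 + np.exp(-(t - onset[b]) / 0.01))
        hm = mx.HeatMap(values, mx.el_bins(0.1), t, "density")
        out = mx.onset_times(hm)
        assert np.allclose(out["t_raw"], onset, atol=0.02)
        assert np.allclose(out["t_onset"], onset, atol=0.05)

    def test_no_division_detected(self):
        values = np.ones((10, 5))
        hm = mx.HeatMap(values, mx.el_bins(0.1), np.linspace(0, 1, 5),
                        "density")
        with pytest.raises(ValueError):
            mx.onset_times(hm)


class TestAreaVariation:
    def test_static_cloud_has_zero_variation(self, wave_traj):
        # build a static trajectory from one frame
        from nucarray.simulator import Trajectory

        static = Trajectory(spheroid=wave_traj.spheroid)
        for k in range(3):
            frame = wave_traj.frames[0].copy()
            frame.time = float(k)
            static.log(frame)
        hm = mx.area_variation(static, ref_time=0.0)
        assert np.nanmax(np.abs(hm.values)) < 1e-12

    def test_expanding_cloud_has_positive_variation(self, wave_traj):
        hm = mx.area_variation(wave_traj, ref_time=0.0)
        assert hm.values.shape[1] == len(wave_traj.times)
        assert np.any(np.abs(hm.values) > 0)
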