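"""Grid construction, bound snapping, and kernel-to-voxel integration."""

import math

import numpy as np
import pytest

import movekde as mk
from conftest import make_spec

MV = mk.MovementVariances(eta2=50.0, gamma2=5.0)


class TestAutoExtent:
    def test_buffered_extent(self, single_step):
        track, step = single_step
        spec = mk.auto_extent(track, [step], MV, track.error,
                              cell_sizes=(10.0, 10.0, 5.0))
        # sigma_max at alpha=0.5: sqrt(60*0.25*50 + 0.5*25) = sqrt(762.5)
        sd = math.sqrt(60 * 0.25 * 50 + 0.5 * 25)
        assert spec.x0 <= 0.0 - 4.265 * sd
        assert spec.x_edges[-1] >= 100.0 + 4.265 * sd
        assert spec.y0 <= -4.265 * sd

    def test_zero_buffer_equals_bounding_box(self, single_step):
        track, step = single_step
        spec = mk.auto_extent(track, [step], MV, track.error,
                              cell_sizes=(10.0, 10.0, 5.0), buffer_sd=0.0)
        assert spec.x0 == pytest.approx(0.0)

    def test_buffer_monotone(self, single_step):
        track, step = single_step
        specs = [
            mk.auto_extent(track, [step], MV, track.error,
                           cell_sizes=(10.0, 10.0, 5.0), buffer_sd=b)
            for b in (0.0, 2.0, 4.265)
        ]
        widths = [s.x_edges[-1] - s.x0 for s in specs]
        assert widths == sorted(widths)


class TestSnapBounds:
    def test_floor_rounds_down(self):
        spec = mk.GridSpec3D(x0=0, y0=0, z0=0, hx=5, hy=5, hz=5, I=2, J=2, K=4)
        snapped = mk.snap_bounds(mk.BoundSurface(lower=12.3), spec)
        assert np.all(snapped.z_lo == 10.0)
        assert np.all(snapped.k_lo == 1)

    def test_ceiling_rounds_up_and_level_is_fixed_point(self):
        spec = mk.GridSpec3D(x0=0, y0=0, z0=0, hx=5, hy=5, hz=5, I=2, J=2, K=4)
        snapped = mk.snap_bounds(mk.BoundSurface(lower=10.0, upper=27.0), spec)
        assert np.all(snapped.z_lo == 10.0)  # already on a level boundary
        assert np.all(snapped.z_hi == 30.0)

    def test_no_upper_bound(self):
        spec = mk.GridSpec3D(x0=0, y0=0, z0=0, hx=5, hy=5, hz=5, I=2, J=2, K=4)
        snapped = mk.snap_bounds(mk.BoundSurface(lower=0.0), spec)
        assert np.all(np.isinf(snapped.z_hi))
        assert np.all(snapped.k_hi == 4)

    def test_inverted_bounds_raise(self):
        spec = mk.GridSpec3D(x0=0, y0=0, z0=0, hx=5, hy=5, hz=5, I=2, J=2, K=4)
        with pytest.raises(ValueError, match="exceeds"):
            mk.snap_bounds(mk.BoundSurface(lower=29.0, upper=21.0), spec)


class TestStepVoxelMasses:
    def test_mass_conserves_step_duration(self, single_step):
        track, step = single_step
        spec = mk.auto_extent(track, [step], MV, track.error,
                              cell_sizes=(20.0, 20.0, 10.0))
        masses = mk.step_voxel_masses(step, MV, track.error, spec, dt_int=1.0)
        assert sum(masses.values()) == pytest.approx(step.dt, abs=1e-6)

    def test_truncation_loss_below_half_percent(self, single_step):
        track, step = single_step
        spec = mk.auto_extent(track, [step], MV, track.error,
                              cell_sizes=(20.0, 20.0, 10.0))
        raw = mk.step_voxel_masses(step, MV, track.error, spec, dt_int=1.0,
                                   renormalize=False)
        assert sum(raw.values()) >= 0.995 * step.dt

    def test_monte_carlo_oracle(self, single_step):
        track, step = single_step
        spec = make_spec((-150, -150, -100), (250, 150, 100), (50, 50, 25))
        masses = mk.step_voxel_masses(step, MV, track.error, spec, dt_int=0.25)
        n = 200_000
        rng = np.random.default_rng(42)
        t = rng.uniform(0.0, step.dt, n)
        alpha = t / step.dt
        var_xy = step.dt * alpha * (1 - alpha) * MV.eta2 \
            + ((1 - alpha) ** 2 + alpha**2) * track.error.var_xy
        var_z = step.dt * alpha * (1 - alpha) * MV.gamma2 \
            + ((1 - alpha) ** 2 + alpha**2) * track.error.var_z
        x = alpha * 100.0 + rng.normal(size=n) * np.sqrt(var_xy)
        y = rng.normal(size=n) * np.sqrt(var_xy)
        z = rng.normal(size=n) * np.sqrt(var_z)
        counts, _ = np.histogramdd(
            np.column_stack([y, x, z]),
            bins=(spec.y_edges, spec.x_edges, spec.z_edges),
        )
        p_mc = counts / n
        p_est = np.zeros_like(p_mc)
        for v, mass in masses.items():
            i = v % spec.I
            j = (v // spec.I) % spec.J
            k = v // (spec.I * spec.J)
            p_est[i, j, k] = mass / step.dt
        se = np.sqrt(p_mc * (1 - p_mc) / n)
        active = p_mc + p_est > 0
        diff = np.abs(p_est - p_mc)[active]
        assert np.all(diff <= 3 * se[active] + 1e-4)

    def test_floor_truncates_and_conserves(self):
        err = mk.ErrorModel(var_xy=25.0, var_z=9.0)
        track = mk.build_track(
            [("a", 0.0, 0.0, 0.0, 5.0), ("a", 30.0, 80.0, 0.0, 5.0)], err
        )
        (step,) = mk.classify_move_steps(track, mk.FilterConfig(t_max=60.0))
        spec = make_spec((-120, -120, 0), (220, 120, 120), (20, 20, 10))
        snapped = mk.snap_bounds(mk.BoundSurface(lower=0.0), spec)
        masses = mk.step_voxel_masses(step, MV, err, spec, bounds=snapped,
                                      dt_int=1.0)
        assert sum(masses.values()) == pytest.approx(step.dt, abs=1e-6)
        for v in masses:
            k = v // (spec.I * spec.J)
            assert spec.z_edges[k] >= 0.0  # nothing below the floor


class TestComputeUD:
    def test_normalization_and_single_step_identity(self, single_step):
        track, step = single_step
        spec = mk.auto_extent(track, [step], MV, track.error,
                              cell_sizes=(20.0, 20.0, 10.0))
        ud = mk.compute_ud(track, [step], MV, track.error, spec, dt_int=1.0)
        assert ud.probs.sum() == pytest.approx(1.0, abs=1e-6)
        masses = mk.step_voxel_masses(step, MV, track.error, spec, dt_int=1.0)
        for v, mass in masses.items():
            i = v % spec.I
            j = (v // spec.I) % spec.J
            k = v // (spec.I * spec.J)
            assert ud.probs[i, j, k] == pytest.approx(mass / step.dt, rel=1e-9)

    def test_3d_marginalizes_to_2d(self, sim_track, sim_steps):
        _, track, _ = sim_track
        mv = mk.MovementVariances(eta2=100.0, gamma2=1.0)
        spec = mk.auto_extent(track, sim_steps, mv, track.error,
                              cell_sizes=(30.0, 30.0, 4.0))
        ud3 = mk.compute_ud(track, sim_steps, mv, track.error, spec,
                            dt_int=1.0, ndim=3)
        ud2 = mk.compute_ud(track, sim_steps, mv, track.error, spec,
                            dt_int=1.0, ndim=2)
        assert np.max(np.abs(ud3.probs.sum(axis=2) - ud2.probs)) < 1e-6

    def test_integration_step_halving_is_stable(self, sim_track, sim_steps):
        _, track, _ = sim_track
        mv = mk.MovementVariances(eta2=100.0, gamma2=1.0)
        spec = mk.auto_extent(track, sim_steps, mv, track.error,
                              cell_sizes=(40.0, 40.0, 5.0))
        ud_a = mk.compute_ud(track, sim_steps, mv, track.error, spec,
                             dt_int=1.0, ndim=3)
        ud_b = mk.compute_ud(track, sim_steps, mv, track.error, spec,
                             dt_int=0.5, ndim=3)
        assert np.max(np.abs(ud_a.probs - ud_b.probs)) < 1e-4

    def test_grid_refinement_converges(self, single_step):
        track, step = single_step
        coarse = make_spec((-150, -150, -100), (250, 150, 100), (50, 50, 25))
        fine = mk.GridSpec3D(
            x0=coarse.x0, y0=coarse.y0, z0=coarse.z0,
            hx=coarse.hx / 2, hy=coarse.hy / 2, hz=coarse.hz / 2,
            I=coarse.I * 2, J=coarse.J * 2, K=coarse.K * 2,
        )
        ud_c = mk.compute_ud(track, [step], MV, track.error, coarse, dt_int=0.5)
        ud_f = mk.compute_ud(track, [step], MV, track.error, fine, dt_int=0.5)
        agg = ud_f.probs.reshape(coarse.I, 2, coarse.J, 2, coarse.K, 2).sum(
            axis=(1, 3, 5)
        )
        assert ud_f.probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.max(np.abs(agg - ud_c.probs)) < 1e-3


class TestEncounterProbability:
    def _toy_ud(self):
        spec = mk.GridSpec3D(x0=0, y0=0, z0=0, hx=5, hy=5, hz=2.5,
                             I=2, J=2, K=10)
        snapped = mk.snap_bounds(mk.BoundSurface(lower=0.0), spec)
        probs = np.zeros((2, 2, 10))
        probs[0, 0, :] = 0.1  # uniform column over 10 admissible levels
        return mk.UDGrid(spec=spec, probs=probs, ndim=3, total_time=60.0,
                         bounds=snapped)

    def test_uniform_column_three_levels(self):
        ud = self._toy_ud()
        df = mk.structure_encounter_probability(ud, [(5.0, 5.0)], n_levels=3)
        assert df.p_3d.iloc[0] == pytest.approx(0.3)

    def test_zero_probability_region(self):
        ud = self._toy_ud()
        df = mk.structure_encounter_probability(ud, [(15.0, 15.0)], n_levels=3)
        assert df.p_3d.iloc[0] == 0.0

    def test_risk_ratio(self):
        ud = self._toy_ud()
        spec2 = mk.GridSpec3D(x0=0, y0=0, z0=0, hx=5, hy=5, hz=0.5, I=2, J=2)
        p2 = np.zeros((2, 2))
        p2[0, 0] = 0.6
        ud2 = mk.UDGrid(spec=spec2, probs=p2, ndim=2, total_time=60.0)
        df = mk.structure_encounter_probability(ud, [(5.0, 5.0)], n_levels=3,
                                                ud2d=ud2)
        assert df.risk_ratio.iloc[0] == pytest.approx(0.6 / 0.3)

    def test_site_outside_grid(self):
        ud = self._toy_ud()
        with pytest.raises(ValueError, match="outside"):
            mk.structure_encounter_probability(ud, [(500.0, 5.0)])
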