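import numpy as np
import pytest

from casitebench import clusters as clu
from casitebench import geometry as geo
from casitebench import rdsolver as rd


def make_cube(n=41, res=107.5):
    grid = np.full((n, n, n), geo.CYTOSOL, dtype=np.uint8)
    cs = geo.CrossSection(grid[:, :, 0].copy(), res, n * res)
    return geo.CellVolume(
        label_grid=grid,
        resolution=res,
        axial_length=n * res,
        sarcomere_length=n * res,
        zdisk_positions=np.array([n * res / 2]),
        diameter=n * res,
        cross_section=cs,
    )


def center_cluster(volume, fire_time=0.0):
    res = volume.resolution
    c = tuple((s // 2 + 0.5) * res for s in volume.shape)
    return clu.RyRCluster(center=c, zdisk_index=0, fire_time=fire_time)


class TestReleaseModel:
    def test_flux_zero_before_fire_time(self):
        rp = rd.ReleaseParams(amplitude=10.0)
        assert rd.release_flux(4.9, 5.0, rp) == 0.0
        assert rd.release_flux(np.array([0.0, 4.0]), 5.0, rp).max() == 0.0

    def test_flux_peak_location_closed_form(self):
        """Peak at t0 + tau_rise ln(1 + tau_decay/tau_rise), vs dense grid search."""
        rp = rd.ReleaseParams(tau_rise=1.0, tau_decay=5.0, amplitude=3.0)
        t = np.linspace(0, 40, 200_001)
        flux = rd.release_flux(t, 0.0, rp)
        t_peak_numeric = t[np.argmax(flux)]
        t_peak_analytic = rp.tau_rise * np.log(1 + rp.tau_decay / rp.tau_rise)
        assert abs(t_peak_numeric - t_peak_analytic) < 1e-3

    def test_flux_decays_to_negligible(self):
        rp = rd.ReleaseParams(tau_rise=1.0, tau_decay=5.0, amplitude=1.0)
        assert rd.release_flux(20 * rp.tau_decay, 0.0, rp) < 1e-6 * rp.amplitude

    def test_source_weights_closed_form(self, plain_volume):
        cl = clu.RyRCluster(
            center=(2902.5, 2902.5, 2042.5), zdisk_index=0  # a cytosol voxel center
        )
        rp = rd.ReleaseParams(weight_sigma=50.0)
        idx, w = rd.build_source_weights(cl, plain_volume, rp)
        # only voxels within 100 nm of the center survive at 215 nm resolution
        res = plain_volume.resolution
        centers = (idx + 0.5) * res
        r = np.linalg.norm(centers - np.array(cl.center), axis=1)
        assert np.all(r <= cl.source_radius)
        # central voxel carries the maximal weight exp(0) = 1
        assert np.isclose(w.max(), 1.0)
        # w(r)/w(0) = exp(-r^2/sigma^2), checked against direct evaluation
        np.testing.assert_allclose(w, np.exp(-(r**2) / 50.0**2))

    def test_weight_formula_at_sigma(self):
        """w(50 nm)/w(0) = e^-1 for sigma = 50 nm, on a fine grid."""
        vol = make_cube(n=9, res=50.0)
        cl = clu.RyRCluster(center=(4.5 * 50, 4.5 * 50, 4.5 * 50), zdisk_index=0)
        idx, w = rd.build_source_weights(cl, vol, rd.ReleaseParams(weight_sigma=50.0))
        res = vol.resolution
        r = np.linalg.norm((idx + 0.5) * res - np.array(cl.center), axis=1)
        at_sigma = np.isclose(r, 50.0)
        assert at_sigma.any()
        np.testing.assert_allclose(w[at_sigma] / w.max(), np.exp(-1), rtol=1e-12)

    def test_source_outside_domain_rejected(self, plain_volume):
        cl = clu.RyRCluster(center=(10.0, 10.0, 10.0), zdisk_index=0)  # exterior corner
        with pytest.raises(ValueError):
            rd.build_source_weights(cl, plain_volume)


class TestEquilibrium:
    def test_reaction_rates_vanish(self, plain_volume):
        params = rd.SolverParams()
        state = rd.init_equilibrium(params, plain_volume)
        totals = params.buffer_totals()
        for b in params.buffers:
            bound = state.fields[f"{b.name}_bound"]
            free = (
                state.fields[f"{b.name}_free"] if b.mobile else totals[b.name] - bound
            )
            rate = b.k_on * state.ca * free - b.k_off * bound
            assert np.abs(rate).max() < 1e-12

    def test_rest_levels(self, plain_volume):
        state = rd.init_equilibrium(rd.SolverParams(), plain_volume)
        np.testing.assert_allclose(state.ca, 0.1)
        np.testing.assert_allclose(state.fca, 2.08)

    def test_equilibrium_is_fixed_point_of_step(self, plain_volume):
        params = rd.SolverParams(dt=0.005)
        state = rd.init_equilibrium(params, plain_volume)
        new = rd.step(state, 0.005, params, plain_volume, clusters=None)
        for name in state.fields:
            np.testing.assert_allclose(new.fields[name], state.fields[name], atol=1e-12)


class TestStep:
    def test_greens_function_agreement(self):
        """Buffer-free impulse matches the 3D diffusion kernel within 2% at 1 ms."""
        vol = make_cube(n=41, res=107.5)
        dt = 0.004
        params = rd.SolverParams(buffers=[], d_ca=0.22, dt=dt)
        st = rd._Stepper(vol, params, None)
        state = rd.init_equilibrium(params, vol)
        M = 100.0
        state.fields["ca"][:] = 0.0
        state.fields["ca"][20, 20, 20] = M
        while state.time < 1.0 - 1e-9:
            state = st.step(state, dt)
        h = vol.resolution / 1000.0
        x = (np.arange(41) - 20) * h
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        D, t = 0.22, 1.0
        analytic = (
            M * h**3 * (4 * np.pi * D * t) ** -1.5 * np.exp(-(X**2 + Y**2 + Z**2) / (4 * D * t))
        )
        mask = analytic > 0.1 * analytic.max()
        rel = np.abs(state.fields["ca"][mask] - analytic[mask]) / analytic[mask]
        assert rel.max() < 0.02

    def test_mass_conservation_with_sources_and_buffers(self, tiny_volume):
        cset = clu.assign_fire_times(
            clu.place_clusters(tiny_volume, "low", seed=2), seed=3
        )
        params = rd.SolverParams(release=rd.ReleaseParams(amplitude=500.0))
        st = rd._Stepper(tiny_volume, params, cset)
        series = rd.simulate(tiny_volume, cset, params)
        initial = st.total_ca_mass(series.snapshots[0])
        final = st.total_ca_mass(series.snapshots[-1])
        expected = initial + series.source_input
        assert series.source_input > 0
        assert abs(final - expected) <= 1e-3 * expected

    def test_mass_conservation_with_obstacles(self, tiny_volume):
        cset = clu.assign_fire_times(
            clu.place_clusters(tiny_volume, "low", seed=2), seed=3
        )
        params = rd.SolverParams(
            release=rd.ReleaseParams(amplitude=500.0), mitochondria_as_obstacles=True
        )
        st = rd._Stepper(tiny_volume, params, cset)
        series = rd.simulate(tiny_volume, cset, params)
        expected = st.total_ca_mass(series.snapshots[0]) + series.source_input
        assert abs(st.total_ca_mass(series.snapshots[-1]) - expected) <= 1e-3 * expected

    def test_stability_violation_raises(self, plain_volume):
        params = rd.SolverParams(dt=1.0)  # far above the diffusion bound
        state = rd.init_equilibrium(params, plain_volume)
        with pytest.raises(rd.StabilityError):
            rd.step(state, 1.0, params, plain_volume)

    def test_axis_permutation_symmetry(self):
        """A centered source in an obstacle-free cube gives a permutation-symmetric field."""
        vol = make_cube(n=21, res=215.0)
        cset = clu.ClusterSet([center_cluster(vol)], "low", 1, None)
        params = rd.SolverParams(
            duration=5.0, release=rd.ReleaseParams(amplitude=500.0)
        )
        fca = rd.simulate(vol, cset, params, check_conservation=False).snapshots[-1].fca
        np.testing.assert_allclose(fca, fca.transpose(1, 0, 2), rtol=1e-8)
        np.testing.assert_allclose(fca, fca.transpose(2, 1, 0), rtol=1e-8)


class TestSimulate:
    def test_source_free_invariance(self, plain_volume):
        params = rd.SolverParams(duration=10.0)
        series = rd.simulate(plain_volume, None, params)
        for snap in series.snapshots[1:]:
            np.testing.assert_allclose(snap.ca, series.snapshots[0].ca, atol=1e-10)
            np.testing.assert_allclose(snap.fca, series.snapshots[0].fca, atol=1e-10)

    def test_snapshot_times(self, plain_volume):
        series = rd.simulate(plain_volume, None, rd.SolverParams(duration=30.0))
        np.testing.assert_allclose(series.times, [0, 5, 10, 15, 20, 25, 30])

    def test_dt_halving_convergence(self, tiny_volume):
        """Halving a fixed dt changes the final FCa field by < 0.5% (max-norm)."""
        cset = clu.assign_fire_times(
            clu.place_clusters(tiny_volume, "low", seed=4), seed=5
        )
        rel = rd.ReleaseParams(amplitude=500.0)
        f = {}
        for dt in (0.008, 0.004):
            params = rd.SolverParams(release=rel, dt=dt)
            f[dt] = rd.simulate(tiny_volume, cset, params, check_conservation=False).snapshots[-1].fca
        diff = np.abs(f[0.008] - f[0.004]).max() / np.abs(f[0.004]).max()
        assert diff < 0.005

    def test_obstacle_reflection_raises_local_fca(self, tiny_volume):
        """FCa outside a mitochondrial face near a firing cluster is >= the
        homogeneous value at the same voxel and time (the reflection effect)."""
        # pick a border-shell cluster adjacent to a mitochondrion
        shell = geo.border_shell(tiny_volume, 250)
        labels = tiny_volume.label_grid
        from scipy import ndimage

        near_mito = ndimage.binary_dilation(labels == geo.MITOCHONDRION) & (
            labels == geo.CYTOSOL
        )
        cand = np.argwhere(shell & near_mito)
        iu, iv, il = cand[len(cand) // 2]
        res = tiny_volume.resolution
        cl = clu.RyRCluster(
            center=((iu + 0.5) * res, (iv + 0.5) * res, (il + 0.5) * res), zdisk_index=0
        )
        cset = clu.ClusterSet([cl], "low", 1, None)
        rel = rd.ReleaseParams(amplitude=1000.0)
        out = {}
        for obstacles in (False, True):
            params = rd.SolverParams(
                duration=10.0, release=rel, mitochondria_as_obstacles=obstacles
            )
            out[obstacles] = rd.simulate(
                tiny_volume, cset, params, check_conservation=False
            ).snapshots[-1].fca[iu, iv, il]
        assert out[True] >= out[False]

    def test_obstacles_raise_bulk_ca(self, tiny_volume):
        """Removing mitochondrial volume concentrates the same release mass."""
        cset = clu.assign_fire_times(
            clu.place_clusters(tiny_volume, "high", seed=6), seed=7
        )
        rel = rd.ReleaseParams(amplitude=800.0)
        bulk = {}
        for obstacles in (False, True):
            params = rd.SolverParams(
                duration=15.0, release=rel, mitochondria_as_obstacles=obstacles
            )
            bulk[obstacles] = rd.simulate(
                tiny_volume, cset, params, check_conservation=False
            ).bulk_ca()
        assert bulk[True] > bulk[False]


class TestCalibration:
    def test_degenerate_target_rejected(self, tiny_volume):
        cset = clu.place_clusters(tiny_volume, "low", seed=1)
        with pytest.raises(ValueError):
            rd.calibrate_amplitude(tiny_volume, cset, rd.SolverParams(), target_bulk_ca=0.1)

    def test_bulk_ca_monotone_in_amplitude(self, tiny_volume):
        cset = clu.assign_fire_times(
            clu.place_clusters(tiny_volume, "low", seed=8), seed=9
        )
        bulks = []
        for amp in (400.0, 800.0, 1600.0):
            params = rd.SolverParams(
                duration=10.0, release=rd.ReleaseParams(amplitude=amp)
            )
            bulks.append(
                rd.simulate(tiny_volume, cset, params, check_conservation=False).bulk_ca()
            )
        assert bulks[0] < bulks[1] < bulks[2]

    def test_calibrated_amplitude_self_consistent(self, tiny_volume):
        cset = clu.assign_fire_times(
            clu.place_clusters(tiny_volume, "low", seed=10), seed=11
        )
        params = rd.SolverParams(duration=15.0)
        amp = rd.calibrate_amplitude(
            tiny_volume, cset, params, target_bulk_ca=0.5, rel_tol=0.05
        )
        check = rd.simulate(
            tiny_volume,
            cset,
            rd.SolverParams(duration=15.0, release=rd.ReleaseParams(amplitude=amp)),
            check_conservation=False,
        ).bulk_ca()
        assert abs(check - 0.5) <= 0.05 * 0.5


def test_series_roundtrip(tmp_path, tiny_volume):
    cset = clu.assign_fire_times(clu.place_clusters(tiny_volume, "low", seed=12), seed=13)
    params = rd.SolverParams(duration=10.0, release=rd.ReleaseParams(amplitude=300.0))
    series = rd.simulate(tiny_volume, cset, params)
    path = tmp_path / "fields.h5"
    rd.save_series(series, path)
    loaded = rd.load_series(path, tiny_volume)
    assert len(loaded.snapshots) == len(series.snapshots)
    np.testing.assert_allclose(loaded.times, series.times)
    np.testing.assert_allclose(
        loaded.snapshots[-1].fca, series.snapshots[-1].fca, rtol=1e-6
    )
    assert np.isclose(loaded.source_input, series.source_input)
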