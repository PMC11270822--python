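"""MLFF pipeline: curation, splitting, histogram sampling, kernel model,
MAD scoring, Langevin MD and VACF spectra."""

import numpy as np
import pytest

import qmcforces as q
from qmcforces.mlff import (
    ConfigurationSet,
    CurationPlan,
    MdConfig,
    curate,
    mad_forces,
    run_langevin_md,
    sample_by_energy_histogram,
    split_train_validation,
    train,
    vacf_spectrum,
)
from qmcforces.units import CM1_PER_HARTREE, FORCE_AU_TO_KCAL_PER_ANG, KB_HARTREE, ME_PER_AMU


@pytest.fixture(scope="module")
def pool(triangle_reference):
    ens = q.perturb_geometries(triangle_reference, 600, 0.08, seed=4)
    return ConfigurationSet.from_ensemble(ens, "B")


class TestCuration:
    def test_pool_of_product_size_is_identity(self, pool):
        small = pool.subset(range(40))
        out = curate(small, CurationPlan(8, 5, seed=0))
        assert len(out) == 40
        assert all(a is b for a, b in zip(out.configurations, small.configurations))

    def test_returns_exact_product_distinct(self, pool):
        plan = CurationPlan(10, 4, seed=1)
        out = curate(pool, plan)
        assert len(out) == 40
        keys = {tuple(g.positions.ravel()) for g in out.configurations}
        assert len(keys) == 40

    def test_deterministic_for_fixed_seed(self, pool):
        plan = CurationPlan(6, 3, seed=2)
        a = curate(pool, plan)
        b = curate(pool, plan)
        assert np.array_equal(a.energies, b.energies)

    def test_pool_too_small_rejected(self, pool):
        with pytest.raises(ValueError):
            curate(pool.subset(range(10)), CurationPlan(10, 4))


class TestSplit:
    def test_even_split_disjoint_union(self, pool):
        cur = pool.subset(range(200))
        tr, va = split_train_validation(cur, seed=3)
        assert len(tr) == len(va) == 100
        kt = {tuple(g.positions.ravel()) for g in tr.configurations}
        kv = {tuple(g.positions.ravel()) for g in va.configurations}
        assert not kt & kv and len(kt | kv) == 200

    def test_odd_size_rejected(self, pool):
        with pytest.raises(ValueError):
            split_train_validation(pool.subset(range(7)))

    def test_different_seeds_differ(self, pool):
        cur = pool.subset(range(100))
        a, _ = split_train_validation(cur, seed=1)
        b, _ = split_train_validation(cur, seed=2)
        assert not np.array_equal(a.energies, b.energies)


class TestHistogramSampling:
    def test_whole_trajectory_returned(self, pool):
        out = sample_by_energy_histogram(pool, len(pool), bins=10, seed=0)
        assert len(out) == len(pool)

    def test_proportional_draws_two_bins(self, triangle_reference):
        # energies split 900/100 across two histogram bins -> 90/10 draws
        geos = tuple(triangle_reference for _ in range(1000))
        energies = np.concatenate([np.zeros(900), np.ones(100)])
        cs = ConfigurationSet(geos, energies, np.zeros((1000, 3, 3)))
        out = sample_by_energy_histogram(cs, 100, bins=2, seed=1)
        assert len(out) == 100
        assert int((out.energies == 0).sum()) == 90
        assert int((out.energies == 1).sum()) == 10

    def test_oversampling_rejected(self, pool):
        with pytest.raises(ValueError):
            sample_by_energy_histogram(pool, len(pool) + 1)


class TestKernelModel:
    def test_training_point_interpolation(self, pool):
        # moderate length scale keeps the kernel matrix well-conditioned so
        # the zero-regularization limit actually interpolates
        small = pool.subset(range(20))
        model = train(small, length_scale=0.05, regularization=1e-12)
        pred = model.predict_forces(small.configurations)
        assert np.abs(pred - small.forces).max() < 1e-6

    def test_held_out_accuracy_on_analytic_surface(self, pool):
        tr = pool.subset(range(300))
        va = pool.subset(range(300, 600))
        model = train(tr)
        mad = mad_forces(model.predict_forces(va.configurations), va.forces)
        rms = np.sqrt(np.mean(va.forces**2)) * FORCE_AU_TO_KCAL_PER_ANG
        assert mad < 0.05 * rms

    def test_duplicate_points_need_jitter(self, pool):
        dup = pool.subset([0, 0, 1])
        model = train(dup, regularization=1e-6)  # solvable with jitter
        assert np.isfinite(model.predict_forces(dup.configurations)).all()

    def test_noise_monotonicity(self, pool):
        tr = pool.subset(range(300))
        va = pool.subset(range(300, 600))
        rng = np.random.default_rng(9)
        mads = []
        for noise in (0.001, 0.005, 0.02):
            noisy = ConfigurationSet(
                tr.configurations, tr.energies, tr.forces + rng.normal(0, noise, tr.forces.shape)
            )
            mads.append(mad_forces(train(noisy).predict_forces(va.configurations), va.forces))
        assert mads[0] < mads[1] < mads[2]

    def test_too_few_points_rejected(self, pool):
        with pytest.raises(ValueError):
            train(pool.subset([0]))


class TestMad:
    def test_identical_arrays_zero(self):
        x = np.random.default_rng(0).normal(size=(5, 3, 3))
        assert mad_forces(x, x) == 0.0

    def test_component_arithmetic(self):
        d = np.array([[[1.0, -1.0, 2.0]]])
        assert mad_forces(d, np.zeros_like(d), input_units="kcal/mol/A") == pytest.approx(4 / 3)

    def test_unit_conversion_at_boundary(self):
        d = np.ones((1, 1, 3))
        assert mad_forces(d, np.zeros_like(d)) == pytest.approx(FORCE_AU_TO_KCAL_PER_ANG)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p, r = rng.normal(size=(6, 2, 3)), rng.normal(size=(6, 2, 3))
        perm = rng.permutation(6)
        assert mad_forces(p, r) == pytest.approx(mad_forces(p[perm], r[perm]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mad_forces(np.zeros((2, 1, 3)), np.zeros((3, 1, 3)))


class TestLangevinMd:
    def test_equipartition_at_room_temperature(self):
        rng = np.random.default_rng(1)
        ref = q.Geometry(rng.normal(scale=2.0, size=(10, 3)), np.ones(10), ("X",) * 10)
        field = q.HarmonicNuclearField(ref.positions, k=0.2)
        cfg = MdConfig(time_step_fs=0.2, temperature_k=300, thermostat_fs=100,
                       duration_fs=20000, seed=5)
        traj = run_langevin_md(field, ref, [1.0] * 10, cfg)
        ke = traj.kinetic[len(traj.kinetic) // 5 :].mean()
        target = 1.5 * 10 * KB_HARTREE * 300
        assert ke == pytest.approx(target, rel=0.05)

    def test_energy_conservation_without_thermostat(self, triangle_reference):
        field = q.HarmonicNuclearField(triangle_reference.positions, k=0.05)
        start = triangle_reference.with_positions(triangle_reference.positions + 0.2)
        cfg = MdConfig(time_step_fs=0.2, temperature_k=0, thermostat_fs=0,
                       duration_fs=2000, seed=0)
        traj = run_langevin_md(field, start, [1.0] * 3, cfg,
                               initial_velocities=np.zeros((3, 3)))
        tot = traj.energies + traj.kinetic
        n = len(tot)
        drift = abs(tot[-n // 10 :].mean() - tot[: n // 10].mean())
        assert drift < 1e-5 * abs(tot.mean())

    def test_zero_temperature_relaxation(self, triangle_reference):
        field = q.HarmonicNuclearField(triangle_reference.positions, k=0.2)
        start = triangle_reference.with_positions(triangle_reference.positions + 0.3)
        cfg = MdConfig(time_step_fs=0.5, temperature_k=0, thermostat_fs=20,
                       duration_fs=4000, seed=0)
        traj = run_langevin_md(field, start, [1.0] * 3, cfg,
                               initial_velocities=np.zeros((3, 3)))
        assert traj.energies[-1] < 1e-3 * traj.energies[0]

    def test_same_seed_identical_trajectory(self, triangle_reference):
        field = q.HarmonicNuclearField(triangle_reference.positions)
        cfg = MdConfig(duration_fs=100, seed=7)
        a = run_langevin_md(field, triangle_reference, [1.0] * 3, cfg)
        b = run_langevin_md(field, triangle_reference, [1.0] * 3, cfg)
        assert np.array_equal(a.positions, b.positions)


class TestVacfSpectrum:
    def _harmonic_trajectory(self, duration_fs, seed=7, k=0.1, m=1.0):
        # weak thermostat coupling: the Langevin line broadening stays well
        # below the frequency-grid spacing of an 8 ps trajectory
        geo = q.Geometry(np.zeros((1, 3)), np.ones(1), ("X",))
        field = q.HarmonicNuclearField(np.zeros((1, 3)), k=k)
        cfg = MdConfig(time_step_fs=0.2, temperature_k=300, thermostat_fs=1000,
                       duration_fs=duration_fs, seed=seed)
        return run_langevin_md(field, geo, [m], cfg)

    def test_peak_at_analytic_frequency(self):
        k, m = 0.1, 1.0
        traj = self._harmonic_trajectory(8000, k=k, m=m)
        sp = vacf_spectrum(traj.velocities, 0.2, [m])
        omega = np.sqrt(k / (m * ME_PER_AMU))
        assert abs(sp.peak_frequency() - omega * CM1_PER_HARTREE) <= sp.grid_spacing

    def test_peak_independent_of_thermostat_seed(self):
        peaks = []
        for seed in (1, 2, 3):
            traj = self._harmonic_trajectory(8000, seed=seed)
            peaks.append(vacf_spectrum(traj.velocities, 0.2, [1.0]).peak_frequency())
        sp = vacf_spectrum(self._harmonic_trajectory(8000, seed=1).velocities, 0.2, [1.0])
        assert max(peaks) - min(peaks) <= sp.grid_spacing

    def test_white_noise_spectrum_flat(self):
        v = np.random.default_rng(3).normal(size=(4096, 1, 3))
        sp = vacf_spectrum(v, 0.2)
        inner = sp.intensity[1:]
        assert inner.max() < 5.0 * np.median(inner)

    def test_resolution_scales_with_length(self):
        a = vacf_spectrum(np.random.default_rng(0).normal(size=(1000, 1, 3)), 0.2)
        b = vacf_spectrum(np.random.default_rng(0).normal(size=(2000, 1, 3)), 0.2)
        assert b.grid_spacing == pytest.approx(a.grid_spacing / 2)

    def test_intensities_nonnegative_grid_monotone(self):
        sp = vacf_spectrum(np.random.default_rng(1).normal(size=(256, 2, 3)), 0.5)
        assert np.all(sp.intensity >= 0)
        assert np.all(np.diff(sp.frequencies_cm1) > 0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            vacf_spectrum(np.zeros((1, 1, 3)), 0.2)
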