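"""DMC engine: propagation, branching, population control, force estimators,
time-step extrapolation."""

import dataclasses

import numpy as np
import pytest

import qmcforces as q
from qmcforces.dmc import (
    DmcConfig,
    Population,
    branch,
    force_hybrid,
    force_re,
    force_vd,
    propagate,
    run_dmc,
    timestep_extrapolate,
    update_trial_energy,
)
from qmcforces.vmc import ForceEstimate, VmcConfig, run_vmc, vmc_force


def _cfg(**kw):
    base = dict(
        tau=0.01,
        target_population=60,
        k_hist=20,
        steps=400,
        equilibration=60,
        seed=2,
    )
    base.update(kw)
    return DmcConfig(**base)


class TestPropagation:
    def test_exact_eigenfunction_constant_unit_weights(self, hydrogen, hydrogen_exact, rng):
        pop = Population(rng.standard_normal((20, 1, 3)), 1, 5)
        pop.init_windows([5])
        # E_T at the exact energy: S = 0 every step, weights stay 1
        for _ in range(10):
            propagate(pop, hydrogen_exact, 0.01, -0.5, rng, e_best=-0.5)
        assert np.allclose(pop.weights, 1.0, atol=1e-12)

    def test_branching_factor_printed_formula(self, hydrogen, hydrogen_exact, rng):
        # constant E_L 0.1 hartree below E_T at tau = 0.005 -> exp(0.0005)
        pop = Population(rng.standard_normal((10, 1, 3)), 1, 1)
        propagate(pop, hydrogen_exact, 0.005, -0.4, rng, e_best=-0.5)
        assert np.allclose(pop.weights, np.exp(0.005 * 0.1), atol=1e-12)

    def test_displacement_vanishes_with_timestep(self, hydrogen, hydrogen_exact):
        disp = []
        for tau in (1e-2, 1e-4, 1e-6):
            rng = np.random.default_rng(9)
            pop = Population(rng.standard_normal((10, 1, 3)), 1, 1)
            before = pop.coords.copy()
            propagate(pop, hydrogen_exact, tau, -0.5, rng, e_best=-0.5)
            disp.append(np.abs(pop.coords - before).max())
        assert disp[0] > disp[1] > disp[2]

    def test_invalid_timestep(self, hydrogen, hydrogen_exact, rng):
        pop = Population(rng.standard_normal((4, 1, 3)), 1, 1)
        with pytest.raises(ValueError):
            propagate(pop, hydrogen_exact, -0.01, -0.5, rng)


class TestBranching:
    def test_unit_weights_unchanged(self, rng):
        pop = Population(rng.standard_normal((25, 1, 3)), 1, 4)
        new, idx = branch(pop, rng)
        assert new.size == 25
        assert np.array_equal(new.coords, pop.coords)

    def test_integer_weight_exact_copies(self, rng):
        pop = Population(rng.standard_normal((1, 1, 3)), 1, 4)
        pop.weights[:] = 2.0
        new, idx = branch(pop, rng)
        assert new.size == 2
        assert np.array_equal(new.coords[0], new.coords[1])

    def test_expected_population_equals_total_weight(self, rng):
        counts = []
        w = np.array([0.3, 1.4, 0.9, 2.2])
        for _ in range(4000):
            pop = Population(np.zeros((4, 1, 3)), 1, 1)
            pop.weights = w.copy()
            new, _ = branch(pop, rng)
            counts.append(new.size)
        mean = np.mean(counts)
        sem = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - w.sum()) < 3 * sem

    def test_children_inherit_history(self, rng):
        pop = Population(rng.standard_normal((2, 1, 3)), 1, 3)
        pop.init_windows([3])
        for v in (1.0, 2.0, 3.0):
            pop.push_history(np.full((2, 1, 3), v))
        pop.weights[:] = np.array([3.0, 1e-9])
        new, idx = branch(pop, np.random.default_rng(0))
        assert np.all(idx == 0)
        assert np.allclose(new.window_sum(3), 6.0)
        w = new.walker(0)
        assert w.history.shape == (3, 1, 3)
        assert np.allclose(w.history[:, 0, 0], [1.0, 2.0, 3.0])

    def test_extinction_raises(self, rng):
        pop = Population(rng.standard_normal((2, 1, 3)), 1, 1)
        pop.weights[:] = 1e-12
        with pytest.raises(RuntimeError, match="extinction"):
            branch(pop, np.random.default_rng(1))


class TestTrialEnergyControl:
    def test_on_target_population_returns_estimate(self):
        assert update_trial_energy(-0.5, 100, 100, 0.02, 0.01) == pytest.approx(-0.5)

    def test_large_population_lowers_et(self):
        assert update_trial_energy(-0.5, 150, 100, 0.02, 0.01) < -0.5
        assert update_trial_energy(-0.5, 50, 100, 0.02, 0.01) > -0.5

    def test_closed_loop_population_stable(self, hydrogen):
        wf = q.slater_lcao(hydrogen, 0.85)
        res = run_dmc(hydrogen, wf, _cfg(steps=600, record_forces=False))
        trace = res.population_trace
        assert np.all(trace > 0.5 * 60) and np.all(trace < 1.5 * 60)


class TestEnergies:
    def test_exact_wavefunction_any_timestep(self, hydrogen, hydrogen_exact):
        for tau in (0.002, 0.05):
            res = run_dmc(hydrogen, hydrogen_exact, _cfg(tau=tau, steps=200, record_forces=False))
            assert res.energy == pytest.approx(-0.5, abs=1e-12)
            assert res.error == 0.0

    def test_nodeless_ground_state_exact_after_extrapolation(self, harmonic):
        # approximate nodeless trial: DMC projects to the exact 1.5 hartree
        wf = q.slater_lcao(harmonic, 1.0)  # wrong functional form on purpose
        points = []
        for tau in (0.06, 0.03, 0.015):
            res = run_dmc(
                harmonic,
                wf,
                _cfg(tau=tau, steps=1200, equilibration=200, target_population=150,
                     record_forces=False, seed=5),
            )
            points.append((tau, res.energy, res.error))
        e0, s0 = timestep_extrapolate(points)
        assert abs(e0 - 1.5) < 3 * max(s0, 1e-4)

    def test_projection_below_vmc_energy(self, two_center):
        wf = q.slater_lcao(two_center, 1.0, jastrow_en=[0.2, 0.2])
        vres = run_vmc(two_center, wf, VmcConfig(steps=600, walkers=150, burn_in=150,
                                                 seed=3, record_forces=False))
        dres = run_dmc(two_center, wf, _cfg(tau=0.02, steps=1200, equilibration=200,
                                            target_population=150, record_forces=False))
        assert dres.energy < vres.energy + 3 * np.hypot(vres.error, dres.error)


class TestForceEstimators:
    def test_vd_at_zero_history_equals_re(self, two_center):
        wf = q.slater_lcao(two_center, 1.0)
        res = run_dmc(two_center, wf, _cfg(steps=300, k_hist=10, equilibration=40))
        fre = force_re(res)
        fvd0 = force_vd(res, 0)
        assert np.array_equal(fre.forces, fvd0.forces)

    def test_exact_wavefunction_forces_match_vmc(self, hydrogen, hydrogen_exact):
        # constant E_L: every covariance term vanishes; both estimators
        # reduce to -<dE_L/dR> = 0 exactly
        res = run_dmc(hydrogen, hydrogen_exact, _cfg(steps=200))
        assert np.all(np.abs(force_re(res).forces) < 1e-10)
        assert np.all(np.abs(force_vd(res, 20).forces) < 1e-10)

    def test_harmonic_force_zero_within_errors(self, harmonic):
        wf = q.slater_lcao(harmonic, 1.2)  # approximate trial
        res = run_dmc(harmonic, wf, _cfg(tau=0.02, steps=1500, equilibration=200,
                                         target_population=100, k_hist=60, seed=6))
        for fe in (force_re(res), force_vd(res, 60)):
            assert np.all(np.abs(fe.forces) < 3.5 * fe.errors)

    def test_unrecorded_history_window_rejected(self, two_center):
        wf = q.slater_lcao(two_center, 1.0)
        res = run_dmc(two_center, wf, _cfg(steps=100, k_hist=10, equilibration=20))
        with pytest.raises(ValueError):
            force_vd(res, 37)

    def test_hybrid_identities(self):
        f1 = ForceEstimate(np.full((1, 3), 1.0), np.full((1, 3), 0.1), 10)
        f2 = ForceEstimate(np.full((1, 3), 0.8), np.full((1, 3), 0.2), 10)
        h = force_hybrid(f1, f2)
        assert np.allclose(h.forces, 1.2)
        # fixed point: F_RE == F_VMC -> hybrid == F_RE
        assert np.allclose(force_hybrid(f1, f1).forces, f1.forces)
        # errors grow in quadrature: always >= the RE error
        assert np.all(h.errors >= f1.errors)
        assert np.allclose(h.errors, np.hypot(2 * 0.1, 0.2))

    def test_hybrid_shape_mismatch(self):
        f1 = ForceEstimate(np.zeros((1, 3)), np.zeros((1, 3)), 1)
        f2 = ForceEstimate(np.zeros((2, 3)), np.zeros((2, 3)), 1)
        with pytest.raises(ValueError):
            force_hybrid(f1, f2)


class TestExtrapolation:
    def test_exact_line_recovered(self):
        pts = [(t, 1.5 + 2.0 * t, 0.0) for t in (0.01, 0.02, 0.04)]
        a, s = timestep_extrapolate(pts)
        assert a == pytest.approx(1.5, abs=1e-12)

    def test_noisy_replicates_within_three_sigma(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            pts = [
                (t, -0.6 + 1.3 * t + rng.normal(0, 0.002), 0.002)
                for t in (0.005, 0.01, 0.02, 0.04)
            ]
            a, s = timestep_extrapolate(pts)
            hits += abs(a - (-0.6)) < 3 * s
        assert hits >= int(0.97 * n_rep) - 3

    def test_duplicate_timesteps_averaged(self):
        pts = [(0.01, 1.0, 0.1), (0.01, 2.0, 0.1), (0.02, 2.0, 0.1)]
        a, s = timestep_extrapolate(pts)
        # duplicates at 0.01 average to 1.5; line through (0.01,1.5),(0.02,2.0)
        assert a == pytest.approx(1.0, abs=1e-9)

    def test_single_timestep_rejected(self):
        with pytest.raises(ValueError):
            timestep_extrapolate([(0.01, 1.0, 0.1), (0.01, 1.1, 0.1)])


class TestReproducibility:
    def test_same_seed_same_result(self, hydrogen):
        wf = q.slater_lcao(hydrogen, 0.9)
        a = run_dmc(hydrogen, wf, _cfg(steps=150, record_forces=False))
        b = run_dmc(hydrogen, wf, _cfg(steps=150, record_forces=False))
        assert a.energy == b.energy
        assert np.array_equal(a.population_trace, b.population_trace)
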