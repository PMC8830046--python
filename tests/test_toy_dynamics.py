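"""Toy Langevin systems: potential, integrator, committor oracle."""

import numpy as np
import pytest

import pathcommit as pc
from pathcommit.toy_dynamics import sample_equilibrium_configs

from oracles import committor_pde_1d


class TestPotential:
    def test_well_minimum_and_barrier_top(self):
        spec = pc.PotentialSpec(n_bath=2, n_noise_features=0)
        E, F = pc.evaluate_potential(spec, np.array([1.0, 1.0, 1.0]))
        assert E == pytest.approx(0.0)
        assert np.allclose(F, 0.0)
        E0, _ = pc.evaluate_potential(spec, np.zeros(3))
        assert E0 == pytest.approx(spec.barrier_height)

    def test_dimension_mismatch_names_expected_length(self):
        spec = pc.PotentialSpec(n_bath=3, n_noise_features=2)
        with pytest.raises(ValueError, match="length-6"):
            pc.evaluate_potential(spec, np.zeros(4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_force_matches_finite_differences(self, seed):
        spec = pc.PotentialSpec(n_bath=4, n_noise_features=2)
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=0.8, size=spec.n_dim)
        _, F = pc.evaluate_potential(spec, x)
        h = 1e-6
        for k in range(spec.n_dim):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            Ep, _ = pc.evaluate_potential(spec, xp)
            Em, _ = pc.evaluate_potential(spec, xm)
            fd = -(Ep - Em) / (2 * h)
            assert F[k] == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_noise_coordinates_feel_no_force(self):
        spec = pc.PotentialSpec(n_bath=1, n_noise_features=3)
        rng = np.random.default_rng(3)
        _, F = pc.evaluate_potential(spec, rng.normal(size=spec.n_dim))
        assert np.allclose(F[2:], 0.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            pc.PotentialSpec(barrier_height=-1.0)
        with pytest.raises(ValueError):
            pc.PotentialSpec(friction=0.0)
        with pytest.raises(ValueError):
            pc.PotentialSpec(kind="no_such_kind")


class TestIntegrator:
    def test_cold_start_at_minimum_stays(self, dw_1d):
        import dataclasses

        cold = dataclasses.replace(dw_1d, temperature=1e-300)
        traj = pc.integrate_langevin(
            cold, pc.PhasePoint([1.0], [0.0]), n_steps=500, rng_seed=0
        )
        assert np.allclose(traj.positions[:, 0], 1.0, atol=1e-8)

    def test_equipartition_in_harmonic_well(self):
        k = 4.0
        spec = pc.PotentialSpec(kind="harmonic_well", stiffness=k)
        traj = pc.integrate_langevin(
            spec, pc.PhasePoint([0.5], [0.0]), n_steps=150_000,
            timestep=0.05, rng_seed=7,
        )
        x = traj.positions[5000:, 0]
        # ~tau/dt correlated samples; 3 standard errors of the variance
        n_eff = x.size * 0.05 / 2.0
        se = np.sqrt(2.0 / n_eff) * (1.0 / k)
        assert abs(x.var() - 1.0 / k) < 3 * se

    def test_same_seed_is_bit_identical(self, dw_1d):
        a = pc.integrate_langevin(dw_1d, pc.PhasePoint([0.0], [1.0]),
                                  n_steps=200, rng_seed=42)
        b = pc.integrate_langevin(dw_1d, pc.PhasePoint([0.0], [1.0]),
                                  n_steps=200, rng_seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_nonfinite_energy_reports_step_index(self, dw_1d):
        with pytest.raises(FloatingPointError, match="step"):
            pc.integrate_langevin(
                dw_1d, pc.PhasePoint([1e8], [0.0]), n_steps=50,
                timestep=10.0, rng_seed=0,
            )

    def test_timestep_stability_bound_documented(self, dw_1d):
        # the bound is 2/omega_max; the default system must admit dt=0.01
        assert dw_1d.stability_limit() > 0.01


class TestMaxwellBoltzmann:
    def test_moments(self):
        v = pc.draw_maxwell_boltzmann(100_000, temperature=2.0, mass=0.5,
                                      rng_seed=0)
        var = 2.0 / 0.5
        assert abs(v.mean()) < 3 * np.sqrt(var / v.size)
        se_var = var * np.sqrt(2.0 / v.size)
        assert abs(v.var() - var) < 3 * se_var

    def test_zero_temperature_limit(self):
        v = pc.draw_maxwell_boltzmann(100, temperature=1e-300, mass=1.0,
                                      rng_seed=1)
        assert np.allclose(v, 0.0)


class TestBruteForceCommittor:
    def test_already_committed_configuration(self, dw_1d, states):
        res = pc.brute_force_committor(dw_1d, np.array([1.0]), states,
                                       n_trials=25, horizon=5.0, rng_seed=0)
        assert res.p_A == 1.0
        assert res.n_A == 25

    def test_symmetric_saddle_is_half(self, states):
        spec = pc.PotentialSpec(n_bath=2, n_noise_features=0)
        res = pc.brute_force_committor(
            spec, np.zeros(3), states, n_trials=100, horizon=30.0, rng_seed=1
        )
        assert res.resolved
        assert abs(res.p_A - 0.5) < 3 * np.sqrt(0.25 / (res.n_A + res.n_B))

    def test_all_unresolved_is_flagged(self, dw_1d, states):
        res = pc.brute_force_committor(
            dw_1d, np.zeros(1), states, n_trials=10, horizon=0.05, rng_seed=2
        )
        assert not res.resolved
        assert np.isnan(res.p_A)
        assert res.n_unresolved == 10

    def test_monotone_in_x(self, dw_1d, states):
        xs = np.array([-0.5, -0.25, 0.0, 0.25, 0.5])
        ps, ses = [], []
        for i, x in enumerate(xs):
            r = pc.brute_force_committor(
                dw_1d, np.array([x]), states, n_trials=150, horizon=30.0,
                rng_seed=10 + i,
            )
            ps.append(r.p_A)
            ses.append(np.sqrt(r.p_A * (1 - r.p_A) / (r.n_A + r.n_B)) + 1e-9)
        for i in range(len(xs) - 1):
            assert ps[i + 1] - ps[i] > -3 * (ses[i] + ses[i + 1])

    def test_matches_backward_kolmogorov_oracle(self, states):
        h, gamma = 4.0, 1.0
        spec = pc.PotentialSpec(barrier_height=h, n_bath=0,
                                n_noise_features=0, friction=gamma)
        oracle = committor_pde_1d(h, gamma, 1.0, 1.0, x_absorb=0.8)
        for i, x0 in enumerate((-0.3, 0.0, 0.35)):
            res = pc.brute_force_committor(
                spec, np.array([x0]), states, n_trials=400, horizon=40.0,
                rng_seed=20 + i, check_every=1,
            )
            p_ref = oracle(x0)
            se = np.sqrt(max(p_ref * (1 - p_ref), 1e-4) / 400)
            assert res.p_A == pytest.approx(p_ref, abs=3 * se)


class TestShootingDataset:
    def test_empty_dataset_has_valid_schema(self):
        spec = pc.default_double_well_spec(n_bath=2, n_noise_features=2)
        data = pc.generate_shooting_dataset(spec, n_points=0, n_trials=5)
        assert data.n_points == 0
        assert data.feature_names == ["x", "z1", "z2", "noise1", "noise2"]

    def test_basin_points_fully_committed(self):
        spec = pc.default_double_well_spec(n_bath=1, n_noise_features=0)
        data = pc.generate_shooting_dataset(
            spec, n_points=6, n_trials=10, region=(0.95, 1.05), rng_seed=3
        )
        assert np.all(data.n_A == 10)

    def test_empty_region_raises(self):
        spec = pc.default_double_well_spec()
        with pytest.raises(ValueError, match="region"):
            pc.generate_shooting_dataset(spec, n_points=5, region=(0.5, 0.5))

    def test_labels_match_pde_oracle_mean(self, states):
        h = 4.0
        spec = pc.PotentialSpec(barrier_height=h, n_bath=0,
                                n_noise_features=0)
        rng = np.random.default_rng(8)
        configs = sample_equilibrium_configs(spec, 30, (-0.4, 0.4), rng)
        data = pc.generate_shooting_dataset(
            spec, n_points=30, n_trials=60, rng_seed=9, configs=configs
        )
        oracle = committor_pde_1d(h, spec.friction, 1.0, 1.0, x_absorb=0.8)
        p_ref = np.mean([oracle(x) for x in configs[:, 0]])
        p_obs = np.nanmean(data.p_A)
        se = np.sqrt(0.25 / (30 * 60)) + 0.25 / np.sqrt(30)
        assert p_obs == pytest.approx(p_ref, abs=3 * se + 0.03)


class TestEquilibriumSampling:
    def test_marginal_matches_boltzmann(self):
        """Long-run histogram of x against exp(-V_dw(x)): the harmonic
        bath integrates out to an x-independent constant."""
        spec = pc.PotentialSpec(barrier_height=2.0, n_bath=2,
                                n_noise_features=0, friction=2.0)
        traj = pc.integrate_langevin(
            spec, pc.PhasePoint([1.0, 1.0, 1.0], [0.0, 0.0, 0.0]),
            n_steps=400_000, timestep=0.04, rng_seed=17,
        )
        x = traj.positions[10_000:, 0]
        counts, edges = np.histogram(x, bins=21, range=(-1.4, 1.4))
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 200
        F_obs = -np.log(counts[keep] / counts.sum())
        F_ref = spec.barrier_height * (centers[keep] ** 2 - 1) ** 2
        diff = F_obs - F_ref
        diff -= diff.mean()
        assert np.max(np.abs(diff)) < 0.35

    def test_window_sampler_stays_in_region(self):
        spec = pc.default_double_well_spec(n_bath=3, n_noise_features=2)
        rng = np.random.default_rng(0)
        P = sample_equilibrium_configs(spec, 500, (-0.2, 0.6), rng)
        assert P.shape == (500, spec.n_dim)
        assert P[:, 0].min() >= -0.2 and P[:, 0].max() <= 0.6
        # bath conditional: z_j - x has variance k_BT/kappa_j
        resid = P[:, 1] - P[:, 0]
        kap = spec.coupling_strengths[0]
        assert np.var(resid) == pytest.approx(1.0 / kap, rel=0.3)


class TestIdealShells:
    def test_octahedron_distances(self, octahedron):
        d = np.linalg.norm(octahedron.ligand_positions, axis=1)
        assert d.shape == (6,)
        assert np.allclose(d, 0.2)

    def test_tetrahedron_angles(self):
        cfg = pc.make_ideal_shell("tetrahedron", 0.15)
        v = cfg.ligand_positions / 0.15
        for i in range(4):
            for j in range(i + 1, 4):
                assert v[i] @ v[j] == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_square_pyramid_c4v(self):
        cfg = pc.make_ideal_shell("square_pyramid", 0.2)
        assert cfg.ligand_positions.shape == (5, 0 + 3)
        d = np.linalg.norm(cfg.ligand_positions, axis=1)
        assert np.allclose(d, 0.2)
        apex = cfg.ligand_positions[0]
        basal = cfg.ligand_positions[1:]
        # basal ligands perpendicular to the C4v axis, fourfold symmetric
        assert np.allclose(basal @ apex, 0.0, atol=1e-12)
        assert np.allclose(np.linalg.norm(basal, axis=1), 0.2)

    def test_unknown_geometry(self):
        with pytest.raises(ValueError, match="unknown geometry"):
            pc.make_ideal_shell("cube", 0.2)
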