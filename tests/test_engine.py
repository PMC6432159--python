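"""Force field and Langevin integrator physics."""

import numpy as np
import pytest

from conftest import free_chain_config, free_state, saw_positions
from poretrans import engine
from poretrans.engine import (bond_harmonic, compute_forces, coulomb_pair,
                              pair_wca, run_translocation)
from poretrans.system import SystemConfig, build_system

SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


class TestPairPotentials:
    @pytest.mark.parametrize("r_factor", [SIXTH_ROOT_2, 2.0, 5.0])
    def test_wca_vanishes_at_and_beyond_cutoff(self, r_factor):
        u, f = pair_wca(r_factor * 1.3, sigma=1.3, eps=2.0)
        assert u == pytest.approx(0.0, abs=1e-12)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_wca_at_contact_equals_eps(self):
        """At r = sigma the r^-12 and r^-6 terms cancel, leaving +eps."""
        u, f = pair_wca(1.0, sigma=1.0, eps=1.2)
        assert u == pytest.approx(1.2)
        assert f > 0

    def test_wca_singular_at_zero(self):
        with pytest.raises(ValueError):
            pair_wca(0.0, 1.0, 1.0)

    @pytest.mark.parametrize("length, tension", [
        (1.0, 0.0), (1.1, 60.0), (0.9, -60.0)])
    def test_bond_tension(self, length, tension):
        u, t = bond_harmonic(length, k=600.0, l0=1.0)
        assert t == pytest.approx(tension, abs=1e-9)
        assert u == pytest.approx(300.0 * (length - 1.0) ** 2)

    def test_coulomb_at_bjerrum_length(self):
        """Unit charges at r = lambda_B interact with exactly +-1 kBT."""
        assert coulomb_pair(3.0, +1, -1, bjerrum=3.0) == pytest.approx(-1.0)
        assert coulomb_pair(3.0, +1, +1, bjerrum=3.0) == pytest.approx(+1.0)

    def test_coulomb_singularity(self):
        with pytest.raises(ValueError):
            coulomb_pair(1e-9, 1, 1, 3.0)

    def test_screened_reduces_coupling(self):
        u_direct = coulomb_pair(3.0, 1, 1, 3.0)
        u_screened = coulomb_pair(3.0, 1, 1, 3.0, debye_length=4.9)
        assert 0 < u_screened < u_direct


class TestForcesAreExactGradients:
    def test_random_charge_gas(self):
        """Central differences match forces to 1e-6 relative (20 charges)."""
        rng = np.random.default_rng(2)
        pos = saw_positions(20, rng, bond=1.8)
        q = rng.choice([-1.0, 1.0], size=20)
        state = free_state(pos, charges=q)
        cfg = free_chain_config(2, electrostatics="direct", elec_cutoff=25.0)
        state.n_monomers = 1  # no bonds: pure WCA + Coulomb gas
        self._check(state, cfg, rng, n_probes=25, rel=1e-6, field_on=False)

    def test_built_system_with_wall_gate_field(self):
        """The full force field (WCA, bonds, screened Coulomb, wall, gate,
        field) is the exact negative gradient of its energy."""
        cfg = SystemConfig.desk(N=8, E=4.0)
        state = build_system(cfg.with_(seed=9))
        rng = np.random.default_rng(0)
        self._check(state, cfg, rng, n_probes=30, rel=2e-6,
                    field_on=True, gate_on=True)

    @staticmethod
    def _check(state, cfg, rng, n_probes, rel, **kw):
        F, _ = compute_forces(state, cfg, **kw)
        h = 1e-6
        mobidx = np.nonzero(state.mobile)[0]
        for _ in range(n_probes):
            i = rng.choice(mobidx)
            a = rng.integers(3)
            sp, sm = state.copy(), state.copy()
            sp.positions[i, a] += h
            sm.positions[i, a] -= h
            _, up = compute_forces(sp, cfg, **kw)
            _, um = compute_forces(sm, cfg, **kw)
            fd = -(up - um) / (2 * h)
            assert fd == pytest.approx(F[i, a], rel=rel, abs=1e-4)


class TestExternalForces:
    def test_field_acts_only_in_pore_with_charge_sign(self):
        cfg = free_chain_config(2, electrostatics="none")
        for q, z, fz in [(-1.0, 0.0, +4.0), (+1.0, 0.0, -4.0),
                         (-1.0, 10.0, 0.0), (-1.0, 2.25, +4.0)]:
            state = free_state(np.array([[0.0, 0.0, z]]), charges=[q])
            F, _ = compute_forces(state, cfg.with_(E=4.0), field_on=True)
            assert F[0, 2] == pytest.approx(fz)
            assert np.allclose(F[0, :2], 0.0)


class TestIntegrator:
    def test_zero_friction_energy_conservation(self):
        """zeta = 0 reduces to velocity Verlet: secular drift < 1e-3
        kBT/bead over 1e4 steps at dt = 0.005."""
        n = 8
        rng = np.random.default_rng(1)
        pos = np.column_stack([np.zeros(n), np.zeros(n), np.arange(n) * 1.06])
        state = free_state(pos, charges=-np.ones(n),
                           velocities=0.25 * rng.normal(size=(n, 3)))
        cfg = free_chain_config(n, electrostatics="direct", elec_cutoff=25.0)
        out = engine.integrate(state, cfg, n_steps=10_000, seed=3,
                               field_on=False, gate_on=False, zeta=0.0,
                               energy_stride=5)
        e = out["energies"]
        nb = len(e) // 10
        drift = abs(e[-nb:].mean() - e[:nb].mean()) / n
        assert drift < 1e-3

    def test_momentum_conservation(self):
        """Isolated, unthermostatted, field-free system conserves momentum."""
        rng = np.random.default_rng(4)
        pos = saw_positions(8, rng)
        state = free_state(pos, velocities=0.3 * rng.normal(size=(8, 3)))
        p0 = state.velocities.sum(axis=0).copy()
        cfg = free_chain_config(8)
        engine.integrate(state, cfg, n_steps=1000, seed=3, field_on=False,
                         gate_on=False, zeta=0.0)
        assert np.abs(state.velocities.sum(axis=0) - p0).max() < 1e-8

    def test_newtons_third_law(self):
        """Total force of an isolated system vanishes."""
        rng = np.random.default_rng(5)
        pos = saw_positions(12, rng)
        state = free_state(pos, charges=rng.choice([-1.0, 1.0], 12))
        cfg = free_chain_config(12, electrostatics="direct", elec_cutoff=25.0)
        F, _ = compute_forces(state, cfg, field_on=False)
        assert np.abs(F.sum(axis=0)).max() < 1e-10

    def test_equipartition_single_bead(self):
        """<v^2> = 3 kBT/m within 3 standard errors for a free bead."""
        state = free_state(np.zeros((1, 3)))
        cfg = free_chain_config(2)
        engine.integrate(state, cfg, n_steps=1000, seed=99, field_on=False,
                         gate_on=False)
        v2 = []
        for i in range(80):
            engine.integrate(state, cfg, n_steps=400, seed=1000 + i,
                             field_on=False, gate_on=False)
            v2.append(float((state.velocities ** 2).sum()))
        v2 = np.asarray(v2)
        se = v2.std(ddof=1) / np.sqrt(len(v2))
        assert abs(v2.mean() - 3.0) < 3 * se

    def test_bond_length_boltzmann_distribution(self):
        """Undriven bond lengths follow the Boltzmann weight of the bonded
        potential (harmonic + WCA), Jacobian r^2 - KS test at 1%."""
        from scipy import stats

        n = 16
        pos = np.column_stack([np.zeros(n), np.zeros(n), np.arange(n) * 1.05])
        state = free_state(pos)
        cfg = free_chain_config(n)
        engine.integrate(state, cfg, n_steps=20_000, seed=2, field_on=False,
                         gate_on=False)
        out = engine.integrate(state, cfg, n_steps=140_000, seed=3,
                               field_on=False, gate_on=False, frame_stride=200)
        bl = np.array([np.linalg.norm(np.diff(f[:n], axis=0), axis=1)
                       for f in out["frames"][5:]])

        k, l0, eps, sig = cfg.k, cfg.l0, cfg.eps_bb, cfg.sigma_bb
        rs = np.linspace(0.7, 1.3, 4001)
        u = 0.5 * k * (rs - l0) ** 2 + np.where(
            rs < SIXTH_ROOT_2 * sig,
            4 * eps * ((sig / rs) ** 12 - (sig / rs) ** 6) + eps, 0.0)
        w = rs**2 * np.exp(-(u - u.min()))
        cdf_grid = np.concatenate(
            [[0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(rs))])
        cdf_grid /= cdf_grid[-1]
        res = stats.kstest(bl.ravel()[::7], lambda x: np.interp(x, rs, cdf_grid))
        assert res.pvalue > 0.01
        # and the mean matches the quadrature oracle within 3 SE
        means = bl.mean(axis=1)
        se = means.std(ddof=1) / np.sqrt(len(means))
        theory = np.trapezoid(rs * w, rs) / np.trapezoid(w, rs)
        assert abs(bl.mean() - theory) < 3 * se

    def test_same_seed_bit_identical(self):
        cfg = SystemConfig.desk(N=8, E=8.0)
        s1 = build_system(cfg.with_(seed=4))
        s2 = build_system(cfg.with_(seed=4))
        engine.integrate(s1, cfg, n_steps=500, seed=11)
        engine.integrate(s2, cfg, n_steps=500, seed=11)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(s1.velocities, s2.velocities)

    def test_different_seed_differs(self):
        cfg = SystemConfig.desk(N=8, E=8.0)
        s1 = build_system(cfg.with_(seed=4))
        s2 = build_system(cfg.with_(seed=4))
        engine.integrate(s1, cfg, n_steps=500, seed=11)
        engine.integrate(s2, cfg, n_steps=500, seed=12)
        assert not np.array_equal(s1.positions, s2.positions)


class TestRunTranslocation:
    def test_small_strong_run_completes(self):
        cfg = SystemConfig.desk(N=16, E=32.0, equilibration_steps=5000)
        traj, rec = run_translocation(cfg, seed=2)
        assert rec.completed
        assert rec.s[-1] == 16
        assert rec.w.sum() == pytest.approx(rec.tau, rel=1e-9)

    def test_mean_tau_decreases_with_field(self, small_run_pair):
        tau4 = np.mean([r.tau for r in small_run_pair[4.0][1]])
        tau32 = np.mean([r.tau for r in small_run_pair[32.0][1]])
        assert all(r.completed for _, recs in small_run_pair.values()
                   for r in recs)
        assert tau32 < tau4

    def test_wall_beads_never_move(self):
        cfg = SystemConfig.desk(N=8, E=8.0)
        state = build_system(cfg.with_(seed=1))
        wall_before = state.wall_positions.copy()
        engine.integrate(state, cfg, n_steps=2000, seed=9)
        assert np.array_equal(state.wall_positions, wall_before)
        assert np.all(state.velocities[~state.mobile] == 0)

    def test_head_stays_past_pore_exit(self, strong_ensemble):
        """With the gate active the head never re-enters the channel."""
        cfg, _, trajs = strong_ensemble
        z_min = min(traj.positions[:, 0, 2].min() for traj in trajs)
        assert z_min > cfg.half_wall - 0.25

    def test_incomplete_run_is_flagged(self):
        cfg = SystemConfig.desk(N=16, E=0.2, equilibration_steps=2000,
                                step_budget=500)
        traj, rec = run_translocation(cfg, seed=3)
        assert not rec.completed
        assert rec.tau < 0
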