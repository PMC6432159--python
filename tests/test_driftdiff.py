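"""Drift velocity, entropic model, variance scaling, log-normal machinery."""

import numpy as np
import pytest

from poretrans import driftdiff as dd
from poretrans import fixtures as fx
from poretrans.tracking import TranslocationRecord, waiting_times


def _record(s_path, N, run_id=0, dt=1.0):
    t = np.arange(len(s_path)) * dt
    s = np.asarray(s_path)
    w, tau = waiting_times(t, s, N)
    return TranslocationRecord(run_id=run_id, seed=run_id, n_monomers=N,
                               times=t, s=s, waiting=w,
                               first_passage=np.zeros(N + 1), tau=tau,
                               completed=True)


class TestDriftVelocity:
    def test_reciprocal(self):
        assert dd.drift_velocity([2.0])[0] == pytest.approx(0.5)
        w = np.full(10, 0.25)
        assert np.allclose(dd.drift_velocity(w), 4.0)

    def test_zero_waiting_flagged_infinite(self):
        v = dd.drift_velocity([1.0, 0.0, 2.0])
        assert np.isinf(v[1])

    def test_reciprocity_identity(self):
        rng = np.random.default_rng(0)
        w = rng.exponential(1.0, size=50) + 0.01
        assert np.allclose(dd.drift_velocity(w) * w, 1.0)

    def test_velocity_minimum_at_waiting_maximum(self):
        s = np.linspace(0.05, 0.95, 31)
        w = np.exp(-((s - 0.7) ** 2) / 0.02)
        v = dd.drift_velocity(w)
        assert np.argmin(v) == np.argmax(w)


class TestEntropicModel:
    def test_balanced_at_midpoint(self):
        m = dd.DriftModel(N=64, E=1.0)
        assert m.entropic_force(32) == pytest.approx(0.0, abs=1e-15)

    def test_closed_form_value(self):
        """N=256, gamma'=0.69, s~=0.75: f = 0.31 (0.5/0.1875)/256."""
        m = dd.DriftModel(N=256, E=1.0)
        expected = 0.31 * (0.5 / 0.1875) / 256
        assert m.entropic_force(192) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.23e-3, rel=1e-2)

    def test_driving_and_friction_arithmetic(self):
        m = dd.DriftModel(N=64, E=8.0)
        out = dd.entropic_drift_model(m, 32, n_mono_pore=4, n_ion_pore=1)
        assert out["f_driving"] == pytest.approx(24.0)
        assert out["zeta_eff"] == pytest.approx(5.0)
        assert out["v_es"] == pytest.approx(24.0 / 5.0)

    def test_two_exponent_form_reduces_to_equal_case(self):
        a = dd.DriftModel(N=100, E=1.0, gamma_cis=0.69, gamma_trans=0.69)
        b = dd.DriftModel(N=100, E=1.0, gamma_cis=0.69, gamma_trans=0.690001)
        s = np.array([20.0, 50.0, 80.0])
        assert np.allclose(a.entropic_force(s), b.entropic_force(s), atol=1e-6)

    def test_divergence_at_ends_is_an_error(self):
        m = dd.DriftModel(N=16, E=1.0)
        with pytest.raises(ValueError, match="diverg"):
            m.entropic_force(0)
        with pytest.raises(ValueError, match="diverg"):
            m.free_energy(16)


class TestVarianceCurve:
    def test_population_variance_of_two_runs(self):
        a = _record([1, 1, 1, 4], N=4)
        b = _record([1, 3, 3, 4], N=4)
        grid, var = dd.variance_curve([a, b], n_grid=4, scaled=False)
        # at t=1: s=1 and s=3 -> population variance 1
        idx = np.argmin(np.abs(grid - 1.0))
        assert var[idx] == pytest.approx(1.0)
        assert var[0] == pytest.approx(0.0)

    def test_scaled_curve_vanishes_at_both_ends(self):
        rng = np.random.default_rng(1)
        recs = []
        for k in range(8):
            steps = rng.choice([0, 1], size=60)
            s = np.concatenate([[1], np.clip(1 + np.cumsum(steps), 1, 16)])
            s[-1] = 16
            recs.append(_record(s, N=16, run_id=k))
        grid, var = dd.variance_curve(recs, scaled=True)
        assert var[0] == pytest.approx(0.0)
        assert var[-1] == pytest.approx(0.0)
        assert var.max() > 0

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            dd.variance_curve([_record([1, 2, 3, 4], N=4)])


class TestDiffusionExponent:
    @pytest.mark.parametrize("power", [1.0, 2.0])
    def test_exact_power_laws(self, power):
        t = np.linspace(0.1, 10, 200)
        xi, se = dd.diffusion_exponent(t, 3.0 * t**power, (0.2, 8.0))
        assert xi == pytest.approx(power, abs=1e-9)

    def test_noisy_superdiffusion_recovered(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0.1, 10, 300)
        var = 2.0 * t**2.5 * np.exp(rng.normal(0, 0.01, size=t.size))
        xi, se = dd.diffusion_exponent(t, var, (0.2, 9.0))
        assert xi == pytest.approx(2.5, abs=0.1)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            dd.diffusion_exponent([1, 2], [1, 2], (5.0, 6.0))


class TestLogNormal:
    def test_density_peak_value(self):
        """At t = mu with sigma = 1, A = 1 the density is 1/sqrt(2 pi)."""
        assert dd.lognormal_density(1.0, 1.0, 1.0, 1.0) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi))

    def test_fwhm_small_sigma_expansion(self):
        """W -> 2 sqrt(2 ln 2) sigma mu as sigma -> 0."""
        mu = 7.0
        for sigma in (1e-3, 1e-4):
            lead = 2 * np.sqrt(2 * np.log(2)) * sigma * mu
            assert dd.lognormal_fwhm(sigma, mu) == pytest.approx(
                lead, rel=5 * sigma)

    def test_parameter_recovery_from_samples(self):
        """Histogram fit of 1e4 log-normal samples recovers (sigma, mu)
        within 5% and the closed-form mean matches the sample mean to 2 SE."""
        samples, truth = fx.lognormal_passage_samples(sigma=0.3, mu=50.0,
                                                      n=10_000, seed=4)
        edges = np.geomspace(samples.min() * 0.9, samples.max() * 1.1, 60)
        hist, _ = np.histogram(samples, bins=edges, density=True)
        centers = np.sqrt(edges[:-1] * edges[1:])
        fit = dd.lognormal_fit(centers, hist, A=1.0)
        assert fit.converged
        assert fit.sigma == pytest.approx(truth["sigma"], rel=0.05)
        assert fit.mu == pytest.approx(truth["mu"], rel=0.05)
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert abs(fit.mean_time - samples.mean()) < 2 * se + 0.02 * samples.mean()
        assert fit.W == pytest.approx(truth["fwhm"], rel=0.1)

    def test_failure_reported_not_raised(self):
        fit = dd.lognormal_fit(np.array([1.0, 2.0]), np.array([0.1, 0.2]),
                               A=1.0)
        assert not fit.converged


class TestRetardation:
    def test_on_schedule_is_zero(self):
        N, tau = 16, 32.0
        s = np.arange(1, N)
        ts = s * tau / N
        _, delta, info = dd.retardation(ts, tau, N, s)
        assert np.allclose(delta, 0.0, atol=1e-12)

    def test_uniform_delay_is_constant(self):
        N, tau, shift = 16, 32.0, 3.0
        s = np.arange(1, N)
        _, delta, _ = dd.retardation(s * tau / N + shift, tau, N, s)
        assert np.allclose(delta, shift / tau)

    def test_s_shaped_schedule_crosses_zero_near_inflection(self):
        """delta_s = 0 where <t_s> crosses the constant-speed schedule,
        near the inflection of an S-shaped <t_s>."""
        N = 100
        s = np.arange(1, N)
        x = s / N
        tau = 50.0
        ts = tau * (x + 0.2 * np.sin(2 * np.pi * (x - 0.5)))
        _, delta, info = dd.retardation(ts, tau, N, s)
        zeros = info["zero_crossings"]
        assert any(abs(z / N - 0.5) < 0.05 for z in zeros)


class TestHumpAndScaling:
    def test_unimodal_peak_found(self):
        st = np.linspace(0.02, 0.98, 49)
        wt = np.exp(-((st - 0.8) ** 2) / 0.01)
        assert dd.hump_position(st, wt) == pytest.approx(0.8, abs=0.02)

    def test_window_excludes_boundary_spikes(self):
        st = np.linspace(0.01, 0.99, 99)
        wt = np.exp(-((st - 0.6) ** 2) / 0.02)
        wt[0] = 100.0  # switch-on spike
        wt[-1] = 50.0  # end overshoot
        assert dd.hump_position(st, wt) == pytest.approx(0.6, abs=0.02)

    def test_symmetric_curve_peaks_at_half(self):
        N = 64
        st = np.arange(1, N) / N
        wt = st * (1 - st)
        assert dd.hump_position(st, wt) == pytest.approx(0.5, abs=1.0 / N)

    def test_scaling_exponent_recovered_exactly(self):
        """Constructed family with N - s* = 2 N^0.58 returns exponent 0.58."""
        curves = {}
        for N in (64, 128, 256, 512):
            s_star = N - 2.0 * N**0.58
            st = np.arange(1, N) / N
            wt = np.exp(-((st - s_star / N) ** 2) / 0.005)
            curves[(N, 8.0)] = (st, wt)
        out = dd.hump_and_scaling(curves)
        exp = out["scaling"][8.0]["exponent"]
        assert exp == pytest.approx(0.58, abs=0.02)

    def test_too_few_chain_lengths_rejected(self):
        st = np.linspace(0.02, 0.98, 20)
        wt = np.ones(20)
        with pytest.raises(ValueError):
            dd.hump_and_scaling({(64, 1.0): (st, wt), (128, 1.0): (st, wt)})


class TestOccupancyDensity:
    def test_integrates_to_waiting_fraction(self):
        """The time integral of p(s, t) equals A_s = w(s)/<tau>."""
        rng = np.random.default_rng(2)
        recs = []
        for k in range(12):
            steps = rng.choice([0, 1], size=80)
            s = np.clip(1 + np.cumsum(steps), 1, 8)
            s[-1] = 8
            recs.append(_record(s, N=8, run_id=k, dt=0.5))
        from poretrans.tracking import ensemble_waiting

        ens = ensemble_waiting(recs)
        s_probe = 4
        centers, p = dd.occupancy_density(recs, s_probe, n_bins=400)
        # crude quadrature on the log grid
        integral = np.sum(p[:-1] * np.diff(centers))
        expected = ens.w[s_probe - 1] / ens.tau_mean
        assert integral == pytest.approx(expected, rel=0.15)


def test_lognormal_fit_of_first_passage_times_matches_direct_mean(
        strong_ensemble):
    """Fitting the first-passage-time density at a state with the log-normal
    form reproduces the directly measured mean arrival time (the
    drift-diffusion consistency check) at interior states."""
    cfg, records, _ = strong_ensemble
    N = cfg.N
    for s_probe in (N // 4, N // 2, 3 * N // 4):
        fp = np.array([r.first_passage[s_probe] for r in records])
        fp = fp[fp >= 0]
        edges = np.geomspace(fp.min() * 0.8, fp.max() * 1.2, 13)
        hist, _ = np.histogram(fp, bins=edges, density=True)
        centers = np.sqrt(edges[:-1] * edges[1:])
        fit = dd.lognormal_fit(centers, hist, A=1.0, s=s_probe)
        se = fp.std(ddof=1) / np.sqrt(fp.size)
        assert fit.converged
        assert abs(fit.mean_time - fp.mean()) < max(3 * se, 0.1 * fp.mean())
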