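"""Stochastic promoter model: generator, master equation, SSA, MS2 signal."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import null_space

import hbdyn as h
from hbdyn.promoter_model import MS2Params


def uniform_kin(n, ku=0.25, **kw):
    return h.PromoterKinetics.uniform(n, ku, **kw)


class TestGenerator:
    @pytest.mark.parametrize("n", [1, 3, 6, 9])
    def test_rows_sum_to_zero(self, n):
        q = h.build_generator(uniform_kin(n), x=-5.0)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
        off = q[~np.eye(n + 1, dtype=bool)]
        assert np.all(off >= 0)

    def test_single_site_detailed_balance(self):
        # k_b = k_u at the boundary => stationary (1/2, 1/2)
        kin = uniform_kin(1, ku=0.25)
        np.testing.assert_allclose(h.stationary_distribution(kin, 0.0), [0.5, 0.5])

    @pytest.mark.parametrize("n,ku", [(3, 0.1), (6, 0.4)])
    def test_uniform_unbinding_gives_binomial_stationary_law(self, n, ku):
        """Independent sites: brute-force eigenvector equals Binomial(N, p)."""
        kin = uniform_kin(n, ku)
        x = -3.0
        q = h.build_generator(kin, x)
        pi_numeric = null_space(q.T)[:, 0]
        pi_numeric = pi_numeric / pi_numeric.sum()
        kb = kin.binding_rate(x)
        p = kb / (kb + ku)
        pi_binom = stats.binom.pmf(np.arange(n + 1), n, p)
        np.testing.assert_allclose(pi_numeric, pi_binom, atol=1e-10)
        np.testing.assert_allclose(h.stationary_distribution(kin, x), pi_binom,
                                   atol=1e-10)

    def test_position_outside_gradient_domain_rejected(self):
        with pytest.raises(ValueError):
            h.build_generator(uniform_kin(2), x=np.nan)


class TestMasterEquation:
    def test_starts_empty_and_conserves_probability(self):
        kin = uniform_kin(6)
        sol = h.solve_master_equation(kin, -5.0, np.linspace(0, 400, 81))
        assert sol.probabilities[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(sol.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(sol.probabilities >= 0)
        assert np.all(sol.probabilities <= 1)

    def test_converges_to_stationary_distribution(self):
        kin = uniform_kin(4, ku=0.3)
        sol = h.solve_master_equation(kin, 2.0, np.array([0.0, 2000.0]))
        np.testing.assert_allclose(sol.probabilities[-1],
                                   h.stationary_distribution(kin, 2.0), atol=1e-6)


class TestSSA:
    def test_absorbing_when_unbinding_is_zero(self):
        kin = h.PromoterKinetics(n_sites=3, k_u=np.zeros(3))
        traj = h.simulate_ssa(kin, 0.0, 500.0, seed=0)
        assert traj.states[-1] == 3
        on = traj.on_intervals()
        assert on.shape == (1, 2) and on[0, 1] == 500.0

    def test_same_seed_same_jump_sequence(self):
        kin = uniform_kin(5)
        t1 = h.simulate_ssa(kin, -2.0, 300.0, seed=11)
        t2 = h.simulate_ssa(kin, -2.0, 300.0, seed=11)
        np.testing.assert_array_equal(t1.times, t2.times)
        np.testing.assert_array_equal(t1.states, t2.states)

    def test_time_in_state_matches_master_equation(self):
        """Monte-Carlo occupancy agrees with the ODE within 3 binomial SEs."""
        kin = uniform_kin(4, ku=0.2)
        x, t_obs, n_traj = -2.0, 250.0, 200
        sol = h.solve_master_equation(kin, x, np.array([0.0, t_obs]))
        expected = sol.probabilities[-1]
        rng = np.random.default_rng(123)
        counts = np.zeros(5)
        for _ in range(n_traj):
            traj = h.simulate_ssa(kin, x, t_obs + 1.0, seed=rng)
            counts[traj.state_at(np.array([t_obs]))[0]] += 1
        frac = counts / n_traj
        se = np.sqrt(expected * (1 - expected) / n_traj)
        assert np.all(np.abs(frac - expected) <= 3 * se + 1e-9)


class TestInitiations:
    def test_no_on_time_no_events(self):
        kin = h.PromoterKinetics(n_sites=2, k_u=np.array([10.0, 10.0]))
        traj = h.PromoterTrajectory(np.array([0.0]), np.array([0]), 100.0, 2)
        assert h.simulate_initiations(traj, 1.0, seed=0).size == 0

    def test_poisson_mean_and_variance(self):
        # fixed ON time T: counts ~ Poisson(k_ini * T)
        traj = h.PromoterTrajectory(np.array([0.0]), np.array([2]), 50.0, 2)
        rng = np.random.default_rng(7)
        counts = [h.simulate_initiations(traj, 0.4, seed=rng).size for _ in range(800)]
        lam = 0.4 * 50.0
        assert np.mean(counts) == pytest.approx(lam, rel=0.05)
        assert np.var(counts) == pytest.approx(lam, rel=0.15)

    def test_events_uniform_within_on_intervals(self):
        traj = h.PromoterTrajectory(np.array([0.0]), np.array([1]), 100.0, 1)
        rng = np.random.default_rng(3)
        ev = np.concatenate([h.simulate_initiations(traj, 0.5, seed=rng)
                             for _ in range(200)])
        # conditional uniformity of Poisson arrivals on [0, 100]
        counts, _ = np.histogram(ev, bins=10, range=(0, 100))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=9) > 1e-3

    def test_events_confined_to_on_intervals(self):
        kin = uniform_kin(3, ku=0.5)
        traj = h.simulate_ssa(kin, -5.0, 400.0, seed=5)
        ev = h.simulate_initiations(traj, 0.5, seed=6)
        on = traj.on_intervals()
        for e in ev:
            assert any(a <= e <= b for a, b in on)


class TestMS2Signal:
    def test_loop_count_shape(self):
        p = MS2Params()
        assert h.ms2_loop_count(0.0, p) == 0.0
        assert h.ms2_loop_count(-5.0, p) == 0.0
        # between cassette completion and release: all 24 loops
        assert h.ms2_loop_count(100.0, p) == 24.0
        assert h.ms2_loop_count(p.t_release, p) == 0.0
        mid = 0.5 * (p.t_cassette_start + p.t_cassette_full)
        assert h.ms2_loop_count(mid, p) == pytest.approx(12.0)

    def test_intensity_of_one_event(self):
        p = MS2Params()
        times = np.array([0.0, p.t_cassette_full + 1.0])
        inten = h.synthesize_intensity(np.array([0.0]), p, times)
        assert inten[0] == 0.0
        assert inten[1] == 24.0

    def test_zero_events_zero_trace(self):
        inten = h.synthesize_intensity(np.array([]), MS2Params(), np.linspace(0, 500, 50))
        assert np.all(inten == 0)

    def test_steady_mean_matches_renewal_theory(self):
        """Under constant-rate firing, mean I = rate * area under L(t)."""
        p = MS2Params()
        rate = 0.2
        rng = np.random.default_rng(42)
        horizon = 4000.0
        n_ev = rng.poisson(rate * horizon)
        events = np.sort(rng.uniform(0, horizon, n_ev))
        times = np.linspace(500.0, horizon - 200.0, 400)
        mean_i = h.synthesize_intensity(events, p, times).mean()
        t_dense = np.linspace(0, p.t_release, 20001)
        area = np.trapezoid(h.ms2_loop_count(t_dense, p), t_dense)
        assert mean_i == pytest.approx(rate * area, rel=0.05)

    def test_unsorted_events_rejected(self):
        with pytest.raises(ValueError):
            h.synthesize_intensity(np.array([5.0, 1.0]), MS2Params(),
                                   np.linspace(0, 10, 5))


class TestSpotProbability:
    def test_timecourse_zero_before_first_mature_transcript(self, independent6):
        p = MS2Params()
        ts = np.arange(0.0, 300.0, 5.0)
        ps = h.spot_probability_timecourse(independent6, 0.0, ts)
        assert np.all(ps[ts < p.t_cassette_full] == 0.0)
        assert ps[-1] > 0

    def test_anterior_reaches_plateau_before_boundary(self, fitted6):
        ts = np.arange(0.0, 700.0, 5.0)
        kin = fitted6.kinetics
        def t90(x):
            ps = h.spot_probability_timecourse(kin, x, ts)
            steady = h.spot_probability_steady(kin, x)
            return ts[np.nonzero(ps >= 0.9 * steady)[0][0]]
        assert t90(-15.0) < t90(0.0)

    def test_mature_transcript_fraction_matches_master_equation(self, fitted6):
        """The exact SSA observable behind the deterministic P_SPOT.

        The deterministic computation gives the probability of at least one
        initiation inside the full-cassette visibility window; the same
        event counted over 300 trajectories must agree within Monte-Carlo
        error.
        """
        kin = fitted6.kinetics
        p = h.MS2Params()
        t_obs, n_traj = 600.0, 300
        rng = np.random.default_rng(9)
        n_visible = 0
        for _ in range(n_traj):
            traj = h.simulate_ssa(kin, 0.0, t_obs, seed=rng)
            ev = h.simulate_initiations(traj, kin.k_ini, seed=rng)
            in_window = (ev >= t_obs - p.t_release) & (ev < t_obs - p.t_cassette_full)
            n_visible += bool(np.any(in_window))
        expected = h.spot_probability_timecourse(kin, 0.0, np.array([0.0, t_obs]))[-1]
        se = np.sqrt(expected * (1 - expected) / n_traj)
        assert n_visible / n_traj == pytest.approx(expected, abs=3.5 * se)

    def test_intensity_threshold_pattern_brackets_deterministic_value(self, fitted6):
        """Thresholding the full MS2 intensity can only add spots.

        Partially transcribed cassettes contribute intensity the
        one-mature-transcript computation ignores, so the simulated
        P_SPOT sits at or slightly above the deterministic value.
        """
        kin = fitted6.kinetics
        times = np.arange(0.0, 700.0, 13.05)
        pat = h.pattern_from_model(kin, np.array([0.0]), times, n_traj=200, seed=9)
        steady_ssa = pat.pspot[-8:, 0].mean()
        assert steady_ssa >= 0.5 - 3 * np.sqrt(0.25 / 200)
        assert steady_ssa <= 0.5 + 0.18

    def test_master_method_matches_direct_call(self, independent6):
        times = np.arange(0.0, 400.0, 10.0)
        pat = h.pattern_from_model(independent6, np.array([-5.0, 0.0]), times,
                                   method="master")
        direct = h.spot_probability_timecourse(independent6, -5.0, times)
        np.testing.assert_allclose(pat.pspot[:, 0], direct, atol=1e-12)


class TestKinetics:
    def test_binding_rate_is_concentration_scaled_cap(self, gradient):
        kin = uniform_kin(6)
        assert kin.binding_rate(0.0) == pytest.approx(1 / 4.0)
        assert kin.binding_rate(gradient.lambda_el) == pytest.approx(np.exp(-1) / 4.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            h.PromoterKinetics(n_sites=0, k_u=np.array([]))
        with pytest.raises(ValueError):
            h.PromoterKinetics(n_sites=2, k_u=np.array([-1.0, 1.0]))
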