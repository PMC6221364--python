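"""Pattern statistics: P_SPOT, P_ON, alignment, sigmoid fits, zones."""

import numpy as np
import pytest

import hbdyn as h
from hbdyn.pattern_stats import PonProfile, _logistic


class TestPspot:
    def test_all_active_gives_one_everywhere(self):
        pos = np.linspace(-20, 20, 50)
        act = np.ones((50, 4), dtype=bool)
        grid = h.compute_pspot(pos, act, np.arange(4.0))
        assert np.nanmax(grid.pspot) == np.nanmin(grid.pspot) == 1.0

    def test_bernoulli_half_within_binomial_ci(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-20, 20, 400)
        act = rng.random((400, 3)) < 0.5
        grid = h.compute_pspot(pos, act, np.arange(3.0), bins=10.0)
        for b, n in enumerate(grid.counts):
            se = np.sqrt(0.25 / n)
            assert np.all(np.abs(grid.pspot[:, b] - 0.5) <= 4 * se)

    def test_time_slices_are_independent(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(-10, 10, 60)
        act = rng.random((60, 5)) < 0.4
        g1 = h.compute_pspot(pos, act, np.arange(5.0))
        g2 = h.compute_pspot(pos, act[:, ::-1], np.arange(5.0))
        np.testing.assert_allclose(g1.pspot, g2.pspot[::-1], equal_nan=True)

    def test_empty_bin_is_nan_not_zero(self):
        pos = np.array([-10.0, -9.5, 10.0])
        act = np.ones((3, 2), dtype=bool)
        grid = h.compute_pspot(pos, act, np.arange(2.0), bins=2.0)
        assert np.isnan(grid.pspot[:, grid.counts == 0]).all()


class TestPon:
    def test_single_frame_activity_counts(self):
        pos = np.array([0.0, 0.5])
        act = np.array([[False, True, False], [False, False, False]])
        prof = h.compute_pon(pos, act, bins=np.array([-1.0, 1.0]))
        assert prof.pon[0] == 0.5

    def test_silent_embryo_gives_zero_profile(self):
        pos = np.linspace(-5, 5, 30)
        prof = h.compute_pon(pos, np.zeros(30, dtype=bool), bins=5.0)
        assert np.nansum(prof.pon) == 0.0

    def test_pon_dominates_pspot_on_many_embryos(self):
        """P_ON(x) >= max_t P_SPOT(t, x) for every synthetic embryo."""
        rng = np.random.default_rng(2)
        for _ in range(40):
            pos = rng.uniform(-25, 25, 120)
            p = 1 / (1 + np.exp(7 * pos / 20))
            act = rng.random((120, 6)) < p[:, None] * rng.uniform(0.3, 1.0, 6)
            grid = h.compute_pspot(pos, act, np.arange(6.0), bins=5.0)
            prof = h.compute_pon(pos, act, bins=5.0)
            gap = prof.pon[None, :] - grid.pspot
            assert np.nanmin(gap) >= -1e-12


class TestAlignment:
    def profile(self, shift=0.0, h_exp=7.0):
        x = np.arange(-25, 25.1, 2.0)
        return PonProfile(x, _logistic(x, 1.0, h_exp, shift, 20.0),
                          np.full(x.size, 30))

    def test_already_aligned_profile_zero_shift(self):
        shifts, _ = h.align_embryos([self.profile(0.0)])
        assert shifts[0] == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_recovers_known_shift(self):
        shifts, aligned = h.align_embryos([self.profile(3.0)])
        assert shifts[0] == pytest.approx(-3.0, abs=0.05)
        s2, _ = h.align_embryos(aligned)
        assert s2[0] == pytest.approx(0.0, abs=1e-6)

    def test_alignment_reduces_boundary_spread(self):
        """Gradient variability of 2-3% EL is compensated by alignment."""
        rng = np.random.default_rng(3)
        raw = [self.profile(shift=rng.normal(0, 2.5)) for _ in range(12)]
        shifts, aligned = h.align_embryos(raw)
        def spread(profiles):
            xs = []
            for p in profiles:
                fit = h.fit_sigmoid(p.x_centers, p.pon)
                xs.append(fit.x0)
            return np.std(xs)
        assert spread(aligned) < spread(raw)

    def test_non_crossing_profile_excluded(self):
        x = np.arange(-25, 25.1, 2.0)
        flat = PonProfile(x, np.full(x.size, 0.9), np.full(x.size, 30))
        with pytest.warns(UserWarning):
            shifts, aligned = h.align_embryos([flat])
        assert np.isnan(shifts[0]) and not aligned


class TestSigmoidFit:
    def test_noiseless_logistic_recovered_exactly(self):
        x = np.arange(-25, 25.1, 1.0)
        y = _logistic(x, 1.0, 7.0, -5.0, 20.0)
        fit = h.fit_sigmoid(x, y, lambda_el=20.0)
        assert fit.hill == pytest.approx(7.0, abs=1e-6)
        assert fit.x0 == pytest.approx(-5.0, abs=1e-6)
        assert fit.rss < 1e-8
        assert fit.ok

    def test_independent_six_site_pattern_has_hill_1_31(self, independent6):
        """Non-cooperative six-site steady pattern: H ~ 1.31 (Berg-Purcell regime).

        The Hill coefficient of this asymmetric profile is its boundary-local
        log-slope; the numeric value from the master equation must match the
        closed form 2N(1 - 2^(-1/N)).
        """
        h_local = h.hill_of_model(independent6, observable="occupancy")
        assert h_local == pytest.approx(h.hill_independent_sites(6), abs=0.01)
        assert h_local == pytest.approx(1.31, abs=0.05)
        # a global sigmoid fit of the same profile overestimates the local
        # steepness (the posterior flank is steeper than the boundary)
        x = np.linspace(-60, 60, 121)
        y = np.array([h.stationary_distribution(independent6, xi)[-1] for xi in x])
        fit = h.fit_sigmoid(x, y, lambda_el=20.0)
        assert fit.hill > h_local

    def test_doubling_lambda_doubles_hill(self):
        x = np.arange(-25, 25.1, 1.0)
        y = _logistic(x, 1.0, 5.0, 0.0, 20.0)
        f1 = h.fit_sigmoid(x, y, lambda_el=20.0)
        f2 = h.fit_sigmoid(x, y, lambda_el=40.0)
        assert f2.hill == pytest.approx(2 * f1.hill, rel=1e-6)

    def test_steepness_recovery_on_binomial_fixtures(self):
        """Fitted H within 15% of truth in >= 90% of 500-nucleus samples."""
        h_true = 6.0
        good = 0
        n_seeds = 40
        for seed in range(n_seeds):
            df = h.sample_hill_activity(500, h_true, x0=0.0, seed=seed)
            prof = h.compute_pon(df["x_pct_el"].to_numpy(),
                                 df["active"].to_numpy(), bins=2.0)
            ok = prof.counts > 0
            fit = h.fit_sigmoid(prof.x_centers[ok], prof.pon[ok],
                                counts=prof.counts[ok])
            good += abs(fit.hill - h_true) <= 0.15 * h_true
        assert good >= 0.9 * n_seeds

    def test_non_bracketing_data_flagged(self):
        x = np.linspace(-25, -15, 11)
        y = _logistic(x, 1.0, 7.0, 10.0, 20.0)  # far from the boundary
        fit = h.fit_sigmoid(x, y)
        assert not fit.ok


class TestFormationTime:
    def test_step_function(self):
        t = np.arange(0.0, 400.0, 5.0)
        v = np.where(t >= 200.0, 1.0, 0.0)
        ft = h.formation_time(t, v)
        assert (ft.t_first, ft.t_steady, ft.delta_t) == (200.0, 200.0, 0.0)

    def test_logistic_rise_onset_150_steady_330(self):
        """A rise built with onset 150 s and 95% at 330 s gives dt = 180 s."""
        t = np.arange(0.0, 500.0, 13.05)
        t50, slope = 240.0, (330.0 - 150.0) / 6.0  # 5%..95% spans ~6 slopes
        v = 0.5 / (1 + np.exp(-(t - t50) / slope))
        v[v < 0.5 * 0.05] = 0.0  # below detection: no signal yet
        ft = h.formation_time(t, v, plateau_tol=0.05)
        assert ft.t_first == pytest.approx(150.0, abs=13.05)
        assert ft.t_steady == pytest.approx(330.0, abs=13.05)
        assert ft.delta_t == pytest.approx(180.0, abs=2 * 13.05)

    def test_series_without_plateau_rejected(self):
        with pytest.raises(ValueError):
            h.formation_time(np.arange(5.0), np.zeros(5))


class TestBoundaryFromDensity:
    def test_step_density_boundary(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-20, 10, 4000)
        b = h.boundary_from_density(pos, bins=np.arange(-20.0, 20.1, 1.0))
        assert b == pytest.approx(10.0, abs=2.0)

    def test_logistic_density_midpoint(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(-25, 25, 20000)
        keep = rng.random(x.size) < 1 / (1 + np.exp(7 * (x - 2.0) / 20))
        b = h.boundary_from_density(x[keep], bins=2.0)
        assert b == pytest.approx(2.0, abs=3.0)

    def test_flat_density_flagged(self):
        pos = np.repeat(np.arange(-10.0, 10.0, 2.0), 50) + 1.0
        with pytest.warns(UserWarning):
            b = h.boundary_from_density(pos, bins=np.arange(-10.0, 10.1, 2.0),
                                        smooth_window=1)
        assert np.isnan(b)


class TestZonePartition:
    def test_identical_distribution_no_edge(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-25, 0, 400)
        v = rng.normal(10.0, 1.0, 400)
        part = h.partition_zones(x, v, window=5.0)
        assert part.edge_x is None

    def test_three_sd_shift_detected_near_true_edge(self):
        """Power: the edge lands within one window of x=-8 in >=90% of runs."""
        rng = np.random.default_rng(8)
        found = 0
        n_sim = 60
        for _ in range(n_sim):
            x = rng.uniform(-25, 0, 500)
            v = rng.normal(0.0, 1.0, 500)
            v[x >= -8.0] += 3.0
            part = h.partition_zones(x, v, window=5.0)
            if part.edge_x is not None and abs(part.edge_x - (-8.0)) <= 5.0:
                found += 1
        assert found >= 0.9 * n_sim

    def test_alpha_one_fires_at_first_window(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(-25, 0, 300)
        v = rng.normal(0.0, 1.0, 300)
        part = h.partition_zones(x, v, window=5.0, alpha=1.0)
        assert part.edge_x == part.window_centers[0]


def test_kymograph_export(tmp_path):
    x = np.arange(-25.0, 25.1, 2.0)
    times = np.arange(0.0, 100.0, 25.0)
    vals = np.tile(_logistic(x, 1.0, 6.0, 0.0, 20.0), (times.size, 1))
    grid = h.PatternGrid(x, times, vals, np.full(x.size, 10))
    from hbdyn.pattern_stats import plot_kymograph
    plot_kymograph(grid, tmp_path / "kymo.png")
    assert (tmp_path / "kymo.png").stat().st_size > 0


class TestSteepnessOverTime:
    def grid_from_model(self, fitted6):
        times = np.arange(100.0, 650.0, 25.0)
        xs = np.arange(-24.0, 25.0, 2.0)
        pat = h.pattern_from_model(fitted6.kinetics, xs, times, method="master")
        return h.PatternGrid(xs, times, pat.pspot, np.full(xs.size, 50))

    def test_model_steepness_is_nondecreasing_toward_steady(self, fitted6):
        grid = self.grid_from_model(fitted6)
        hs = h.steepness_over_time(grid).dropna(subset=["hill"])
        vals = hs["hill"].to_numpy()
        assert vals.size >= 5
        assert np.all(np.diff(vals) >= -0.15)  # monotone up to fit noise
        assert vals[-1] > vals[0]

    def test_final_slice_matches_direct_fit(self, fitted6):
        grid = self.grid_from_model(fitted6)
        hs = h.steepness_over_time(grid)
        direct = h.fit_sigmoid(grid.x_centers, grid.pspot[-1], lambda_el=20.0)
        assert hs["hill"].iloc[-1] == pytest.approx(direct.hill, rel=1e-6)

    def test_constant_pattern_gives_flat_series(self):
        x = np.arange(-25.0, 25.1, 2.0)
        y = _logistic(x, 1.0, 6.0, 0.0, 20.0)
        grid = h.PatternGrid(x, np.arange(4.0), np.tile(y, (4, 1)),
                             np.full(x.size, 20))
        hs = h.steepness_over_time(grid)
        np.testing.assert_allclose(hs["hill"], 6.0, atol=1e-6)
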