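import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from promap import (
    ConditionPair,
    WindowConfig,
    WindowEstimate,
    compute_ma,
    fit_variance_function,
    make_windows,
    plotting_positions,
    qq_regression,
    rescaled_qq_summary,
)

A_CONST = 0.3175


def brute_force_positions(n, omega, a):
    """Term-by-term evaluation of the plotting-position product formula."""
    out = []
    for i in omega:
        prod = 1.0
        for j in omega:
            if j >= i:
                prod *= (j - a) / (j - a + 1.0)
        out.append((n - a + 1.0) / (n - 2.0 * a + 1.0) * prod)
    return np.array(out)


class TestComputeMA:
    @pytest.mark.parametrize(
        "s1, s2, a, m",
        [(8.0, 2.0, 2.0, 2.0), (7.0, 7.0, np.log2(7), 0.0), (1.0, 4.0, 1.0, -2.0)],
    )
    def test_exact_values(self, s1, s2, a, m):
        pair = ConditionPair(
            ids=np.array(["x"], dtype=object), a=np.array([s1]), b=np.array([s2])
        )
        points = compute_ma(pair)
        assert points["A"].iloc[0] == pytest.approx(a, abs=1e-12)
        assert points["M"].iloc[0] == pytest.approx(m, abs=1e-12)

    def test_nonpositive_intensity_names_protein(self):
        pair = ConditionPair(
            ids=np.array(["good", "bad"], dtype=object),
            a=np.array([2.0, 1.0]),
            b=np.array([2.0, 1.0]),
        )
        pair.a[1] = 0.0  # bypass the constructor check
        with pytest.raises(ValueError, match="bad"):
            compute_ma(pair)


class TestMakeWindows:
    @staticmethod
    def oracle(n, size, step):
        """Brute-force enumeration of the window rule."""
        starts = [s for s in range(0, n + 1, step) if s + size <= n]
        if starts[-1] + size < n:
            starts.append(n - size)
        return [(s, s + size) for s in starts]

    @pytest.mark.parametrize(
        "n, expected_count, last",
        [(1000, 7, (600, 1000)), (400, 1, (0, 400)), (950, 7, (550, 950))],
    )
    def test_window_enumeration(self, n, expected_count, last):
        windows = make_windows(n, WindowConfig(size=400, step=100))
        assert windows == self.oracle(n, 400, 100)
        assert len(windows) == expected_count
        assert windows[0] == (0, 400)
        assert windows[-1] == last

    def test_fewer_points_than_window_rejected(self):
        with pytest.raises(ValueError, match="smaller window"):
            make_windows(399, WindowConfig(size=400))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(20, 500), st.integers(20, 200), st.integers(1, 200))
    def test_windows_cover_every_index(self, n, size, step):
        """The union of window ranges is exactly 0..n-1."""
        if size > n or step > size:
            return
        windows = make_windows(n, WindowConfig(size=max(size, 20), step=min(step, size)))
        covered = set()
        for s, e in windows:
            covered.update(range(s, e))
        assert covered == set(range(n))


class TestPlottingPositions:
    @pytest.mark.parametrize("n", [5, 17, 100, 1000])
    def test_complete_sample_telescopes_to_closed_form(self, n):
        omega = np.arange(1, n + 1)
        p, q = plotting_positions(n, omega, A_CONST)
        closed = (omega - A_CONST) / (n - 2 * A_CONST + 1)
        np.testing.assert_allclose(p, closed, rtol=0, atol=1e-12)
        # symmetry of the complete sample: p_i + p_{n+1-i} = 1
        np.testing.assert_allclose(p + p[::-1], 1.0, atol=1e-12)
        # quantiles are antisymmetric about zero
        np.testing.assert_allclose(q, -q[::-1], atol=1e-9)

    def test_n5_closed_form(self):
        p, _ = plotting_positions(5, np.arange(1, 6), 0.3175)
        np.testing.assert_allclose(
            p, (np.arange(1, 6) - 0.3175) / 5.365, atol=1e-12
        )

    def test_middle_subset_matches_bruteforce(self):
        omega = np.array([3, 4, 5, 6])
        p, _ = plotting_positions(8, omega, A_CONST)
        np.testing.assert_allclose(p, brute_force_positions(8, omega, A_CONST), atol=0)

    def test_positions_lie_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            k = int(rng.integers(1, n + 1))
            omega = np.sort(rng.choice(np.arange(1, n + 1), size=k, replace=False))
            p, _ = plotting_positions(n, omega, A_CONST)
            assert np.all((p > 0) & (p < 1))

    def test_empty_omega_rejected(self):
        with pytest.raises(ValueError):
            plotting_positions(10, np.array([]), A_CONST)


class TestQQRegression:
    def test_exact_linear_data_recovered(self):
        cfg = WindowConfig(size=40, step=40, middle_fraction=0.5)
        _, q = plotting_positions(40, np.arange(1, 41), cfg.a)
        m = 0.3 + 0.5 * q  # already sorted since q is increasing
        est = qq_regression(m, cfg)
        assert est.mu == pytest.approx(0.3, abs=1e-12)
        assert est.sigma == pytest.approx(0.5, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not est.degenerate

    def test_constant_window_is_degenerate(self):
        est = qq_regression(np.full(40, 1.7), WindowConfig(size=40, step=40))
        assert est.degenerate
        assert est.sigma == 0.0
        assert est.mu == pytest.approx(1.7)

    def test_monte_carlo_scale_recovery(self):
        """Repeated null windows recover sigma without material bias."""
        cfg = WindowConfig()
        rng = np.random.default_rng(11)
        sigmas = [
            qq_regression(rng.normal(0.0, 0.5, 400), cfg).sigma for _ in range(200)
        ]
        se = np.std(sigmas, ddof=1) / np.sqrt(len(sigmas))
        assert abs(np.mean(sigmas) - 0.5) < 5 * se

    def test_shift_invariance_and_scale_equivariance(self):
        cfg = WindowConfig(size=50, step=50)
        rng = np.random.default_rng(3)
        m = rng.normal(0, 0.4, 50)
        base = qq_regression(m, cfg)
        shifted = qq_regression(m + 1.23, cfg)
        scaled = qq_regression(m * 3.0, cfg)
        assert shifted.sigma == pytest.approx(base.sigma, rel=1e-9)
        assert shifted.mu == pytest.approx(base.mu + 1.23, rel=1e-9)
        assert scaled.sigma == pytest.approx(3.0 * base.sigma, rel=1e-9)

    def test_too_small_window_rejected(self):
        with pytest.raises(ValueError):
            qq_regression(np.ones(10), WindowConfig(size=20, step=20))


def _estimate(mean_a, sigma2, mu=0.0, index=0):
    return WindowEstimate(
        index=index,
        start=0,
        stop=0,
        mu=mu,
        sigma=float(np.sqrt(sigma2)),
        r_squared=1.0,
        mean_a=mean_a,
        n_selected=200,
    )


class TestFitVarianceFunction:
    def test_constant_variance_gives_flat_exponential(self):
        ests = [_estimate(a, 0.25, index=i) for i, a in enumerate([10, 15, 20])]
        model = fit_variance_function(ests)
        assert model.theta2 == pytest.approx(0.0, abs=1e-8)
        assert model.theta1 == pytest.approx(np.log(0.25), abs=1e-8)
        assert model.fit_r_squared == 1.0

    def test_two_windows_interpolate_exactly(self):
        ests = [_estimate(10.0, 0.2, index=0), _estimate(20.0, 0.02, index=1)]
        model = fit_variance_function(ests)
        np.testing.assert_allclose(
            model.variance([10.0, 20.0]), [0.2, 0.02], rtol=1e-8
        )
        assert model.fit_r_squared == pytest.approx(1.0, abs=1e-10)

    def test_parameter_recovery_with_one_percent_noise(self):
        rng = np.random.default_rng(5)
        a_values = np.linspace(10, 25, 40)
        sigma2 = np.exp(2.0 - 0.4 * a_values) * rng.normal(1.0, 0.01, 40)
        model = fit_variance_function(
            [_estimate(a, s2, index=i) for i, (a, s2) in enumerate(zip(a_values, sigma2))]
        )
        assert model.theta1 == pytest.approx(2.0, rel=0.05)
        assert model.theta2 == pytest.approx(-0.4, rel=0.05)

    def test_sigma_mu_sq_is_variance_of_intercepts(self):
        mus = [0.01, -0.02, 0.03]
        ests = [
            _estimate(a, np.exp(2 - 0.4 * a), mu=mu, index=i)
            for i, (a, mu) in enumerate(zip([10, 15, 20], mus))
        ]
        model = fit_variance_function(ests)
        assert model.sigma_mu_sq == pytest.approx(np.var(mus, ddof=1))

    def test_fewer_than_two_usable_windows_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_variance_function([_estimate(10.0, 0.2)])

    def test_too_many_degenerate_windows_abort(self):
        good = [_estimate(a, np.exp(2 - 0.4 * a), index=i) for i, a in enumerate([10, 12, 14])]
        bad = WindowEstimate(
            index=3, start=0, stop=0, mu=0.0, sigma=0.0, r_squared=0.0,
            mean_a=16.0, n_selected=200, degenerate=True,
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit_variance_function(good + [bad])


class TestRescaledQQSummary:
    def test_single_exact_window_lies_on_y_equals_x(self):
        cfg = WindowConfig(size=40, step=40)
        _, q = plotting_positions(40, np.arange(1, 41), cfg.a)
        m = 0.5 * q
        est = qq_regression(m, cfg)
        summary = rescaled_qq_summary(m, [(0, 40)], [est], cfg)
        np.testing.assert_allclose(summary["mean"], summary["q"], atol=1e-9)
        np.testing.assert_array_equal(summary["sd"], 0.0)

    def test_identical_windows_have_zero_sd(self):
        cfg = WindowConfig(size=40, step=40)
        rng = np.random.default_rng(9)
        block = rng.normal(0, 0.5, 40)
        m = np.concatenate([block, block])
        ests = [
            qq_regression(block, cfg, window_index=0, start=0),
            qq_regression(block, cfg, window_index=1, start=40),
        ]
        summary = rescaled_qq_summary(m, [(0, 40), (40, 80)], ests, cfg)
        np.testing.assert_allclose(summary["sd"], 0.0, atol=1e-12)

    def test_partial_windows_excluded(self):
        cfg = WindowConfig(size=40, step=40)
        rng = np.random.default_rng(10)
        m = rng.normal(0, 0.5, 70)
        ests = [
            qq_regression(m[:40], cfg, window_index=0, start=0),
            qq_regression(m[40:], cfg, window_index=1, start=40),
        ]
        summary = rescaled_qq_summary(m, [(0, 40), (40, 70)], ests, cfg)
        assert summary["n_windows"].iloc[0] == 1
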