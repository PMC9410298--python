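"""Statistics stage: log-normal fits, rank correlations against brute-force
enumeration, Kruskal-Wallis, bootstrap, and the plateau estimator."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemocoherence.stats import (
    StatsError,
    bootstrap_correlation,
    compare_velocity_distributions,
    estimate_plateau,
    fit_lognormal,
    rank_correlation,
)


def brute_force_tau_b(x, y):
    """Exhaustive concordant/discordant enumeration with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) // 2
    return (nc - nd) / math.sqrt((n0 - tx) * (n0 - ty))


class TestLogNormalFit:
    def test_degenerate_sample(self):
        fit = fit_lognormal([math.e] * 3)
        assert fit.mu_log == pytest.approx(1.0)
        assert fit.sigma_log == 0.0
        assert fit.ks_p == 1.0

    def test_parameter_recovery(self, rng):
        mu, sigma = 2.554, 0.5545
        draws = rng.lognormal(mu, sigma, size=10_000)
        fit = fit_lognormal(draws)
        se = sigma / math.sqrt(draws.size)
        assert abs(fit.mu_log - mu) < 3 * se
        assert fit.implied_mean == pytest.approx(15.0, rel=0.05)
        assert fit.ks_p > 0.01

    def test_moment_identity(self):
        fit = fit_lognormal([5.0, 10.0, 20.0, 40.0])
        assert fit.implied_mean == pytest.approx(
            math.exp(fit.mu_log + fit.sigma_log**2 / 2)
        )

    def test_domain_errors(self):
        with pytest.raises(StatsError):
            fit_lognormal([1.0, 2.0])
        with pytest.raises(StatsError):
            fit_lognormal([1.0, -2.0, 3.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = compare_velocity_distributions([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert h == 0.0
        assert p == 1.0

    def test_hand_computed_fixture(self):
        # ranks 1..6 split cleanly: H = 12/(6*7) * (36/3 + 225/3) - 21
        h, p = compare_velocity_distributions([[1, 2, 3], [10, 11, 12]])
        assert h == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(0.0495, abs=1e-3)

    def test_needs_two_groups(self):
        with pytest.raises(StatsError):
            compare_velocity_distributions([[1, 2, 3]])


class TestRankCorrelation:
    def test_perfect_monotone(self):
        r = rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.coefficient == pytest.approx(1.0)

    def test_enumerated_fixture(self):
        # pairs of (1,2,3,4) vs (2,1,4,3): 4 concordant, 2 discordant
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        assert brute_force_tau_b(x, y) == pytest.approx(1 / 3)
        r = rank_correlation(x, y)
        assert r.coefficient == pytest.approx(1 / 3)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        for method in ("kendall", "spearman"):
            a = rank_correlation(x, y, method).coefficient
            b = rank_correlation(x, -y, method).coefficient
            assert a == pytest.approx(-b)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(StatsError):
            rank_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=8),
        st.data(),
    )
    def test_tau_matches_exhaustive_enumeration(self, x, data):
        y = data.draw(
            st.lists(st.integers(0, 5), min_size=len(x), max_size=len(x))
        )
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        expected = brute_force_tau_b(x, y)
        got = rank_correlation(x, y, "kendall").coefficient
        assert got == pytest.approx(expected, abs=1e-12)

    def test_spearman_example(self):
        r = rank_correlation([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], "spearman")
        assert r.coefficient == pytest.approx(0.8)


class TestBootstrap:
    def test_monotone_data_has_degenerate_interval(self):
        x = np.arange(8.0)
        bs = bootstrap_correlation(x, 2 * x + 1, n_resamples=30, seed=5)
        np.testing.assert_allclose(bs.replicates, 1.0, rtol=1e-12)
        np.testing.assert_allclose(bs.ci, (1.0, 1.0), rtol=1e-12)
        assert bs.point_estimate == pytest.approx(1.0)

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = bootstrap_correlation(x, y, seed=9)
        b = bootstrap_correlation(x, y, seed=9)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_large_resample_concentrates_on_plug_in(self, rng):
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        bs = bootstrap_correlation(x, y, n_resamples=2000, seed=3)
        assert abs(bs.point_estimate - bs.plug_in.coefficient) < 0.05
        lo, hi = bs.ci
        assert lo < bs.plug_in.coefficient < hi

    def test_minimum_sample_size(self):
        with pytest.raises(StatsError):
            bootstrap_correlation([1, 2, 3], [3, 2, 1])


class TestPlateau:
    def test_constant_plateau(self):
        est = estimate_plateau([14.0] * 5, [8, 10, 15, 20, 24])
        assert est.mean == 14.0
        assert est.sd == 0.0
        assert est.n_in_band == 5

    def test_band_selection_is_closed(self):
        est = estimate_plateau([14.0, 12.0, 14.2], [24.0, 30.0, 6.0])
        assert est.n_in_band == 2
        assert est.mean == pytest.approx(14.1)

    def test_empty_band_is_explicit(self):
        est = estimate_plateau([12.0, 13.0], [30.0, 40.0])
        assert est.n_in_band == 0
        assert est.mean is None
        assert est.mean_rounded is None
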