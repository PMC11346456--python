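import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import poisson
from sklearn.base import clone

from abxdyn import (
    CouponCollectorDiscovery,
    DiscoveryParams,
    EstimationError,
    YearlyCounts,
    discovery_loglik,
    expected_discoveries,
    expected_distinct_given_draws,
    fit_discovery,
)


def enumerate_expected_distinct(k: int, m: int) -> float:
    """Brute force: average distinct count over all k**m equally likely draws."""
    if m == 0:
        return 0.0
    total = 0
    for draws in itertools.product(range(k), repeat=m):
        total += len(set(draws))
    return total / k**m


class TestExpectedDistinct:
    def test_two_draws_from_three_classes(self):
        # 9 equally likely pairs: 3 doubles, 6 distinct pairs -> (3*1 + 6*2)/9
        assert enumerate_expected_distinct(3, 2) == pytest.approx(5 / 3, abs=1e-15)
        assert expected_distinct_given_draws(3, 2) == pytest.approx(5 / 3, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_matches_enumeration(self, k):
        for m in range(7):
            assert expected_distinct_given_draws(k, m) == pytest.approx(
                enumerate_expected_distinct(k, m), abs=1e-12)

    def test_single_coupon_saturates(self):
        for m in (1, 5, 100):
            assert expected_distinct_given_draws(1, m) == 1.0

    def test_saturation_limit(self):
        assert expected_distinct_given_draws(5, 1000) == pytest.approx(5.0, abs=1e-9)

    def test_strictly_increasing_below_pool_size(self):
        vals = [expected_distinct_given_draws(7, m) for m in range(50)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 7

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            expected_distinct_given_draws(0, 3)
        with pytest.raises(ValueError):
            expected_distinct_given_draws(3, -1)


class TestExpectedDiscoveries:
    def test_zero_during_lag_phase(self):
        p = DiscoveryParams(k=30, n=1.5, t_lag=28, t0=1900)
        assert expected_discoveries(1900, p) == 0.0
        assert expected_discoveries(1928, p) == 0.0

    def test_closed_form_value(self):
        p = DiscoveryParams(k=30, n=1.5, t_lag=28, t0=1900)
        assert expected_discoveries(1950, p) == pytest.approx(30 * (1 - math.exp(-1.1)))

    def test_poisson_mixture_identity(self, rng):
        """Averaging the fixed-draw expectation over a Poisson number of
        draws reproduces k(1 - exp(-n tau / k))."""
        for _ in range(20):
            k = int(rng.integers(2, 100))
            n = float(rng.uniform(0.1, 5.0))
            tau = float(rng.uniform(0.5, 80.0))
            nu = n * tau
            m_hi = int(nu + 20 * math.sqrt(nu) + 50)
            ms = np.arange(m_hi + 1)
            mix = float(np.sum(poisson.pmf(ms, nu) *
                               [expected_distinct_given_draws(k, int(m)) for m in ms]))
            p = DiscoveryParams(k=k, n=n, t_lag=0, t0=0)
            assert mix == pytest.approx(expected_discoveries(tau, p), abs=1e-9)

    def test_bounded_by_pool_and_linear_limit(self):
        p = DiscoveryParams(k=30, n=1.5, t_lag=0, t0=0)
        t = np.linspace(0, 500, 100)
        d = expected_discoveries(t, p)
        assert np.all(d <= 30 + 1e-12)
        assert np.all(np.diff(d) >= 0)
        # infinite-pool limit: no rediscovery, growth is linear at rate n
        big = DiscoveryParams(k=10**6, n=1.5, t_lag=0, t0=0)
        assert expected_discoveries(40.0, big) == pytest.approx(1.5 * 40, rel=1e-3)


class TestDiscoveryLoglik:
    def test_empty_window_gives_zero(self):
        counts = YearlyCounts(1900, [0, 0, 0])
        p = DiscoveryParams(k=10, n=1.0, t_lag=50, t0=1900)
        assert discovery_loglik(counts, p) == 0.0

    def test_count_before_onset_is_impossible(self):
        counts = YearlyCounts(1900, [1, 0, 0])
        p = DiscoveryParams(k=10, n=1.0, t_lag=5, t0=1900)
        assert discovery_loglik(counts, p) == float("-inf")

    def test_matches_hand_computation_on_toy_series(self):
        """Term-by-term independent computation with math.* only."""
        counts = YearlyCounts(1950, [1, 2, 0])
        p = DiscoveryParams(k=10, n=2.0, t_lag=0, t0=1950)
        expected = 0.0
        for i, c in enumerate([1, 2, 0]):
            d0 = 10 * (1 - math.exp(-2.0 * i / 10))
            d1 = 10 * (1 - math.exp(-2.0 * (i + 1) / 10))
            mu = d1 - d0
            expected += c * math.log(mu) - mu - math.lgamma(c + 1)
        assert discovery_loglik(counts, p) == pytest.approx(expected, abs=1e-12)

    def test_telescoping_increments(self):
        p = DiscoveryParams(k=30, n=1.5, t_lag=28, t0=1900)
        years = np.arange(1900, 2021, dtype=float)
        mu = np.diff(expected_discoveries(years, p))
        assert mu.sum() == pytest.approx(
            expected_discoveries(2020, p) - expected_discoveries(1900, p), abs=1e-10)


def _noise_free_counts(params: DiscoveryParams, end_year: int) -> YearlyCounts:
    """Integer counts whose cumulative sum tracks E[D(t)] to within 0.5.

    Rounding the cumulative curve (not the per-year means) keeps the total
    and the timing of the expected curve; per-year rounding would flatten
    sub-unit means into a caricature block of 0s and 1s.
    """
    years = np.arange(params.t0, end_year + 1, dtype=float)
    cum = np.rint(np.asarray(expected_discoveries(years, params))).astype(int)
    return YearlyCounts(params.t0, np.diff(cum))


class TestFitDiscovery:
    def test_noise_free_recovery(self):
        truth = DiscoveryParams(k=30, n=1.5, t_lag=28, t0=1900)
        counts = _noise_free_counts(truth, 1990)
        fit = fit_discovery(counts, k_max=200, t_lag_max=60)
        assert abs(fit.params.t_lag - 28) <= 3
        assert fit.params.n == pytest.approx(1.5, rel=0.20)
        assert fit.converged

    def test_matches_brute_force_grid_on_small_instance(self):
        """Exhaustive dense-grid oracle over (k, n, t_lag) on a toy series."""
        truth = DiscoveryParams(k=5, n=1.0, t_lag=2, t0=0)
        counts = _noise_free_counts(truth, 15)
        fit = fit_discovery(counts, k_max=12, t_lag_max=5)
        best_oracle = -np.inf
        argmax = None
        for k in range(counts.total, 13):
            for t_lag in range(0, 6):
                res = minimize_scalar(
                    lambda n: -discovery_loglik(counts, DiscoveryParams(k, n, t_lag, 0))
                    if n > 0 else np.inf,
                    bounds=(1e-6, 20.0), method="bounded", options={"xatol": 1e-10})
                if -res.fun > best_oracle:
                    best_oracle = -res.fun
                    argmax = (k, t_lag)
        assert fit.loglik == pytest.approx(best_oracle, abs=1e-6)
        assert (fit.params.k, fit.params.t_lag) == argmax

    def test_fit_is_deterministic(self):
        truth = DiscoveryParams(k=5, n=1.0, t_lag=2, t0=0)
        counts = _noise_free_counts(truth, 15)
        a = fit_discovery(counts, k_max=12, t_lag_max=5)
        b = fit_discovery(counts, k_max=12, t_lag_max=5)
        assert (a.params, a.loglik) == (b.params, b.loglik)

    def test_k_max_below_observed_rejected(self):
        counts = YearlyCounts(1900, [2, 1, 2])
        with pytest.raises(ValueError, match="k_max"):
            fit_discovery(counts, k_max=3)

    def test_single_year_counts_rejected(self):
        with pytest.raises(EstimationError):
            fit_discovery(YearlyCounts(1900, [5, 0, 0]))


class TestYearlyCounts:
    def test_from_years_tallies_and_window(self):
        c = YearlyCounts.from_years([1950, 1950, 1953], start_year=1948, end_year=1955)
        assert c.start_year == 1948
        assert c.counts.tolist() == [0, 0, 2, 0, 0, 1, 0, 0]
        assert c.total == 3

    def test_years_outside_window_rejected(self):
        with pytest.raises(ValueError):
            YearlyCounts.from_years([1950], start_year=1960, end_year=1970)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            YearlyCounts(1900, [-1, 2])


class TestEstimator:
    def test_fit_predict_contract(self):
        truth = DiscoveryParams(k=30, n=1.5, t_lag=28, t0=1900)
        counts = _noise_free_counts(truth, 1990)
        est = CouponCollectorDiscovery(k_max=100).fit(counts)
        assert est.k_ >= counts.total
        assert abs(est.t_lag_ - 28) <= 3
        pred = est.predict([1900, 1950, 2100])
        assert pred[0] == 0.0
        assert np.all(np.diff(pred) > 0)
        assert est.score(counts) == pytest.approx(est.loglik_)

    def test_sklearn_params_contract(self):
        est = CouponCollectorDiscovery(k_max=50, t_lag_max=10)
        assert clone(est).get_params() == est.get_params()
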