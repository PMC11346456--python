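"""Coupon-collector model of antibacterial class discovery.

Discovery is modelled as sampling with replacement from a finite pool of
``k`` drug classes: screening draws arrive as a homogeneous Poisson
process at rate ``n`` per year, starting after a lag of ``t_lag`` years
from an origin year ``t0``, and each draw lands on one of the ``k``
classes uniformly at random. A class is "discovered" at its first draw.

Conditional on ``m`` draws, the expected number of distinct classes seen
is the classic coupon-collector expectation

    E[distinct | m] = k * (1 - (1 - 1/k)**m),

and marginalising over the Poisson number of draws in an elapsed time
``tau`` gives the exact expectation

    E[D(t)] = k * (1 - exp(-n * tau / k)),    tau = max(0, t - t0 - t_lag).

Early on this grows linearly at rate ``n`` (the golden age of discovery);
as the pool is exhausted, draws increasingly re-discover known classes
and the curve saturates at ``k`` — the rediscovery plateau.

Fitting treats the yearly counts of newly discovered classes as
independent Poisson variates whose means are the yearly increments of
E[D(t)] ("Poisson maximum likelihood"). The likelihood is maximised over
an integer grid in ``k`` and ``t_lag`` with a bounded continuous search
in ``n`` at each grid point. Treating increments as independent is an
approximation — true increments are negatively correlated near
saturation — but is unbiased in the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .errors import EstimationError


@dataclass(frozen=True)
class DiscoveryParams:
    """Coupon-collector parameters: pool size k, draw rate n (per year),
    lag t_lag (years) and origin calendar year t0."""

    k: int
    n: float
    t_lag: float
    t0: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("pool size k must be >= 1")
        if self.n <= 0:
            raise ValueError("sampling rate n must be > 0")
        if self.t_lag < 0:
            raise ValueError("lag t_lag must be >= 0")


@dataclass
class DiscoveryFit:
    """Maximum-likelihood discovery parameters plus search provenance."""

    params: DiscoveryParams
    loglik: float
    searched: str
    converged: bool

    def to_dict(self) -> dict:
        return {
            "k": self.params.k,
            "n": self.params.n,
            "t_lag": self.params.t_lag,
            "t0": self.params.t0,
            "loglik": self.loglik,
            "searched": self.searched,
            "converged": self.converged,
        }


@dataclass
class YearlyCounts:
    """New-class counts per calendar year, ``counts[i]`` for year
    ``start_year + i``. The total equals the number of discovered classes."""

    start_year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("yearly counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(len(self.counts))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_years(cls, years, start_year: int | None = None,
                   end_year: int | None = None) -> "YearlyCounts":
        """Tally event years into a contiguous yearly count series.

        ``start_year``/``end_year`` extend (or clip is an error: years must
        fall inside) the window; by default the window spans the observed
        years exactly. Trailing zero years matter to the likelihood — pass
        ``end_year`` = observation year so the model sees the drought.
        """
        years = np.asarray(years, dtype=int)
        if years.size == 0:
            if start_year is None or end_year is None:
                raise ValueError("empty year list needs an explicit window")
            return cls(start_year, np.zeros(end_year - start_year + 1, dtype=int))
        lo = int(years.min()) if start_year is None else int(start_year)
        hi = int(years.max()) if end_year is None else int(end_year)
        if years.min() < lo or years.max() > hi:
            raise ValueError("event years fall outside the requested window")
        counts = np.bincount(years - lo, minlength=hi - lo + 1)
        return cls(lo, counts)


def expected_distinct_given_draws(k: int, m: int) -> float:
    """Coupon-collector expectation: distinct classes after m uniform draws.

    Exactly ``k * (1 - (1 - 1/k)**m)``; 0 at m = 0, strictly increasing in
    m, and < k for any finite m when k > 1.
    """
    if k < 1 or m < 0:
        raise ValueError("need k >= 1 and m >= 0")
    if m == 0:
        return 0.0
    if k == 1:
        return 1.0
    return float(k * -np.expm1(m * np.log1p(-1.0 / k)))


def expected_discoveries(t, params: DiscoveryParams):
    """E[D(t)] = k (1 - exp(-n tau / k)), tau = max(0, t - t0 - t_lag).

    The exact marginal expectation when draws arrive as a rate-``n``
    Poisson process; vectorised over ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    tau = np.maximum(0.0, t_arr - params.t0 - params.t_lag)
    out = params.k * -np.expm1(-params.n * tau / params.k)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _yearly_means(edges: np.ndarray, k: float, n: float, t_lag: float) -> np.ndarray:
    """Expected new discoveries per year: increments of E[D] on year edges
    given as offsets from t0.

    Computed in incremental form k * exp(-a tau0) * (1 - exp(-a dtau)),
    a = n/k, not by differencing the cumulative curve: near saturation the
    cumulative form rounds to exactly k in float64 and differencing would
    return spurious zeros for the late-year means.
    """
    tau = np.maximum(0.0, edges - t_lag)
    a = n / k
    return k * np.exp(-a * tau[:-1]) * -np.expm1(-a * np.diff(tau))


def discovery_loglik(counts: YearlyCounts, params: DiscoveryParams) -> float:
    """Poisson log-likelihood of yearly new-class counts under E[D] increments.

    Years with model mean 0 but a positive count are impossible under the
    model: the function returns ``-inf`` (not an exception).
    """
    edges = np.arange(len(counts) + 1, dtype=float) + (counts.start_year - params.t0)
    mu = _yearly_means(edges, params.k, params.n, params.t_lag)
    c = counts.counts
    if np.any((mu <= 0) & (c > 0)):
        return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(c > 0, c * np.log(np.where(mu > 0, mu, 1.0)), 0.0) - mu - gammaln(c + 1)
    return float(np.sum(ll))


def fit_discovery(
    counts: YearlyCounts,
    k_max: int = 200,
    t_lag_max: float = 60,
    t0: int | None = None,
    n_max: float = 50.0,
) -> DiscoveryFit:
    """Maximum-likelihood (k, n, t_lag) by exhaustive integer-grid search.

    The grid is integer ``k`` from the observed number of classes to
    ``k_max`` and integer ``t_lag`` from 0 to ``t_lag_max``; at each grid
    point the draw rate ``n`` is optimised by bounded scalar search
    (xatol 1e-8). Lags that place a positive count before the onset have
    likelihood -inf for every ``n`` and are pruned. Ties break toward the
    smallest ``k``, then the smallest ``t_lag``, so the result is
    deterministic.
    """
    t0 = counts.start_year if t0 is None else int(t0)
    c = counts.counts
    nonzero_years = counts.years[c > 0]
    if counts.total < 2 or len(nonzero_years) < 2:
        raise EstimationError("need >= 2 discoveries over >= 2 distinct years")
    k_min = counts.total
    if k_max < k_min:
        raise ValueError(f"k_max={k_max} below the {k_min} observed classes")
    # any positive count strictly before t0 + t_lag is impossible -> -inf
    lag_cap = int(min(t_lag_max, nonzero_years.min() - t0))
    if lag_cap < 0:
        raise EstimationError("counts precede the origin year: no finite-likelihood grid point")

    edges = np.arange(len(counts) + 1, dtype=float) + (counts.start_year - t0)
    lgamma = gammaln(c + 1)

    # impossible regions get a large finite penalty instead of +inf: Brent's
    # parabolic steps produce NaNs when fed infinities
    _PENALTY = 1e12

    def negll(n: float, k: int, t_lag: int) -> float:
        mu = _yearly_means(edges, k, n, t_lag)
        if np.any((mu <= 0) & (c > 0)):
            return _PENALTY
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(c > 0, c * np.log(np.where(mu > 0, mu, 1.0)), 0.0) - mu
        return -float(np.sum(ll) - np.sum(lgamma))

    # coarse log-spaced scan brackets the optimum before the bounded
    # refinement: the likelihood basin in n can be narrow relative to
    # (0, n_max] and unbracketed Brent may otherwise settle on a shoulder
    n_grid = np.geomspace(1e-3, n_max, 25)

    best_ll = -np.inf
    best: tuple[int, float, int] | None = None
    for k in range(k_min, k_max + 1):
        for t_lag in range(0, lag_cap + 1):
            coarse = np.array([negll(n, k, t_lag) for n in n_grid])
            i = int(coarse.argmin())
            lo = n_grid[max(i - 1, 0)]
            hi = n_grid[min(i + 1, len(n_grid) - 1)]
            res = minimize_scalar(
                negll, args=(k, t_lag), bounds=(lo, hi),
                method="bounded", options={"xatol": 1e-8},
            )
            ll = -float(res.fun)
            if ll > -1e11 and ll > best_ll:
                best_ll = ll
                best = (k, float(res.x), t_lag)
    if best is None:
        raise EstimationError("no finite-likelihood grid point found")
    k, n, t_lag = best
    searched = (
        f"k in [{k_min},{k_max}]; t_lag in [0,{lag_cap}] "
        f"(cap {t_lag_max} tightened by first non-zero count); "
        f"n in (0,{n_max}] bounded search, xatol=1e-8"
    )
    return DiscoveryFit(
        params=DiscoveryParams(k=k, n=n, t_lag=float(t_lag), t0=t0),
        loglik=best_ll,
        searched=searched,
        converged=True,
    )


class CouponCollectorDiscovery(BaseEstimator):
    """Coupon-collector discovery-curve estimator, scikit-learn style.

    Fits pool size ``k_``, draw rate ``n_`` and lag ``t_lag_`` to yearly
    new-class counts; :meth:`predict` evaluates the fitted E[D(t)].
    """

    def __init__(self, k_max: int = 200, t_lag_max: float = 60,
                 t0: int | None = None, n_max: float = 50.0):
        self.k_max = k_max
        self.t_lag_max = t_lag_max
        self.t0 = t0
        self.n_max = n_max

    def fit(self, X, y=None):
        """``X``: a :class:`YearlyCounts`, or a sequence of per-year counts
        with ``y`` giving the first calendar year (default 0)."""
        if isinstance(X, YearlyCounts):
            counts = X
        else:
            start = 0 if y is None else int(y)
            counts = YearlyCounts(start, np.asarray(X, dtype=int).ravel())
        fitres = fit_discovery(counts, k_max=self.k_max, t_lag_max=self.t_lag_max,
                               t0=self.t0, n_max=self.n_max)
        self.result_ = fitres
        self.k_ = fitres.params.k
        self.n_ = fitres.params.n
        self.t_lag_ = fitres.params.t_lag
        self.t0_ = fitres.params.t0
        self.loglik_ = fitres.loglik
        self.converged_ = fitres.converged
        return self

    def predict(self, years) -> np.ndarray:
        """Expected cumulative discovered classes at the given calendar years."""
        return expected_discoveries(np.asarray(years, float), self.result_.params)

    def score(self, X, y=None) -> float:
        """Poisson log-likelihood of counts under the fitted parameters."""
        counts = X if isinstance(X, YearlyCounts) else YearlyCounts(
            0 if y is None else int(y), np.asarray(X, dtype=int).ravel())
        return discovery_loglik(counts, self.result_.params)
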