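"""Joint dynamics: discovered, resistant, and not-yet-resistant classes.

Combines the coupon-collector discovery curve D(t) with the exponential
time-to-resistance model into the three curves of the discovery/resistance
race:

* ``D(t)`` — expected cumulative discovered classes;
* ``R(t)`` — expected classes with resistance already detected;
* ``U(t) = D(t) - R(t)`` — the clinically precious repertoire of classes
  with resistance not yet detected.

Two readings of the resistance curve are provided. The mechanistic default
(``per_class_hazard``) lets every discovered class start its own
exponential resistance clock at discovery, so

    R(t) = integral over discovery times s of D'(s) * (1 - exp(-lam (t-s))) ds,

with per-class hazard ``lam = ln2 / t_half`` (a flag selects the literal
``lam = 1 / t_half`` reading). The integral is evaluated by adaptive
quadrature. The alternative ``literal_exponential`` mode draws R(t) as a
bare exponential-growth curve ``exp((t - t_onset)/t_half)`` capped at
D(t); it has no mechanistic amplitude and is provided for comparison.

The resistance-side parameter is fitted stagewise: discovery parameters
are estimated first from yearly discovery counts and held fixed, then the
half-life is estimated by Poisson maximum likelihood on yearly counts of
first resistance detection, whose model means are increments of R(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .discovery import DiscoveryFit, DiscoveryParams, YearlyCounts, expected_discoveries
from .errors import EstimationError
from .resistance import LN2
from scipy.special import gammaln

MODES = ("per_class_hazard", "literal_exponential")


def _lam(half_life: float, rate_convention: str) -> float:
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    if rate_convention == "half_life":
        return LN2 / half_life
    if rate_convention == "reciprocal":
        return 1.0 / half_life
    raise ValueError(f"unknown rate_convention {rate_convention!r}")


@dataclass
class DynamicsCurve:
    """Yearly D, R and U = D - R curves on a calendar-year grid."""

    years: np.ndarray
    expected_discovered: np.ndarray
    expected_resistant: np.ndarray
    expected_undetected: np.ndarray
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "discovered": self.expected_discovered,
                "resistant": self.expected_resistant,
                "undetected": self.expected_undetected,
            }
        )


def _resistant_scalar(t: float, dparams: DiscoveryParams, lam: float) -> float:
    onset = dparams.t0 + dparams.t_lag
    tau = t - onset
    if tau <= 0:
        return 0.0
    a = dparams.n / dparams.k

    def integrand(u: float) -> float:
        # u: time since onset at which a class is discovered
        return dparams.n * np.exp(-a * u) * -np.expm1(-lam * (tau - u))

    val, _ = quad(integrand, 0.0, tau, epsabs=1e-8, limit=200)
    return float(val)


def expected_resistant(
    t,
    dparams: DiscoveryParams,
    half_life: float,
    mode: str = "per_class_hazard",
    rate_convention: str = "half_life",
    t_onset: float | None = None,
):
    """Expected number of classes with detected resistance at time(s) t.

    ``per_class_hazard``: adaptive-quadrature convolution of the discovery
    intensity with the per-class exponential CDF. ``literal_exponential``:
    ``min(E[D(t)], exp((t - t_onset)/half_life))`` with onset defaulting to
    the end of the lag phase. Both are 0 before any discovery and
    non-decreasing in t.
    """
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if mode == "per_class_hazard":
        lam = _lam(half_life, rate_convention)
        out = np.array([_resistant_scalar(ti, dparams, lam) for ti in t_arr])
    else:
        onset = dparams.t0 + dparams.t_lag if t_onset is None else float(t_onset)
        d = expected_discoveries(t_arr, dparams)
        growth = np.exp((t_arr - onset) / half_life)
        out = np.minimum(np.asarray(d, float), growth)
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def undetected_curve(
    dparams: DiscoveryParams,
    half_life: float,
    years,
    mode: str = "per_class_hazard",
    rate_convention: str = "half_life",
    t_onset: float | None = None,
) -> DynamicsCurve:
    """D, R and U = D - R on a year grid; U >= 0 holds by construction."""
    years = np.asarray(years, dtype=float)
    d = np.asarray(expected_discoveries(years, dparams), dtype=float)
    r = np.asarray(
        expected_resistant(years, dparams, half_life, mode=mode,
                           rate_convention=rate_convention, t_onset=t_onset),
        dtype=float,
    )
    return DynamicsCurve(
        years=years,
        expected_discovered=d,
        expected_resistant=r,
        expected_undetected=d - r,
        mode=mode,
    )


@dataclass
class ResistanceDetectionFit:
    """Stagewise half-life estimate from yearly first-resistance counts."""

    half_life: float
    loglik: float
    mode: str
    rate_convention: str
    t_onset: float | None
    converged: bool

    def to_dict(self) -> dict:
        return {
            "half_life": self.half_life,
            "loglik": self.loglik,
            "mode": self.mode,
            "rate_convention": self.rate_convention,
            "t_onset": self.t_onset,
            "converged": self.converged,
        }


def fit_resistance_detection(
    resistance_counts: YearlyCounts,
    dfit: DiscoveryFit | DiscoveryParams,
    mode: str = "per_class_hazard",
    rate_convention: str = "half_life",
    t_onset: float | None = None,
    half_life_bounds: tuple[float, float] = (0.5, 300.0),
) -> ResistanceDetectionFit:
    """Poisson ML for the half-life, discovery parameters held fixed.

    Yearly counts of first resistance detection are modelled as Poisson
    with means equal to yearly increments of R(t). The half-life is found
    by bounded scalar search (xatol 1e-8); the fit is deterministic.
    In literal mode the onset defaults to the first year with a non-zero
    count.
    """
    dparams = dfit.params if isinstance(dfit, DiscoveryFit) else dfit
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    c = resistance_counts.counts
    if c.sum() == 0:
        raise EstimationError("all resistance counts are zero: half-life not identified")
    if mode == "literal_exponential" and t_onset is None:
        t_onset = float(resistance_counts.years[c > 0].min())
    edges = resistance_counts.start_year + np.arange(len(c) + 1, dtype=float)
    lgamma = gammaln(c + 1)

    def negll(half_life: float) -> float:
        r = np.asarray(
            expected_resistant(edges, dparams, half_life, mode=mode,
                               rate_convention=rate_convention, t_onset=t_onset),
            dtype=float,
        )
        nu = np.maximum(np.diff(r), 0.0)  # clip quadrature jitter
        if np.any((nu <= 0) & (c > 0)):
            return 1e12  # impossible count; finite penalty keeps Brent stable
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(c > 0, c * np.log(np.where(nu > 0, nu, 1.0)), 0.0) - nu
        return -float(np.sum(ll) - np.sum(lgamma))

    # bracket with a coarse log-spaced scan, then refine: the likelihood
    # basin can be narrow relative to the bounds
    hl_grid = np.geomspace(half_life_bounds[0], half_life_bounds[1], 12)
    coarse = np.array([negll(h) for h in hl_grid])
    i = int(coarse.argmin())
    lo = hl_grid[max(i - 1, 0)]
    hi = hl_grid[min(i + 1, len(hl_grid) - 1)]
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    if float(res.fun) >= 1e11:
        raise EstimationError("no finite Poisson likelihood in the half-life bounds")
    return ResistanceDetectionFit(
        half_life=float(res.x),
        loglik=-float(res.fun),
        mode=mode,
        rate_convention=rate_convention,
        t_onset=t_onset,
        converged=bool(res.success),
    )


class ResistanceDetection(BaseEstimator):
    """Stagewise resistance-detection estimator, scikit-learn style.

    Holds fixed discovery parameters and fits the resistance half-life to
    yearly first-detection counts; :meth:`predict` evaluates the fitted
    R(t) curve.
    """

    def __init__(self, discovery_params: DiscoveryParams | None = None,
                 mode: str = "per_class_hazard", rate_convention: str = "half_life",
                 t_onset: float | None = None,
                 half_life_bounds: tuple[float, float] = (0.5, 300.0)):
        self.discovery_params = discovery_params
        self.mode = mode
        self.rate_convention = rate_convention
        self.t_onset = t_onset
        self.half_life_bounds = half_life_bounds

    def fit(self, X, y=None):
        """``X``: a :class:`YearlyCounts` of first resistance detections,
        or per-year counts with ``y`` the first calendar year."""
        if self.discovery_params is None:
            raise ValueError("discovery_params must be set before fitting")
        counts = X if isinstance(X, YearlyCounts) else YearlyCounts(
            0 if y is None else int(y), np.asarray(X, dtype=int).ravel())
        fitres = fit_resistance_detection(
            counts, self.discovery_params, mode=self.mode,
            rate_convention=self.rate_convention, t_onset=self.t_onset,
            half_life_bounds=self.half_life_bounds,
        )
        self.result_ = fitres
        self.half_life_ = fitres.half_life
        self.loglik_ = fitres.loglik
        self.converged_ = fitres.converged
        return self

    def predict(self, years) -> np.ndarray:
        """Expected cumulative resistant classes at the given years."""
        return np.asarray(
            expected_resistant(np.asarray(years, float), self.discovery_params,
                               self.half_life_, mode=self.mode,
                               rate_convention=self.rate_convention,
                               t_onset=self.result_.t_onset),
            dtype=float,
        )
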