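"""Semivariogram estimation and parametric model fitting.

The semivariogram :math:`\\gamma(h)` is half the expected squared difference
between values at locations separated by distance *h*.  The empirical estimate
(Matheron's method-of-moments) averages squared differences within lag bins;
a parametric model (spherical, exponential or Gaussian) is then fitted by
weighted least squares and drives the kriging weights.

All three families are parameterised by an *effective* range: the distance at
which the model reaches (for the spherical family, exactly; for the others, to
within 5%) its sill ``nugget + partial_sill``.  For the exponential and
Gaussian families this is the ArcGIS-style convention with a factor of 3 in
the exponent, so fitted ranges are comparable across families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

__all__ = [
    "FAMILIES",
    "VariogramModel",
    "EmpiricalVariogram",
    "VariogramEstimator",
    "model_gamma",
    "model_correlation",
    "empirical_variogram",
    "default_lag_edges",
    "fit_variogram",
]

FAMILIES = ("spherical", "exponential", "gaussian")


def _check_family(family: str) -> str:
    if family not in FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}; choose from {FAMILIES}")
    return family


def model_correlation(family: str, h, range_km: float):
    """Correlation function rho(h) of the structured component, in [0, 1].

    rho(0) = 1 and rho -> 0 (spherical: exactly; others: ~0.05) at the
    effective range.  Used both for semivariance (gamma = c0 + c*(1 - rho))
    and to build covariance matrices for Gaussian-field simulation.
    """
    _check_family(family)
    if range_km <= 0:
        raise ValueError("range_km must be > 0")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    u = h / range_km
    if family == "spherical":
        rho = np.where(u < 1.0, 1.0 - 1.5 * u + 0.5 * u**3, 0.0)
    elif family == "exponential":
        rho = np.exp(-3.0 * u)
    else:  # gaussian
        rho = np.exp(-3.0 * u**2)
    return rho


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram: nugget + partial sill + effective range.

    ``gamma(0) = 0`` exactly; the nugget is the limit from the right, i.e. the
    model is discontinuous at the origin whenever ``nugget > 0``.  This makes
    ordinary kriging an exact interpolator at data locations.
    """

    family: str = "spherical"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_km: float = 1.0

    def __post_init__(self) -> None:
        _check_family(self.family)
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if self.range_km <= 0:
            raise ValueError("range_km must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h):
        return model_gamma(self, h)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": float(self.nugget),
            "partial_sill": float(self.partial_sill),
            "range_km": float(self.range_km),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VariogramModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def model_gamma(model: VariogramModel, h):
    """Evaluate the model semivariance gamma(h).

    gamma(0) = 0 exactly; for h > 0,
    gamma(h) = nugget + partial_sill * (1 - rho(h)).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    rho = model_correlation(model.family, h, model.range_km)
    gamma = model.nugget + model.partial_sill * (1.0 - rho)
    gamma = np.where(h == 0.0, 0.0, gamma)
    return gamma if gamma.ndim else float(gamma)


@dataclass
class EmpiricalVariogram:
    """Binned method-of-moments semivariance estimates.

    ``gamma_hat`` is NaN in bins with ``pair_count == 0``.
    """

    lag_edges: np.ndarray
    gamma_hat: np.ndarray
    pair_count: np.ndarray
    lag_centers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.lag_edges = np.asarray(self.lag_edges, dtype=float)
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        self.pair_count = np.asarray(self.pair_count, dtype=int)
        if self.lag_edges.ndim != 1 or len(self.lag_edges) < 2:
            raise ValueError("lag_edges must be a 1-d array of >= 2 edges")
        if np.any(np.diff(self.lag_edges) <= 0):
            raise ValueError("lag_edges must be strictly increasing")
        n_bins = len(self.lag_edges) - 1
        if len(self.gamma_hat) != n_bins or len(self.pair_count) != n_bins:
            raise ValueError("gamma_hat/pair_count length must equal number of bins")
        self.lag_centers = 0.5 * (self.lag_edges[:-1] + self.lag_edges[1:])

    @property
    def n_nonempty(self) -> int:
        return int(np.sum(self.pair_count > 0))


def default_lag_edges(points: np.ndarray, n_lags: int = 12) -> np.ndarray:
    """Equal-width lag bins spanning (0, half the maximum pairwise distance]."""
    points = np.asarray(points, dtype=float)
    d_max = float(pdist(points).max())
    if d_max <= 0:
        raise ValueError("all points coincide; cannot build lag bins")
    return np.linspace(0.0, 0.5 * d_max, n_lags + 1)


def empirical_variogram(points, values, lag_edges=None, n_lags: int = 12) -> EmpiricalVariogram:
    """Matheron estimator: for each lag bin (e_k, e_{k+1}],

        gamma_hat_k = sum over pairs with e_k < d_ij <= e_{k+1} of
                      (z_i - z_j)^2 / (2 * pair_count_k).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if len(points) != len(values):
        raise ValueError("points and values must have equal length")
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if lag_edges is None:
        lag_edges = default_lag_edges(points, n_lags=n_lags)
    lag_edges = np.asarray(lag_edges, dtype=float)
    if np.any(np.diff(lag_edges) <= 0):
        raise ValueError("lag_edges must be strictly increasing")

    d = pdist(points)
    sq = pdist(values[:, None], metric="sqeuclidean")
    # right-closed bins (e_k, e_{k+1}]
    idx = np.searchsorted(lag_edges, d, side="left") - 1
    n_bins = len(lag_edges) - 1
    in_range = (idx >= 0) & (idx < n_bins) & (d > lag_edges[0])
    idx, d, sq = idx[in_range], d[in_range], sq[in_range]
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sq, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    return EmpiricalVariogram(lag_edges=lag_edges, gamma_hat=gamma, pair_count=counts)


def fit_variogram(
    emp: EmpiricalVariogram,
    family: str = "spherical",
    range_lower_km: float | None = None,
) -> VariogramModel:
    """Fit a variogram model to binned estimates by weighted least squares.

    Minimises  sum_k  n_k * (gamma_hat_k - gamma(h_k))^2 / gamma(h_k)^2
    (Cressie's weighting: pair counts over the squared model value) subject to
    nugget, partial sill >= 0 and range > 0, with a deterministic multistart
    from quantile-based initial values.

    A flat (pure-nugget) empirical variogram drives the partial sill to ~0;
    the range is then pinned at its lower bound and a warning is issued.
    """
    _check_family(family)
    ok = emp.pair_count > 0
    if emp.n_nonempty < 3:
        raise ValueError("need at least 3 non-empty lag bins to fit a variogram")
    h = emp.lag_centers[ok]
    g = emp.gamma_hat[ok]
    n = emp.pair_count[ok].astype(float)
    if np.allclose(g, 0.0):
        raise ValueError("all semivariance estimates are zero; nothing to fit")

    h_max = float(h.max())
    a_lo = range_lower_km if range_lower_km is not None else max(1e-6, 1e-3 * h_max)
    a_hi = 10.0 * h_max
    sill0 = float(np.nanmean(g[-max(1, len(g) // 3):]))
    eps = 1e-12 * max(sill0, 1.0)

    def objective(params):
        c0, c, a = params
        gam = c0 + c * (1.0 - model_correlation(family, h, max(a, a_lo)))
        return float(np.sum(n * (g - gam) ** 2 / np.maximum(gam, eps) ** 2))

    starts = []
    for a0 in np.quantile(h, [0.25, 0.5, 0.75]):
        for frac in (0.0, 0.25, 0.5):
            starts.append((frac * sill0, max((1 - frac) * sill0, eps), float(a0)))

    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0=np.asarray(x0),
            method="L-BFGS-B",
            bounds=[(0.0, None), (0.0, None), (a_lo, a_hi)],
        )
        if best is None or res.fun < best.fun:
            best = res
    c0, c, a = best.x
    if c <= 1e-8 * max(sill0, 1.0) or np.isclose(a, a_lo):
        warnings.warn(
            "variogram appears to have no spatial structure (pure nugget); "
            "range pinned at its lower bound",
            stacklevel=2,
        )
        a = max(a, a_lo)
    return VariogramModel(family=family, nugget=float(c0), partial_sill=float(c), range_km=float(a))


class VariogramEstimator(BaseEstimator):
    """Estimate a parametric semivariogram from point observations.

    Computes the binned empirical variogram of ``y`` over locations ``X``
    (n_samples, 2) and fits the chosen family by weighted least squares.

    Parameters
    ----------
    family : {'spherical', 'exponential', 'gaussian'}, default 'spherical'
        Model family; the range is the effective range in the same units as X.
    n_lags : int, default 12
        Number of equal-width lag bins spanning (0, max pairwise distance / 2].
    lag_edges : array-like or None
        Explicit bin edges; overrides ``n_lags``.

    Attributes
    ----------
    empirical_ : EmpiricalVariogram
    model_ : VariogramModel
    nugget_, partial_sill_, range_km_ : float
        Fitted parameters.
    """

    def __init__(self, family: str = "spherical", n_lags: int = 12, lag_edges=None):
        self.family = family
        self.n_lags = n_lags
        self.lag_edges = lag_edges

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2) planar coordinates")
        self.empirical_ = empirical_variogram(X, y, lag_edges=self.lag_edges, n_lags=self.n_lags)
        self.model_ = fit_variogram(self.empirical_, family=self.family)
        self.nugget_ = self.model_.nugget
        self.partial_sill_ = self.model_.partial_sill
        self.range_km_ = self.model_.range_km
        return self

    def predict_gamma(self, h):
        """Model semivariance at distances ``h`` (after fitting)."""
        if not hasattr(self, "model_"):
            raise AttributeError("VariogramEstimator is not fitted yet")
        return model_gamma(self.model_, h)
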