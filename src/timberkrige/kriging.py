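"""Ordinary kriging with prediction standard errors.

Ordinary kriging is the best linear unbiased predictor under an unknown
constant mean: the weights :math:`\\lambda` at a target :math:`s_0` solve

.. math::

    \\begin{bmatrix} \\Gamma & \\mathbf{1} \\\\ \\mathbf{1}^T & 0 \\end{bmatrix}
    \\begin{bmatrix} \\lambda \\\\ \\mu \\end{bmatrix}
    =
    \\begin{bmatrix} \\gamma_0 \\\\ 1 \\end{bmatrix}

with :math:`\\Gamma_{ij} = \\gamma(\\|s_i - s_j\\|)`,
:math:`\\gamma_{0,i} = \\gamma(\\|s_i - s_0\\|)` and a Lagrange multiplier
:math:`\\mu` enforcing :math:`\\sum \\lambda_i = 1`.  The prediction is
:math:`\\hat z = \\lambda^T z` and the kriging variance
:math:`\\sigma^2 = \\lambda^T \\gamma_0 + \\mu`.

Because the model semivariogram satisfies gamma(0) = 0 exactly (the nugget is
a right-limit discontinuity), the predictor is an exact interpolator: at a
target coinciding with a datum the prediction equals that datum and, with
zero nugget, sigma = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin

from .variogram import VariogramEstimator, VariogramModel, model_gamma

__all__ = [
    "KrigingConfig",
    "OrdinaryKriging",
    "ordinary_krige",
    "cross_validate",
]


@dataclass(frozen=True)
class KrigingConfig:
    """Search-neighbourhood settings for kriging.

    ``neighborhood='all'`` uses every datum for every target (the dense
    solve); ``'knn'`` uses the ``n_neighbors`` nearest data points, requiring
    at least ``min_neighbors`` (within ``max_radius_km`` if set).  Distance
    ties are broken by ascending point index for determinism.
    """

    neighborhood: str = "knn"
    n_neighbors: int = 16
    min_neighbors: int = 4
    max_radius_km: float | None = None

    def __post_init__(self) -> None:
        if self.neighborhood not in ("all", "knn"):
            raise ValueError("neighborhood must be 'all' or 'knn'")
        if not (self.n_neighbors >= self.min_neighbors >= 1):
            raise ValueError("need n_neighbors >= min_neighbors >= 1")


def _average_duplicates(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values observed at identical coordinates (singular Gamma otherwise)."""
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    if len(uniq) == len(X):
        # preserve original order when nothing is duplicated
        return X, y
    sums = np.bincount(inverse, weights=y, minlength=len(uniq))
    counts = np.bincount(inverse, minlength=len(uniq))
    return uniq, sums / counts


class OrdinaryKriging(RegressorMixin, BaseEstimator):
    """Ordinary kriging regressor with model-based standard errors.

    Parameters
    ----------
    variogram : VariogramModel or None, default None
        Semivariogram driving the weights.  When None, a variogram of the
        given ``family`` is fitted to the training data at ``fit`` time.
    family : str, default 'spherical'
        Family used when fitting the variogram internally.
    n_lags : int, default 12
        Lag bins for the internal variogram fit.
    neighborhood : {'knn', 'all'}, default 'knn'
    n_neighbors : int, default 16
    min_neighbors : int, default 4
    max_radius_km : float or None, default None

    Attributes
    ----------
    X_ : ndarray of shape (n_unique, 2)
        Training coordinates after duplicate averaging.
    y_ : ndarray of shape (n_unique,)
    variogram_ : VariogramModel
        The model actually used (given or fitted).

    Examples
    --------
    >>> ok = OrdinaryKriging(variogram=VariogramModel("spherical", 0.0, 1.0, 10.0),
    ...                      neighborhood="all")
    >>> _ = ok.fit([[0, 0], [1, 0], [0, 1]], [1.0, 2.0, 3.0])
    >>> zhat, se = ok.predict([[0, 0]], return_std=True)
    >>> float(zhat[0]), float(se[0])
    (1.0, 0.0)
    """

    def __init__(
        self,
        variogram: VariogramModel | None = None,
        family: str = "spherical",
        n_lags: int = 12,
        neighborhood: str = "knn",
        n_neighbors: int = 16,
        min_neighbors: int = 4,
        max_radius_km: float | None = None,
    ):
        self.variogram = variogram
        self.family = family
        self.n_lags = n_lags
        self.neighborhood = neighborhood
        self.n_neighbors = n_neighbors
        self.min_neighbors = min_neighbors
        self.max_radius_km = max_radius_km

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2) planar coordinates in km")
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite")
        X, y = _average_duplicates(X, y)
        if len(X) < 2:
            raise ValueError("need at least 2 distinct data points")
        # validate neighbourhood settings eagerly
        KrigingConfig(self.neighborhood, self.n_neighbors, self.min_neighbors, self.max_radius_km)
        self.X_, self.y_ = X, y
        if self.variogram is not None:
            self.variogram_ = self.variogram
        else:
            self.variogram_ = (
                VariogramEstimator(family=self.family, n_lags=self.n_lags).fit(X, y).model_
            )
        self._gamma_data = model_gamma(self.variogram_, cdist(X, X))
        np.fill_diagonal(self._gamma_data, 0.0)
        return self

    # -------------------------------------------------------------- helpers
    def _check_fitted(self):
        if not hasattr(self, "X_"):
            raise AttributeError("OrdinaryKriging is not fitted yet")

    def _neighbor_indices(self, dist_row: np.ndarray) -> np.ndarray:
        """k nearest by distance, ties broken by ascending index."""
        n = len(dist_row)
        if self.neighborhood == "all":
            return np.arange(n)
        k = min(self.n_neighbors, n)
        order = np.argsort(dist_row, kind="stable")[:k]
        if self.max_radius_km is not None:
            within = order[dist_row[order] <= self.max_radius_km]
            if len(within) >= self.min_neighbors:
                order = within
            else:  # fall back to the nearest min_neighbors regardless of radius
                order = order[: max(self.min_neighbors, len(within))]
        return np.sort(order)

    def _solve_target(self, idx: np.ndarray, gamma0: np.ndarray, target_label) -> tuple[float, float]:
        n = len(idx)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = self._gamma_data[np.ix_(idx, idx)]
        A[n, :n] = A[:n, n] = 1.0
        A[n, n] = 0.0
        b = np.empty(n + 1)
        b[:n] = gamma0
        b[n] = 1.0
        try:
            sol = scipy.linalg.solve(A, b, assume_a="sym")
        except scipy.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular kriging system at target {target_label}") from exc
        if not np.all(np.isfinite(sol)):
            raise RuntimeError(f"singular kriging system at target {target_label}")
        lam, mu = sol[:n], sol[n]
        zhat = float(lam @ self.y_[idx])
        var = float(lam @ gamma0 + mu)
        return zhat, np.sqrt(max(var, 0.0))

    # -------------------------------------------------------------- predict
    def predict(self, X, return_std: bool = False):
        """Kriged predictions at target coordinates.

        With ``return_std=True`` also returns the kriging standard error
        (same units as ``y``).
        """
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 2:
            raise ValueError("targets must be (n_targets, 2)")
        dists = cdist(X, self.X_)
        gam = model_gamma(self.variogram_, dists)
        preds = np.empty(len(X))
        ses = np.empty(len(X))
        for t in range(len(X)):
            idx = self._neighbor_indices(dists[t])
            preds[t], ses[t] = self._solve_target(idx, gam[t, idx], target_label=t)
        if return_std:
            return preds, ses
        return preds

    def weights(self, target) -> tuple[np.ndarray, np.ndarray, float]:
        """Kriging weights, neighbour indices and Lagrange multiplier at one target.

        Exposed for auditing the unbiasedness constraint (weights sum to 1).
        """
        self._check_fitted()
        target = np.asarray(target, dtype=float).reshape(1, 2)
        dist = cdist(target, self.X_)[0]
        idx = self._neighbor_indices(dist)
        gamma0 = model_gamma(self.variogram_, dist[idx])
        n = len(idx)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = self._gamma_data[np.ix_(idx, idx)]
        A[n, :n] = A[:n, n] = 1.0
        A[n, n] = 0.0
        b = np.concatenate([gamma0, [1.0]])
        sol = scipy.linalg.solve(A, b, assume_a="sym")
        return sol[:n], idx, float(sol[n])

    def cross_val_predict(self, return_std: bool = False):
        """Leave-one-out predictions at the training locations.

        Each training point is predicted from all the others under the fitted
        variogram (the variogram itself is not re-fitted per fold).
        """
        self._check_fitted()
        n = len(self.X_)
        if n < 3:
            raise ValueError("need at least 3 points for leave-one-out validation")
        dists = cdist(self.X_, self.X_)
        gam = self._gamma_data
        preds = np.empty(n)
        ses = np.empty(n)
        for i in range(n):
            row = dists[i].copy()
            row[i] = np.inf  # exclude self
            if self.neighborhood == "all":
                idx = np.delete(np.arange(n), i)
            else:
                idx = self._neighbor_indices(row)
                idx = idx[idx != i]
            preds[i], ses[i] = self._solve_target(idx, gam[i, idx], target_label=i)
        if return_std:
            return preds, ses
        return preds


def ordinary_krige(
    data_points,
    data_values,
    model: VariogramModel,
    targets,
    config: KrigingConfig | None = None,
):
    """Functional front end: kriged predictions and standard errors at targets."""
    config = config or KrigingConfig()
    ok = OrdinaryKriging(
        variogram=model,
        neighborhood=config.neighborhood,
        n_neighbors=config.n_neighbors,
        min_neighbors=config.min_neighbors,
        max_radius_km=config.max_radius_km,
    ).fit(data_points, data_values)
    return ok.predict(targets, return_std=True)


def cross_validate(
    data_points,
    data_values,
    model: VariogramModel,
    config: KrigingConfig | None = None,
):
    """Leave-one-out validation pairs: (observed, predicted, standard error)."""
    config = config or KrigingConfig()
    ok = OrdinaryKriging(
        variogram=model,
        neighborhood=config.neighborhood,
        n_neighbors=config.n_neighbors,
        min_neighbors=config.min_neighbors,
        max_radius_km=config.max_radius_km,
    ).fit(data_points, data_values)
    pred, se = ok.cross_val_predict(return_std=True)
    return ok.y_, pred, se
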