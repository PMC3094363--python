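"""Asymptotic height-diameter model (Chapman-Richards form).

Standard volume/biomass equations need total height, which inventories
often lack.  Heights are therefore generated from DBH with the
Chapman-Richards curve

    h(d) = b0 * (1 - exp(b1 * d)) ** b2,       b0 > 0, b1 < 0, b2 > 0

whose asymptote ``b0`` (maximum height, m) avoids the unrealistic
predictions many polynomial height models give for large trees.  ``b1``
is the steepness parameter and ``b2`` the curvature parameter.
Parameters are estimated from (DBH class, mean height) pairs by
nonlinear least squares weighted by DBH^-1, which keeps the numerous
small-tree classes from being swamped by the few large ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "HeightParams",
    "ChapmanRichardsHeight",
    "chapman_richards",
    "predict_height",
    "fit_height_params",
]


def chapman_richards(d, b0: float, b1: float, b2: float):
    d = np.asarray(d, dtype=float)
    return b0 * (1.0 - np.exp(b1 * d)) ** b2


@dataclass(frozen=True)
class HeightParams:
    """Fitted Chapman-Richards parameters for one species.

    ``n`` (number of DBH classes) and ``mse`` (fit mean squared error)
    are metadata carried along from the regression.
    """

    species: str
    b0: float
    b1: float
    b2: float
    n: int | None = None
    mse: float | None = None

    def __post_init__(self) -> None:
        if not self.b0 > 0:
            raise ValueError(f"{self.species}: asymptote b0 must be > 0, got {self.b0}")
        if not self.b1 < 0:
            raise ValueError(f"{self.species}: steepness b1 must be < 0, got {self.b1}")
        if not self.b2 > 0:
            raise ValueError(f"{self.species}: curvature b2 must be > 0, got {self.b2}")


def predict_height(params: HeightParams, dbh):
    """Height (m) at DBH (cm); h(0) = 0 and h(d) -> b0 as d grows."""
    d = np.asarray(dbh, dtype=float)
    if np.any(d < 0):
        raise ValueError("DBH must be non-negative")
    h = chapman_richards(d, params.b0, params.b1, params.b2)
    return float(h) if np.ndim(dbh) == 0 else h


class ChapmanRichardsHeight(RegressorMixin, BaseEstimator):
    """Chapman-Richards height-diameter regressor.

    Parameters
    ----------
    weight_by_inverse_dbh : bool, default True
        Use DBH^-1 observation weights (the convention for fitting to
        per-class mean heights) when no explicit ``sample_weight`` is
        passed to :meth:`fit`.
    start_b0_factor, start_b1, start_b2 : float
        Fixed optimiser starting point: ``b0 = start_b0_factor * max(y)``,
        then ``b1``, ``b2`` as given.  Fixing the start makes fits
        reproducible.

    Attributes
    ----------
    b0_, b1_, b2_ : float
        Fitted parameters (b0 > 0, b1 < 0, b2 > 0 by constraint).
    mse_ : float
        Weighted residual sum of squares / (n - 3).
    converged_ : bool
        Optimiser status; non-convergence raises rather than passing
        silently.

    Examples
    --------
    >>> d = np.arange(4, 100, 2.0)
    >>> h = chapman_richards(d, 60.0, -0.02, 1.1)
    >>> est = ChapmanRichardsHeight().fit(d, h)
    >>> round(est.b0_, 3)
    60.0
    """

    def __init__(
        self,
        *,
        weight_by_inverse_dbh: bool = True,
        start_b0_factor: float = 1.05,
        start_b1: float = -0.02,
        start_b2: float = 1.0,
        max_nfev: int = 10_000,
    ):
        self.weight_by_inverse_dbh = weight_by_inverse_dbh
        self.start_b0_factor = start_b0_factor
        self.start_b1 = start_b1
        self.start_b2 = start_b2
        self.max_nfev = max_nfev

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("X must be 1-d DBH values or a single-column matrix")
        return x

    def fit(self, X, y, sample_weight=None):
        d = self._as_1d(X)
        h = np.asarray(y, dtype=float)
        if d.shape != h.shape:
            raise ValueError("X and y lengths differ")
        if np.any(d <= 0):
            raise ValueError("DBH classes must be positive")
        if np.any(h <= 0):
            raise ValueError("heights must be positive")
        if np.unique(d).size < 4:
            raise ValueError("need at least 4 distinct DBH classes to fit 3 parameters")
        if np.allclose(h, h[0]):
            raise ValueError("degenerate input: all heights equal")
        if sample_weight is None:
            w = 1.0 / d if self.weight_by_inverse_dbh else np.ones_like(d)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if np.any(w < 0):
                raise ValueError("negative sample_weight")
        sw = np.sqrt(w)

        def resid(theta):
            return sw * (h - chapman_richards(d, *theta))

        x0 = np.array([self.start_b0_factor * h.max(), self.start_b1, self.start_b2])
        res = least_squares(
            resid,
            x0,
            bounds=([1e-8, -10.0, 1e-8], [1e5, -1e-10, 100.0]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=self.max_nfev,
        )
        self.converged_ = bool(res.success)
        if not self.converged_:
            raise RuntimeError(f"height fit did not converge: {res.message}")
        self.b0_, self.b1_, self.b2_ = (float(v) for v in res.x)
        dof = max(d.size - 3, 1)
        self.mse_ = float(np.sum(res.fun**2)) / dof
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "b0_"):
            raise AttributeError("estimator is not fitted")
        d = self._as_1d(X)
        if np.any(d < 0):
            raise ValueError("DBH must be non-negative")
        return chapman_richards(d, self.b0_, self.b1_, self.b2_)

    def to_height_params(self, species: str = "") -> HeightParams:
        if not hasattr(self, "b0_"):
            raise AttributeError("estimator is not fitted")
        return HeightParams(
            species=species,
            b0=self.b0_,
            b1=self.b1_,
            b2=self.b2_,
            n=int(self.n_obs_) if hasattr(self, "n_obs_") else None,
            mse=self.mse_,
        )


def fit_height_params(dbh, height, *, species: str = "", sample_weight=None) -> HeightParams:
    """Fit Chapman-Richards parameters to (DBH class, mean height) pairs.

    Thin wrapper over :class:`ChapmanRichardsHeight` with DBH^-1 weights.
    """
    est = ChapmanRichardsHeight().fit(dbh, height, sample_weight=sample_weight)
    d = est._as_1d(dbh)
    return HeightParams(
        species=species, b0=est.b0_, b1=est.b1_, b2=est.b2_, n=int(d.size), mse=est.mse_
    )
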