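"""City-level quasi-Poisson time-series regression.

Model: log E[deaths] = intercept + cross-basis block + day-of-week
indicators (reference Monday) + natural cubic spline of the in-season
time index with four degrees of freedom per year.  Fitting is by
iteratively reweighted least squares with the log link; the covariance is
scaled by the Pearson dispersion (quasi-Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .config import StudyConfig
from .data_io import CityPanel
from .dlnm_basis import CrossBasisMatrix, SplineBasisSpec, ns_basis

_DOW_ORDER = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclass
class DesignMatrix:
    """Assembled regression design with a stable column layout:
    intercept | cross-basis | DOW dummies (Tue..Sun) | seasonal spline."""

    X: np.ndarray
    row_mask: np.ndarray
    column_names: list[str]
    cb_slice: slice
    dow_slice: slice
    seasonal_slice: slice

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


@dataclass
class FitResult:
    beta: np.ndarray
    vcov: np.ndarray
    dispersion: float
    n_fitted: int
    converged: bool
    column_names: list[str] = field(default_factory=list)
    n_iter: int = 0


def dow_dummies(dow_labels) -> np.ndarray:
    """Six indicator columns Tue..Sun (Monday is the reference)."""
    labels = np.asarray(dow_labels)
    return np.column_stack(
        [(labels == d).astype(float) for d in _DOW_ORDER[1:]]
    )


def seasonal_spline(time_index, n_years: int, df_per_year: int,
                    fit_mask=None) -> np.ndarray:
    """NS(time) block with df_per_year * n_years total columns.

    Built over the full panel time index with boundary knots at the panel
    endpoints and internal knots at quantiles of the fitted rows, so
    held-out rows always evaluate in-range.
    """
    t = np.asarray(time_index, dtype=float)
    df = df_per_year * n_years
    if fit_mask is None:
        fit_mask = np.ones(t.size, dtype=bool)
    tf = t[fit_mask]
    n_internal = df - 1
    qs = np.linspace(0, 100, n_internal + 2)[1:-1]
    knots = np.quantile(tf, qs / 100.0)
    knots = np.unique(knots)
    # boundary knots at the fitted rows' range: held-out rows beyond it are
    # covered by the natural spline's linear tail, which keeps edge-year
    # predictions in cross-validation stable
    lo, hi = float(tf.min()), float(tf.max())
    knots = tuple(float(k) for k in knots if lo < k < hi)
    spec = SplineBasisSpec(knots, (lo, hi), include_intercept=False)
    return ns_basis(t, spec)


def build_design(
    panel: CityPanel,
    cb: CrossBasisMatrix,
    config: StudyConfig,
    fit_mask=None,
) -> DesignMatrix:
    """Assemble intercept, cross-basis, DOW and seasonal-spline columns.

    ``fit_mask`` restricts the rows that will enter the likelihood (e.g.
    training rows of a cross-validation fold); the seasonal spline knots
    are placed from those rows only.  Columns that are identically zero on
    the fitted rows raise a rank-deficiency error naming the block.
    """
    n = len(panel)
    if cb.values.shape[0] != n:
        raise ValueError("cross-basis was not built from this panel")
    mask = cb.valid_row_mask.copy()
    if fit_mask is not None:
        mask &= np.asarray(fit_mask, dtype=bool)
    mask &= np.isfinite(panel.deaths.astype(float))

    n_years = len(np.unique(panel.years))
    cb_block = cb.values
    dow_block = dow_dummies(panel.dow)
    seas_block = seasonal_spline(
        panel.time_index, n_years, config.seasonal_df_per_year, fit_mask=mask
    )
    X = np.column_stack([np.ones(n), cb_block, dow_block, seas_block])
    names = (
        ["intercept"]
        + [f"cb{j}" for j in range(cb_block.shape[1])]
        + [f"dow_{d}" for d in _DOW_ORDER[1:]]
        + [f"seas{j}" for j in range(seas_block.shape[1])]
    )
    dm = DesignMatrix(
        X=X,
        row_mask=mask,
        column_names=names,
        cb_slice=slice(1, 1 + cb_block.shape[1]),
        dow_slice=slice(1 + cb_block.shape[1], 1 + cb_block.shape[1] + 6),
        seasonal_slice=slice(1 + cb_block.shape[1] + 6, X.shape[1]),
    )
    _check_degenerate_blocks(dm)
    return dm


def _check_degenerate_blocks(dm: DesignMatrix) -> None:
    Xf = dm.X[dm.row_mask]
    for name, sl in (("cross-basis", dm.cb_slice),
                     ("day-of-week", dm.dow_slice),
                     ("seasonal-spline", dm.seasonal_slice)):
        block = Xf[:, sl]
        if block.shape[1] and np.allclose(block.std(axis=0), 0.0):
            raise ValueError(f"rank-deficient design: {name} block is constant "
                             "on the fitted rows")


def fit_quasipoisson(
    y,
    dm: DesignMatrix,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> FitResult:
    """Quasi-Poisson fit by IRLS with log link.

    Point estimates equal the Poisson ML fit; vcov = dispersion *
    (X'WX)^-1 with dispersion = Pearson chi^2 / (n - p).  Convergence is
    relative coefficient change below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    yf = y[dm.row_mask]
    if np.any(yf < 0):
        raise ValueError("negative counts in response")
    X0 = dm.X[dm.row_mask]
    n, p = X0.shape
    if n <= p:
        raise ValueError(f"too few rows ({n}) for {p} coefficients")
    # unit-column-norm preconditioning for the normal equations
    scale = np.linalg.norm(X0, axis=0)
    scale[scale == 0] = 1.0
    X = X0 / scale

    beta = np.zeros(p)
    beta[0] = np.log(yf.mean() + 0.5) * scale[0]
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu
        z = eta + (yf - mu) / mu
        xtw = X.T * w
        xtwx = xtw @ X
        xtwz = xtw @ z
        try:
            c = cho_factor(xtwx)
            beta_new = cho_solve(c, xtwz)
        except np.linalg.LinAlgError as exc:
            raise ValueError("rank-deficient design in IRLS") from exc
        delta = np.max(np.abs(beta_new - beta)) / (np.max(np.abs(beta)) + 1e-10)
        trace.append(float(delta))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations; trace={trace[-5:]}"
        )
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    pearson = float(np.sum((yf - mu) ** 2 / mu))
    dispersion = pearson / (n - p)
    xtwx = (X.T * mu) @ X
    c = cho_factor(xtwx)
    xtwx_inv = cho_solve(c, np.eye(p))
    beta = beta / scale
    xtwx_inv = xtwx_inv / np.outer(scale, scale)
    vcov = dispersion * 0.5 * (xtwx_inv + xtwx_inv.T)
    return FitResult(
        beta=beta,
        vcov=vcov,
        dispersion=dispersion,
        n_fitted=n,
        converged=converged,
        column_names=list(dm.column_names),
        n_iter=it,
    )


def predict_deaths(fit: FitResult, X_new: np.ndarray) -> np.ndarray:
    """Expected daily deaths exp(X_new @ beta) per row."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != fit.beta.size:
        raise ValueError(
            f"design has {X_new.shape[1]} columns; fit expects {fit.beta.size}"
        )
    return np.exp(np.clip(X_new @ fit.beta, -30.0, 30.0))
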