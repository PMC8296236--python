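"""Natural cubic splines, the lagged-exposure cross-basis, and the
lag-cumulation reduction.

The cross-basis is the tensor product of a natural cubic spline in the
exposure dimension (no intercept) and one in the lag dimension (with
intercept), evaluated over each day's lag window.  Column ordering is
exposure-major: all lag columns for exposure-basis 1, then exposure-basis
2, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineBasisSpec:
    """Configuration of one natural-cubic-spline basis.

    df = n_internal_knots + 1 without intercept, + 2 with intercept.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    include_intercept: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary knots must satisfy lo < hi")
        ks = self.internal_knots
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("internal knots must be strictly increasing")
        if ks and not (lo < ks[0] and ks[-1] < hi):
            raise ValueError("internal knots must lie strictly inside boundary knots")

    @property
    def df(self) -> int:
        return len(self.internal_knots) + 1 + (1 if self.include_intercept else 0)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure x lag tensor-product basis configuration."""

    exposure_spec: SplineBasisSpec
    lag_spec: SplineBasisSpec
    max_lag: int

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")

    @property
    def df(self) -> int:
        return self.exposure_spec.df * self.lag_spec.df


@dataclass
class CrossBasisMatrix:
    """Evaluated cross-basis for one panel.

    ``valid_row_mask`` is False on rows whose lag window was padded (or,
    under the "drop" policy, rows excluded from fitting); ``values`` rows
    are still populated wherever the underlying series allows.
    """

    values: np.ndarray
    spec: CrossBasisSpec
    valid_row_mask: np.ndarray
    #: True where the lag window fit entirely inside the season (no padding)
    complete_history: np.ndarray | None = None


def _natural_constrained_basis(knots_all: np.ndarray):
    """Build the natural-constrained cubic B-spline machinery.

    Returns (spline, d1, Z, lo, hi): a vector-valued BSpline over the full
    knot sequence, its first derivative, and the null-space transform Z
    enforcing zero second derivative at both boundaries.
    """
    lo, hi = knots_all[0], knots_all[-1]
    t = np.concatenate(([lo] * 4, knots_all[1:-1], [hi] * 4))
    nb = len(knots_all) + 2
    spl = BSpline(t, np.eye(nb), 3, extrapolate=True)
    const = spl.derivative(2)(np.array([lo, hi]))  # (2, nb)
    # Z spans the null space of the second-derivative constraints.
    q, _ = np.linalg.qr(const.T, mode="complete")
    z = q[:, 2:]
    return spl, spl.derivative(1), z, lo, hi


def ns_basis(x, spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Linear beyond the boundary knots (value + first derivative
    extrapolation).  Raises on non-finite inputs, listing the offending
    indices.
    """
    x = np.asarray(x, dtype=float)
    flat = x.ravel()
    bad = np.flatnonzero(~np.isfinite(flat))
    if bad.size:
        raise ValueError(f"non-finite values in spline input at indices {bad.tolist()}")
    knots_all = np.concatenate(
        ([spec.boundary_knots[0]], spec.internal_knots, [spec.boundary_knots[1]])
    )
    spl, d1, z, lo, hi = _natural_constrained_basis(knots_all)
    xin = np.clip(flat, lo, hi)
    basis = spl(xin) @ z
    below = flat < lo
    above = flat > hi
    if below.any():
        basis[below] += np.outer(flat[below] - lo, d1(lo) @ z)
    if above.any():
        basis[above] += np.outer(flat[above] - hi, d1(hi) @ z)
    if not spec.include_intercept:
        # drop the first constrained column; the rest plus an external
        # intercept span the same natural-spline space
        basis = basis[:, 1:]
    return basis.reshape(x.shape + (basis.shape[1],)) if x.ndim > 1 else basis


def log_lag_knots(max_lag: int, n_knots: int) -> np.ndarray:
    """Internal lag knots equally spaced on the log scale.

    Knot k (k = 1..n_knots) sits at max_lag**(k/(n_knots+1)), i.e. equally
    spaced in log between lag 1 and max_lag.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    k = np.arange(1, n_knots + 1)
    return np.asarray(max_lag, dtype=float) ** (k / (n_knots + 1))


def exposure_spec_from_values(
    values, knot_percentiles=(10.0, 75.0, 90.0)
) -> SplineBasisSpec:
    """Exposure spline spec with knots at percentiles of the pooled
    regional distribution and boundary knots at its range."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to place exposure knots")
    knots = np.percentile(v, knot_percentiles)
    lo, hi = float(v.min()), float(v.max())
    knots = tuple(float(k) for k in knots if lo < k < hi)
    return SplineBasisSpec(knots, (lo, hi), include_intercept=False)


def lag_spec(max_lag: int, n_knots: int = 2) -> SplineBasisSpec:
    """Lag spline spec: log-spaced internal knots, boundaries 0 and
    max_lag, intercept included."""
    knots = tuple(float(k) for k in log_lag_knots(max_lag, n_knots))
    return SplineBasisSpec(knots, (0.0, float(max_lag)), include_intercept=True)


def default_cross_basis_spec(values, config) -> CrossBasisSpec:
    """Cross-basis spec from pooled metric values and a StudyConfig."""
    return CrossBasisSpec(
        exposure_spec=exposure_spec_from_values(
            values, config.exposure_knot_percentiles
        ),
        lag_spec=lag_spec(config.max_lag, config.n_lag_knots),
        max_lag=config.max_lag,
    )


def lagged_matrix(
    series, max_lag: int, season_id=None, policy: str = "pad"
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix L with L[t, l] = series[t - l], respecting season blocks.

    Lags never cross a season boundary: when t - l falls before the
    current season's first day, the value is padded with that first day's
    value ("pad") and the row flagged in the returned mask; under "drop"
    padded rows are flagged for exclusion instead.  Returns (L, complete)
    where complete[t] is True iff no padding was needed.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < max_lag + 1:
        raise ValueError(f"series of length {n} shorter than max_lag+1={max_lag + 1}")
    if season_id is None:
        season_id = np.zeros(n, dtype=int)
    season_id = np.asarray(season_id)
    # first index of each season block
    starts = np.empty(n, dtype=int)
    cur = 0
    for i in range(n):
        if i > 0 and season_id[i] != season_id[i - 1]:
            cur = i
        starts[i] = cur
    t = np.arange(n)
    lags = np.arange(max_lag + 1)
    idx = t[:, None] - lags[None, :]
    padded_pos = idx < starts[:, None]
    idx = np.where(padded_pos, starts[:, None], idx)
    lagmat = x[idx]
    complete = ~padded_pos.any(axis=1)
    return lagmat, complete


def build_cross_basis(
    series,
    spec: CrossBasisSpec,
    season_id=None,
    policy: str = "pad",
) -> CrossBasisMatrix:
    """Evaluate the cross-basis over a panel's metric series.

    Row t, column (j, k) = sum_l B_exp_j(x[t-l]) * B_lag_k(l), with lag
    windows padded at season starts per ``policy``.  Rows whose window
    contains a missing value are NaN and masked out.
    """
    x = np.asarray(series, dtype=float)
    lagmat, complete = lagged_matrix(x, spec.max_lag, season_id, policy)
    n = x.size
    finite_rows = np.isfinite(lagmat).all(axis=1)
    # evaluate exposure basis on finite lag values only
    flat = lagmat.reshape(-1)
    ok = np.isfinite(flat)
    exp_eval = np.full((flat.size, spec.exposure_spec.df), np.nan)
    if ok.any():
        exp_eval[ok] = ns_basis(flat[ok], spec.exposure_spec)
    exp_eval = exp_eval.reshape(n, spec.max_lag + 1, spec.exposure_spec.df)
    lag_eval = ns_basis(np.arange(spec.max_lag + 1, dtype=float), spec.lag_spec)
    # values[t, j, k] = sum_l exp_eval[t, l, j] * lag_eval[l, k]
    vals = np.einsum("tlj,lk->tjk", exp_eval, lag_eval)
    values = vals.reshape(n, spec.df)
    if policy == "pad":
        mask = finite_rows
    elif policy == "drop":
        mask = finite_rows & complete
    else:
        raise ValueError("policy must be 'pad' or 'drop'")
    return CrossBasisMatrix(
        values=values, spec=spec, valid_row_mask=mask, complete_history=complete
    )


def lag_cumulation_map(spec: CrossBasisSpec) -> np.ndarray:
    """Reduction matrix M mapping cross-basis coefficients beta to
    overall-cumulative exposure-curve coefficients theta = M.T @ beta.

    M is the Kronecker lift of s = column sums of the lag basis over
    integer lags 0..max_lag; the reduced covariance is M.T @ V @ M.
    """
    lag_eval = ns_basis(np.arange(spec.max_lag + 1, dtype=float), spec.lag_spec)
    s = lag_eval.sum(axis=0)  # (df_lag,)
    return np.kron(np.eye(spec.exposure_spec.df), s[:, None])


def reduce_to_curve(beta: np.ndarray, vcov: np.ndarray, spec: CrossBasisSpec):
    """Lag-cumulated exposure curve coefficients and covariance."""
    m = lag_cumulation_map(spec)
    theta = m.T @ beta
    v = m.T @ vcov @ m
    return theta, 0.5 * (v + v.T)
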