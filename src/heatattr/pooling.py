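"""Multivariate random-effects meta-analysis of city curves and BLUPs.

Stage two of the two-stage design: each city contributes a lag-cumulated
exposure-curve coefficient vector theta with covariance V; the pooled
mean mu and between-city covariance Psi are estimated by a closed-form
method of moments, and city-specific curves are shrunk toward the pool by
best linear unbiased prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dlnm_basis import SplineBasisSpec


@dataclass
class ReducedCurve:
    """Lag-cumulated exposure-response summary for one city and metric."""

    theta: np.ndarray
    vcov: np.ndarray
    city_id: str
    metric: str
    exposure_spec: SplineBasisSpec

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.vcov.shape != (self.theta.size, self.theta.size):
            raise ValueError("vcov shape does not match theta")


@dataclass
class PooledCurves:
    """Meta-analytic pool: mean mu, between-city covariance Psi, BLUPs."""

    mu: np.ndarray
    mu_vcov: np.ndarray
    psi: np.ndarray
    blups: dict[str, np.ndarray]
    blup_vcovs: dict[str, np.ndarray]
    exposure_spec: SplineBasisSpec
    metric: str = ""
    psi_repaired: bool = False


def _clip_psd(a: np.ndarray) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clip a symmetric matrix to the PSD cone."""
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    if (w >= 0).all():
        return a, False
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T, True


def estimate_psi(curves: list[ReducedCurve]) -> tuple[np.ndarray, bool]:
    """Between-city covariance by the moment estimator.

    Sample covariance of the thetas minus the mean within-city covariance,
    eigenvalue-clipped to PSD.  Zero for a single curve.
    """
    k = curves[0].theta.size
    n = len(curves)
    if n < 2:
        return np.zeros((k, k)), False
    thetas = np.stack([c.theta for c in curves])
    s = np.cov(thetas, rowvar=False, ddof=1).reshape(k, k)
    vbar = np.mean([c.vcov for c in curves], axis=0)
    return _clip_psd(s - vbar)


def meta_fit(curves: list[ReducedCurve]) -> PooledCurves:
    """Multivariate random-effects pool of city curves.

    mu = (sum W_i)^-1 sum W_i theta_i with W_i = (V_i + Psi)^-1 and Psi
    from :func:`estimate_psi`.  A single curve is returned unchanged with
    Psi = 0.  City ordering is immaterial.
    """
    if not curves:
        raise ValueError("meta_fit needs at least one curve")
    k = curves[0].theta.size
    for c in curves[1:]:
        if c.theta.size != k:
            raise ValueError("curve dimension mismatch in meta-analysis")
        if c.exposure_spec != curves[0].exposure_spec:
            raise ValueError("curves entering one meta-analysis must share the "
                             "same exposure basis")
    psi, repaired = estimate_psi(curves)
    wsum = np.zeros((k, k))
    wtheta = np.zeros(k)
    weights = []
    for c in curves:
        w = np.linalg.inv(c.vcov + psi)
        weights.append(w)
        wsum += w
        wtheta += w @ c.theta
    mu_vcov = np.linalg.inv(wsum)
    mu = mu_vcov @ wtheta

    blups: dict[str, np.ndarray] = {}
    blup_vcovs: dict[str, np.ndarray] = {}
    for c, w in zip(curves, weights):
        shrink = psi @ w
        blups[c.city_id] = mu + shrink @ (c.theta - mu)
        resid = psi - psi @ w @ psi
        a = np.eye(k) - shrink
        blup_vcovs[c.city_id], _ = _clip_psd(resid + a @ mu_vcov @ a.T)
    return PooledCurves(
        mu=mu,
        mu_vcov=0.5 * (mu_vcov + mu_vcov.T),
        psi=psi,
        blups=blups,
        blup_vcovs=blup_vcovs,
        exposure_spec=curves[0].exposure_spec,
        metric=curves[0].metric,
        psi_repaired=repaired,
    )


def blup(pooled: PooledCurves, curve: ReducedCurve) -> np.ndarray:
    """BLUP = mu + Psi (V_i + Psi)^-1 (theta_i - mu)."""
    w = np.linalg.inv(curve.vcov + pooled.psi)
    return pooled.mu + pooled.psi @ w @ (curve.theta - pooled.mu)
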