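"""RR curves, minimum-mortality temperature, and attributable fractions.

The lag-cumulated coefficient vector theta defines the overall
exposure-response curve g(x) = b(x) . theta with b the exposure
natural-spline basis.  Centering at the minimum-mortality temperature
(MMT) turns it into a relative-risk curve RR(x) = exp(g(x) - g(MMT));
the heat-attributable fraction sums daily excess risks m_i * (1 - 1/RR_i)
over the days at or above the MMT, divided by total deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dlnm_basis import SplineBasisSpec, ns_basis


@dataclass
class RRCurve:
    """Exposure-response curve defined by spline coefficients and a center."""

    exposure_spec: SplineBasisSpec
    coefficients: np.ndarray
    center: float | None = None
    vcov: np.ndarray | None = None

    def log_rr_uncentered(self, temps) -> np.ndarray:
        return ns_basis(np.asarray(temps, dtype=float), self.exposure_spec) @ np.asarray(
            self.coefficients, dtype=float
        )

    def centered_at(self, center: float) -> "RRCurve":
        return RRCurve(self.exposure_spec, np.asarray(self.coefficients, float),
                       float(center), self.vcov)


@dataclass
class MMTResult:
    mmt: float
    mmp: float
    search_interval: tuple[float, float]
    ci: tuple[float, float] | None = None
    flat: bool = False


@dataclass
class AttributionResult:
    """HAF/EHAF/MHAF (percent) plus per-day audit components."""

    haf: float
    ehaf: float
    mhaf: float
    mmt: float
    p90: float
    total_deaths: float
    haf_numerator: float
    ehaf_numerator: float
    mhaf_numerator: float
    n_days: int
    mmt_above_p90: bool = False
    daily_attributable: np.ndarray | None = None
    #: days whose temperature fell beyond the curve's boundary knots and
    #: were evaluated via the natural-spline linear extrapolation
    extrapolated_days: int = 0


def predict_rr(curve: RRCurve, temps) -> np.ndarray:
    """RR(x) = exp(g(x) - g(center)); requires a centered curve.

    Values outside the spline's boundary knots follow the natural-spline
    linear extrapolation.
    """
    if curve.center is None:
        raise ValueError("curve must be centered (at the MMT) before RR prediction")
    temps = np.asarray(temps, dtype=float)
    out = np.full(temps.shape, np.nan)
    ok = np.isfinite(temps)
    if ok.any():
        g = curve.log_rr_uncentered(temps[ok])
        g0 = curve.log_rr_uncentered(np.array([curve.center]))[0]
        out[ok] = np.exp(g - g0)
    return out


def find_mmt(
    curve: RRCurve,
    temps,
    search: tuple[float, float] = (1.0, 99.0),
    n_grid: int = 1000,
    ci_draws: int = 0,
    rng: np.random.Generator | None = None,
) -> MMTResult:
    """Locate the minimum of the cumulative curve over the observed
    temperature distribution.

    The grid spans the ``search`` percentile interval of ``temps`` in
    percentile space, so the minimizer's percentile (MMP) is read off
    directly.  An optional empirical CI resamples coefficient vectors
    from N(theta, vcov) and recomputes the argmin per draw.
    """
    temps = np.asarray(temps, dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size == 0:
        raise ValueError("no finite temperatures to search for the MMT")
    ps = np.linspace(search[0], search[1], n_grid)
    xs = np.percentile(temps, ps)
    basis = ns_basis(xs, curve.exposure_spec)
    g = basis @ np.asarray(curve.coefficients, dtype=float)
    flat = bool(np.ptp(g) < 1e-12)
    if flat:
        k = n_grid // 2
    else:
        k = int(np.argmin(g))
    result = MMTResult(
        mmt=float(xs[k]),
        mmp=float(ps[k]),
        search_interval=(float(search[0]), float(search[1])),
        flat=flat,
    )
    if ci_draws and curve.vcov is not None:
        rng = rng or np.random.default_rng()
        draws = rng.multivariate_normal(
            np.asarray(curve.coefficients, float), curve.vcov, size=ci_draws,
            method="svd",
        )
        argmins = xs[np.argmin(draws @ basis.T, axis=1)]
        result.ci = (
            float(np.percentile(argmins, 2.5)),
            float(np.percentile(argmins, 97.5)),
        )
    return result


def attributable_fractions(
    deaths,
    temps,
    curve: RRCurve | None,
    mmt: float,
    p90: float | None = None,
    rr=None,
) -> AttributionResult:
    """HAF, EHAF and MHAF (in percent) for one city's panel.

    HAF sums m_i (1 - 1/RR_i) over days with T_i >= MMT; EHAF restricts
    to T_i >= P90 (90th percentile of the city's warm-season metric
    values); MHAF to MMT <= T_i < P90.  The denominator is total deaths
    over all days.  Days with missing temperature contribute to the
    denominator only.  ``rr`` supplies per-day relative risks directly,
    bypassing the curve (e.g. for a known ground-truth curve).
    """
    deaths = np.asarray(deaths, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if deaths.shape != temps.shape:
        raise ValueError("deaths and temps must align")
    total = float(deaths.sum())
    if total <= 0:
        raise ValueError("total deaths are zero; attributable fraction undefined")
    if p90 is None:
        p90 = float(np.percentile(temps[np.isfinite(temps)], 90))
    extrapolated = 0
    if rr is None:
        if curve is None:
            raise ValueError("either a curve or explicit rr values are required")
        ccurve = curve if curve.center is not None else curve.centered_at(mmt)
        rr = predict_rr(ccurve, temps)
        lo, hi = ccurve.exposure_spec.boundary_knots
        with np.errstate(invalid="ignore"):
            extrapolated = int(np.sum((temps < lo) | (temps > hi)))
    else:
        rr = np.asarray(rr, dtype=float)
    finite = np.isfinite(temps) & np.isfinite(rr)
    excess = np.where(finite, deaths * (1.0 - 1.0 / np.where(finite, rr, 1.0)), 0.0)
    in_b = finite & (temps >= mmt)
    in_c = finite & (temps >= p90)
    in_d = finite & (temps >= mmt) & (temps < p90)
    haf_num = float(excess[in_b].sum())
    ehaf_num = float(excess[in_c].sum())
    mhaf_num = float(excess[in_d].sum())
    return AttributionResult(
        haf=100.0 * haf_num / total,
        ehaf=100.0 * ehaf_num / total,
        mhaf=100.0 * mhaf_num / total,
        mmt=float(mmt),
        p90=float(p90),
        total_deaths=total,
        haf_numerator=haf_num,
        ehaf_numerator=ehaf_num,
        mhaf_numerator=mhaf_num,
        n_days=int(deaths.size),
        mmt_above_p90=bool(mmt > p90),
        daily_attributable=np.where(in_b, excess, 0.0),
        extrapolated_days=extrapolated,
    )


def combine_attributions(results: list[AttributionResult]) -> AttributionResult:
    """Country-level fractions: pooled numerators over pooled denominators.

    Equals the death-weighted mean of city fractions.
    """
    if not results:
        raise ValueError("nothing to combine")
    total = sum(r.total_deaths for r in results)
    haf_num = sum(r.haf_numerator for r in results)
    ehaf_num = sum(r.ehaf_numerator for r in results)
    mhaf_num = sum(r.mhaf_numerator for r in results)
    return AttributionResult(
        haf=100.0 * haf_num / total,
        ehaf=100.0 * ehaf_num / total,
        mhaf=100.0 * mhaf_num / total,
        mmt=float("nan"),
        p90=float("nan"),
        total_deaths=total,
        haf_numerator=haf_num,
        ehaf_numerator=ehaf_num,
        mhaf_numerator=mhaf_num,
        n_days=sum(r.n_days for r in results),
        mmt_above_p90=any(r.mmt_above_p90 for r in results),
    )
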