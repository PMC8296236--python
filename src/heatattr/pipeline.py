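"""Top-level driver: fit per city per metric, pool, locate MMTs,
cross-validate, select the best metric, and compute attributable
fractions, per country.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from .crossval import CVResult, cross_validate, score_predictions, select_best
from .curves_attribution import (
    AttributionResult,
    RRCurve,
    attributable_fractions,
    combine_attributions,
    find_mmt,
)
from .dlnm_basis import (
    CrossBasisSpec,
    build_cross_basis,
    exposure_spec_from_values,
    lag_spec,
    reduce_to_curve,
)
from .pooling import PooledCurves, ReducedCurve, meta_fit
from .regression import build_design, fit_quasipoisson

logger = logging.getLogger("heatattr")


@dataclass
class CountryReport:
    country_id: str
    mmt_table: pd.DataFrame
    attribution_table: pd.DataFrame
    cv_table: pd.DataFrame
    overall_best: str
    city_best: dict[str, str]
    skipped_metrics: list[str]
    city_attributions: dict[str, dict[str, AttributionResult]] = field(
        default_factory=dict
    )
    pooled_curves: dict[str, PooledCurves] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "country": self.country_id,
            "overall_best": self.overall_best,
            "city_best": self.city_best,
            "skipped_metrics": self.skipped_metrics,
            "mmt": self.mmt_table.to_dict(orient="index"),
            "attribution": self.attribution_table.to_dict(orient="index"),
            "cv": self.cv_table.to_dict(orient="index"),
        }


def fit_city_metric(panel, metric: str, spec: CrossBasisSpec, config: StudyConfig):
    """First-stage fit for one (city, metric): reduced curve + artifacts."""
    x = panel.metric(metric)
    cb = build_cross_basis(x, spec, panel.season_id, policy=config.season_boundary)
    dm = build_design(panel, cb, config)
    fit = fit_quasipoisson(panel.deaths, dm)
    beta_cb = fit.beta[dm.cb_slice]
    vcov_cb = fit.vcov[dm.cb_slice, dm.cb_slice]
    theta, v = reduce_to_curve(beta_cb, vcov_cb, spec)
    curve = ReducedCurve(
        theta=theta,
        vcov=v,
        city_id=panel.city_id,
        metric=metric,
        exposure_spec=spec.exposure_spec,
    )
    return curve, fit, dm, cb


def _metric_analysis(panels, metric, config, rng):
    """Pool one metric across a country's cities; return curves + MMTs + HAFs."""
    if config.knot_scope == "city" and len(panels) > 1:
        raise ValueError(
            "knot_scope='city' gives each city its own exposure basis, which "
            "precludes coefficient-space pooling across cities; use "
            "knot_scope='country' for multi-city countries"
        )
    pooled_vals = np.concatenate([p.metric(metric) for p in panels])
    pooled_vals = pooled_vals[np.isfinite(pooled_vals)]
    spec = CrossBasisSpec(
        exposure_spec=exposure_spec_from_values(
            pooled_vals, config.exposure_knot_percentiles
        ),
        lag_spec=lag_spec(config.max_lag, config.n_lag_knots),
        max_lag=config.max_lag,
    )
    curves = [fit_city_metric(p, metric, spec, config)[0] for p in panels]
    pooled = meta_fit(curves)

    country_curve = RRCurve(spec.exposure_spec, pooled.mu, vcov=pooled.mu_vcov)
    country_mmt = find_mmt(
        country_curve,
        pooled_vals,
        search=config.mmt_search_percentiles,
        n_grid=config.mmt_n_grid,
        ci_draws=config.mmt_ci_draws,
        rng=rng,
    )

    city_attr: dict[str, AttributionResult] = {}
    for p, c in zip(panels, curves):
        if config.attribution_curve == "blup":
            coefs = pooled.blups[p.city_id]
        elif config.attribution_curve == "city":
            coefs = c.theta
        else:
            coefs = pooled.mu
        temps = p.metric(metric)
        curve = RRCurve(spec.exposure_spec, coefs)
        mmt = find_mmt(
            curve,
            temps[np.isfinite(temps)],
            search=config.mmt_search_percentiles,
            n_grid=config.mmt_n_grid,
        )
        city_attr[p.city_id] = attributable_fractions(
            p.deaths, temps, curve.centered_at(mmt.mmt), mmt.mmt
        )
    return spec, pooled, country_mmt, city_attr


def run_pipeline(config: StudyConfig, panels) -> dict[str, CountryReport]:
    """Run the full two-stage analysis per country.

    Returns one :class:`CountryReport` per country: an MMT/MMP table, an
    attribution (HAF/EHAF/MHAF) table and a cross-validation table, each
    with one row per metric plus "Average" and "City-specific best model"
    rows, and the overall-best / city-specific-best metric selections.
    Deterministic given ``config.rng_seed``.
    """
    by_country: dict[str, list] = {}
    for p in panels:
        by_country.setdefault(p.country_id, []).append(p)

    reports: dict[str, CountryReport] = {}
    for country, cpanels in by_country.items():
        rng = np.random.default_rng(config.rng_seed)
        t0 = time.perf_counter()
        available = [
            m for m in config.metrics if all(p.has_metric(m) for p in cpanels)
        ]
        skipped = [m for m in config.metrics if m not in available]
        if skipped:
            logger.warning("%s: metrics skipped (missing in some city): %s",
                           country, skipped)

        mmt_rows, attr_rows = {}, {}
        city_attrs: dict[str, dict[str, AttributionResult]] = {}
        pooled_curves: dict[str, PooledCurves] = {}
        for m in available:
            spec, pooled, country_mmt, city_attr = _metric_analysis(
                cpanels, m, config, rng
            )
            pooled_curves[m] = pooled
            city_attrs[m] = city_attr
            mmt_rows[m] = {"mmp": country_mmt.mmp, "mmt": country_mmt.mmt}
            combined = combine_attributions(list(city_attr.values()))
            attr_rows[m] = {
                "haf": combined.haf, "ehaf": combined.ehaf, "mhaf": combined.mhaf,
            }
        logger.info("%s: first stage + attribution done in %.1fs",
                    country, time.perf_counter() - t0)

        t0 = time.perf_counter()
        cv_scores: dict[str, dict[str, CVResult]] = {}
        for m in available:
            cv_scores[m] = {
                p.city_id: cross_validate(p, m, config) for p in cpanels
            }
        selection = select_best(cv_scores, tuple(config.metrics))
        logger.info("%s: cross-validation done in %.1fs",
                    country, time.perf_counter() - t0)

        cv_rows = {
            m: {
                "r2_pct": 100.0 * selection.country_scores[m]["r2"],
                "rmse": selection.country_scores[m]["rmse"],
            }
            for m in available
        }

        # "Average" rows: mean over the eight metrics
        def _avg(rows):
            df = pd.DataFrame(rows).T
            return df.mean(axis=0).to_dict()

        # "City-specific best model" rows: each city contributes its best
        # metric's numbers, pooled across cities
        best_attr = combine_attributions(
            [city_attrs[selection.city_best[c]][c]
             for c in selection.city_best if selection.city_best[c] in city_attrs]
        )
        best_obs = np.concatenate(
            [cv_scores[selection.city_best[c]][c].observed
             for c in selection.city_best]
        )
        best_pred = np.concatenate(
            [cv_scores[selection.city_best[c]][c].predicted
             for c in selection.city_best]
        )
        best_r2, best_rmse = score_predictions(best_obs, best_pred)

        mmt_table = pd.DataFrame(mmt_rows).T
        attr_table = pd.DataFrame(attr_rows).T
        attr_table.loc["Average"] = _avg(attr_rows)
        attr_table.loc["City-specific best model"] = {
            "haf": best_attr.haf, "ehaf": best_attr.ehaf, "mhaf": best_attr.mhaf,
        }
        cv_table = pd.DataFrame(cv_rows).T
        cv_table.loc["Average"] = _avg(cv_rows)
        cv_table.loc["City-specific best model"] = {
            "r2_pct": 100.0 * best_r2, "rmse": best_rmse,
        }

        reports[country] = CountryReport(
            country_id=country,
            mmt_table=mmt_table,
            attribution_table=attr_table,
            cv_table=cv_table,
            overall_best=selection.overall_best,
            city_best=selection.city_best,
            skipped_metrics=skipped,
            city_attributions=city_attrs,
            pooled_curves=pooled_curves,
        )
    return reports
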