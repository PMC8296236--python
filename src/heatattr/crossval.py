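"""Leave-one-year-out cross-validation and best-metric selection.

Each baseline year in turn is the validation set; the DLNM is refit on
the remaining years (cross-basis knots re-estimated from training rows
only) and predicts the validation year's daily deaths.  Scores are
pooled over all validation days, never averaged over years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import StudyConfig
from .data_io import CityPanel
from .dlnm_basis import (
    CrossBasisSpec,
    build_cross_basis,
    exposure_spec_from_values,
    lag_spec,
)
from .regression import build_design, fit_quasipoisson, predict_deaths


@dataclass
class CVResult:
    city_id: str
    metric: str
    per_year: dict[int, dict]
    overall_r2: float
    overall_rmse: float
    overall_corr_r2: float
    n_failed_folds: int = 0
    observed: np.ndarray | None = None
    predicted: np.ndarray | None = None

    @property
    def complete(self) -> bool:
        return self.n_failed_folds == 0


@dataclass
class MetricSelection:
    overall_best: str
    city_best: dict[str, str]
    scores: dict[str, dict[str, CVResult]]  # metric -> city -> CVResult
    country_scores: dict[str, dict]  # metric -> pooled {r2, rmse}


def loyo_split(panel: CityPanel, year: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (training, validation) row masks for one held-out year."""
    years = panel.years
    if year not in years:
        raise ValueError(f"year {year} absent from panel {panel.city_id!r}")
    val = years == year
    return ~val, val


def score_predictions(observed, predicted) -> tuple[float, float]:
    """(R2, RMSE) of predicted vs observed counts.

    R2 = 1 - SS_res/SS_tot about the observed mean of the scored set; may
    be negative.  Zero observed variance yields NaN R2.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("need equal-length series of length >= 2")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / obs.size))
    r2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return r2, rmse


def squared_correlation(observed, predicted) -> float:
    """Squared Pearson correlation, reported alongside R2 for transparency."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.std() == 0 or pred.std() == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def _fold_predictions(
    panel: CityPanel,
    metric: str,
    config: StudyConfig,
    train_mask: np.ndarray,
    val_mask: np.ndarray,
) -> np.ndarray:
    """Fit on training rows, predict expected deaths on validation rows."""
    x = panel.metric(metric)
    train_vals = x[train_mask]
    spec = CrossBasisSpec(
        exposure_spec=exposure_spec_from_values(
            train_vals, config.exposure_knot_percentiles
        ),
        lag_spec=lag_spec(config.max_lag, config.n_lag_knots),
        max_lag=config.max_lag,
    )
    cb = build_cross_basis(x, spec, panel.season_id, policy=config.season_boundary)
    dm = build_design(panel, cb, config, fit_mask=train_mask)
    fit = fit_quasipoisson(panel.deaths, dm)
    rows = val_mask & cb.valid_row_mask
    return rows, predict_deaths(fit, dm.X[rows])


def cross_validate(panel: CityPanel, metric: str, config: StudyConfig) -> CVResult:
    """Leave-one-year-out CV of the DLNM for one city and metric."""
    if not panel.has_metric(metric):
        raise ValueError(f"metric {metric!r} not present in panel {panel.city_id!r}")
    per_year: dict[int, dict] = {}
    all_obs: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    n_failed = 0
    for year in sorted(np.unique(panel.years)):
        train, val = loyo_split(panel, year)
        try:
            rows, pred = _fold_predictions(panel, metric, config, train, val)
        except (ValueError, RuntimeError) as exc:
            per_year[int(year)] = {"failed": str(exc)}
            n_failed += 1
            continue
        obs = panel.deaths[rows].astype(float)
        r2, rmse = score_predictions(obs, pred)
        per_year[int(year)] = {"r2": r2, "rmse": rmse, "n_days": int(obs.size)}
        all_obs.append(obs)
        all_pred.append(pred)
    obs = np.concatenate(all_obs) if all_obs else np.array([])
    pred = np.concatenate(all_pred) if all_pred else np.array([])
    if obs.size >= 2:
        overall_r2, overall_rmse = score_predictions(obs, pred)
        corr_r2 = squared_correlation(obs, pred)
    else:
        overall_r2 = overall_rmse = corr_r2 = float("nan")
    return CVResult(
        city_id=panel.city_id,
        metric=metric,
        per_year=per_year,
        overall_r2=overall_r2,
        overall_rmse=overall_rmse,
        overall_corr_r2=corr_r2,
        n_failed_folds=n_failed,
        observed=obs,
        predicted=pred,
    )


def _pooled_score(results: list[CVResult]) -> dict:
    obs = np.concatenate([r.observed for r in results if r.observed is not None])
    pred = np.concatenate([r.predicted for r in results if r.predicted is not None])
    r2, rmse = score_predictions(obs, pred)
    return {"r2": r2, "rmse": rmse, "n_days": int(obs.size)}


def select_best(
    cv: dict[str, dict[str, CVResult]],
    metric_order: tuple[str, ...],
) -> MetricSelection:
    """Best metric overall (country-pooled validation days) and per city.

    Ties break by lower RMSE, then by the fixed metric ordering.
    """
    metrics = [m for m in metric_order if m in cv]
    if not metrics:
        raise ValueError("no scored metrics to select from")
    country_scores = {m: _pooled_score(list(cv[m].values())) for m in metrics}

    def key(m):
        s = country_scores[m]
        return (-s["r2"], s["rmse"], metric_order.index(m))

    overall_best = min(metrics, key=key)

    cities = sorted({c for m in metrics for c in cv[m]})
    city_best: dict[str, str] = {}
    for c in cities:
        avail = [m for m in metrics if c in cv[m]]

        def ckey(m):
            r = cv[m][c]
            return (-r.overall_r2, r.overall_rmse, metric_order.index(m))

        city_best[c] = min(avail, key=ckey)
    return MetricSelection(
        overall_best=overall_best,
        city_best=city_best,
        scores=cv,
        country_scores=country_scores,
    )
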