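"""Derivation of the eight daily temperature metrics.

Five plain metrics (tmean, tmax, tmax_day, tmin, tmin_night) pass through
unchanged; three apparent-temperature variants (tmean_app, tmax_app,
tmin_app) combine air temperature with humidity.  Humidity may be supplied
as dew point directly or as relative humidity (converted via the Magnus
approximation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import METRIC_NAMES

PLAIN_METRICS = ("tmean", "tmax", "tmax_day", "tmin", "tmin_night")
APPARENT_METRICS = ("tmean_app", "tmax_app", "tmin_app")

# Magnus dew-point approximation constants (over water).
MAGNUS_ALPHA = 17.27
MAGNUS_BETA = 237.7  # degC


def dew_point_from_rh(t_air, rh):
    """Dew point (degC) from air temperature (degC) and relative humidity (%).

    Uses the Magnus formula with alpha=17.27, beta=237.7 degC.  Non-finite
    or out-of-range humidity yields NaN.
    """
    t_air = np.asarray(t_air, dtype=float)
    rh = np.asarray(rh, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rh_frac = np.where((rh > 0) & (rh <= 100.0), rh / 100.0, np.nan)
        gamma = np.log(rh_frac) + MAGNUS_ALPHA * t_air / (MAGNUS_BETA + t_air)
        td = MAGNUS_BETA * gamma / (MAGNUS_ALPHA - gamma)
    return td


def saturation_vapour_pressure(t_air):
    """Saturation vapour pressure in kPa (Magnus form)."""
    t_air = np.asarray(t_air, dtype=float)
    return 0.6108 * np.exp(MAGNUS_ALPHA * t_air / (MAGNUS_BETA + t_air))


def apparent_temperature(t_air, dew_point, formula: str = "kalkstein"):
    """Apparent temperature (degC) combining heat and humidity.

    formula="kalkstein" (default):
        AT = -2.653 + 0.994*t_air + 0.0153*dew_point**2
    formula="steadman" (vapour-pressure form, e the actual vapour
    pressure in kPa at the dew point):
        AT = -1.3 + 0.92*t_air + 2.2*e

    Non-finite inputs propagate to NaN.
    """
    t_air = np.asarray(t_air, dtype=float)
    dew_point = np.asarray(dew_point, dtype=float)
    if formula == "kalkstein":
        at = -2.653 + 0.994 * t_air + 0.0153 * dew_point ** 2
    elif formula == "steadman":
        e = saturation_vapour_pressure(dew_point)
        at = -1.3 + 0.92 * t_air + 2.2 * e
    else:
        raise ValueError(f"unknown apparent-temperature formula: {formula!r}")
    bad = ~(np.isfinite(t_air) & np.isfinite(dew_point))
    return np.where(bad, np.nan, at)


def _dew_point_columns(raw: pd.DataFrame) -> dict[str, np.ndarray]:
    """Resolve per-day dew points for the mean/max-time/min-time slots.

    Prefers explicit dew-point columns; falls back to RH conversion; falls
    back to the daily-mean value for the time-resolved slots.  Returns a
    dict with keys 'mean', 'max_time', 'min_time' and a 'fallback' flag.
    """
    n = len(raw)
    nan = np.full(n, np.nan)

    def col(name):
        return raw[name].to_numpy(dtype=float) if name in raw.columns else None

    out: dict[str, np.ndarray] = {}
    fallback = False
    # daily-mean dew point
    td_mean = col("dewpoint_mean")
    if td_mean is None:
        rh = col("rh_mean")
        t = col("tmean")
        td_mean = dew_point_from_rh(t, rh) if (rh is not None and t is not None) else nan
    out["mean"] = td_mean
    for slot, tdcol, rhcol, tcol in (
        ("max_time", "dewpoint_max_time", "rh_max_time", "tmax"),
        ("min_time", "dewpoint_min_time", "rh_min_time", "tmin"),
    ):
        td = col(tdcol)
        if td is None:
            rh = col(rhcol)
            t = col(tcol)
            if rh is not None and t is not None:
                td = dew_point_from_rh(t, rh)
            else:
                td = td_mean
                fallback = True
        out[slot] = td
    out["fallback"] = fallback  # type: ignore[assignment]
    return out


def derive_metrics(raw: pd.DataFrame, formula: str = "kalkstein") -> pd.DataFrame:
    """Derive all eight metric series from raw weather columns.

    The five plain metrics are passed through bit-exactly.  Apparent
    variants pair (tmean, mean dew point), (tmax, dew point at time of
    max) and (tmin, dew point at time of min), falling back to the daily
    mean dew point when time-resolved humidity is absent.  Missing
    humidity leaves the apparent metrics NaN for that day.

    Returns a DataFrame with the eight canonical metric columns plus a
    ``.attrs['dewpoint_fallback']`` flag recording any fallback.
    """
    missing = [m for m in PLAIN_METRICS if m not in raw.columns]
    if missing:
        raise ValueError(f"raw weather data lacks required columns: {missing}")
    td = _dew_point_columns(raw)
    out = pd.DataFrame(index=raw.index)
    for m in PLAIN_METRICS:
        out[m] = raw[m].to_numpy()
    out["tmean_app"] = apparent_temperature(out["tmean"], td["mean"], formula)
    out["tmax_app"] = apparent_temperature(out["tmax"], td["max_time"], formula)
    out["tmin_app"] = apparent_temperature(out["tmin"], td["min_time"], formula)
    out = out[list(METRIC_NAMES)]
    out.attrs["dewpoint_fallback"] = bool(td["fallback"])
    return out
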