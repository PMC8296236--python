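"""Panel data model and CSV reading/writing.

A :class:`CityPanel` holds one city's warm-season daily series: dates,
death counts, and the eight temperature-metric series.  CSVs use the
canonical dialect: comma-separated, UTF-8, header row, "." decimal,
ISO-8601 dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import METRIC_NAMES, StudyConfig
from .metrics import PLAIN_METRICS, derive_metrics

_DOW_LABELS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: raw-weather columns recognised beyond the plain metrics
_HUMIDITY_COLUMNS = (
    "rh_mean", "rh_max_time", "rh_min_time",
    "dewpoint_mean", "dewpoint_max_time", "dewpoint_min_time",
)


@dataclass
class CityPanel:
    """One city's daily warm-season series over the baseline period."""

    city_id: str
    country_id: str
    dates: pd.DatetimeIndex
    deaths: np.ndarray
    metric_values: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.deaths = np.asarray(self.deaths)
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing and unique")
        months = self.dates.month
        season = self.meta.get("season_months", (5, 6, 7, 8, 9))
        if not np.isin(months, list(season)).all():
            raise ValueError("panel contains dates outside the warm season")
        d = np.asarray(self.deaths, dtype=float)
        if np.any(~np.isfinite(d)) or np.any(d < 0) or np.any(d != np.round(d)):
            raise ValueError("deaths must be non-negative integers")
        self.deaths = d.astype(np.int64)
        if len(self.metric_values) != len(self.dates):
            raise ValueError("metric series length differs from dates")
        # a season block = one (year, contiguous run) of in-season days
        self._validate_contiguity()

    def _validate_contiguity(self) -> None:
        # within a year's season there must be no silent calendar gaps
        for year, sub in pd.Series(1, index=self.dates).groupby(self.dates.year):
            idx = sub.index
            expected = (idx.max() - idx.min()).days + 1
            if len(idx) != expected:
                raise ValueError(
                    f"missing calendar days inside season of year {year}; "
                    "represent gaps as explicit missing-value rows"
                )

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def dow(self) -> np.ndarray:
        """Day-of-week label per day (Mon..Sun)."""
        return np.asarray([_DOW_LABELS[d] for d in self.dates.dayofweek])

    @property
    def time_index(self) -> np.ndarray:
        """Consecutive in-season day index over the full panel (no winter gaps)."""
        return np.arange(len(self.dates))

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.dates.year)

    @property
    def season_id(self) -> np.ndarray:
        """Identifier of the contiguous season block each day belongs to."""
        return np.asarray(self.dates.year)

    def metric(self, name: str) -> np.ndarray:
        if name not in self.metric_values.columns:
            raise KeyError(f"metric {name!r} not present in panel {self.city_id!r}")
        return self.metric_values[name].to_numpy(dtype=float)

    def has_metric(self, name: str) -> bool:
        return (
            name in self.metric_values.columns
            and np.isfinite(self.metric_values[name].to_numpy(dtype=float)).any()
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"city": self.city_id, "date": self.dates.strftime("%Y-%m-%d")})
        df["deaths"] = self.deaths
        for m in self.metric_values.columns:
            df[m] = self.metric_values[m].to_numpy()
        return df


def read_city_panel(
    path,
    schema: dict | None = None,
    config: StudyConfig | None = None,
    city_id: str | None = None,
    country_id: str = "",
) -> CityPanel:
    """Read and validate one city's CSV into a :class:`CityPanel`.

    ``schema`` maps canonical column names (date, deaths, tmean, ...) to
    the file's column names.  Rows outside the configured season months or
    baseline years are dropped.  Missing weather values are retained as
    NaN.  Duplicate dates and non-integer death counts are hard errors; a
    metric with more than 10% missing days is recorded as a warning in
    ``panel.meta['warnings']``.
    """
    config = config or StudyConfig()
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    if "date" not in df.columns or "deaths" not in df.columns:
        raise ValueError("CSV must contain 'date' and 'deaths' columns")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    lo, hi = config.baseline_years
    keep = (
        df["date"].dt.month.isin(config.season_months)
        & (df["date"].dt.year >= lo)
        & (df["date"].dt.year <= hi)
    )
    df = df.loc[keep].sort_values("date").reset_index(drop=True)
    if df["date"].duplicated().any():
        dups = df.loc[df["date"].duplicated(), "date"].dt.strftime("%Y-%m-%d").tolist()
        raise ValueError(f"duplicate dates in {path}: {dups}")
    deaths = pd.to_numeric(df["deaths"], errors="raise")
    if (deaths.astype(float) != deaths.astype(float).round()).any():
        raise ValueError("death counts must be integers")

    have_plain = [m for m in PLAIN_METRICS if m in df.columns]
    raw_cols = have_plain + [c for c in _HUMIDITY_COLUMNS if c in df.columns]
    app_present = [m for m in ("tmean_app", "tmax_app", "tmin_app") if m in df.columns]
    if len(have_plain) == len(PLAIN_METRICS) and not app_present:
        mv = derive_metrics(df[raw_cols], formula=config.apparent_formula)
    else:
        cols = [m for m in METRIC_NAMES if m in df.columns]
        mv = df[cols].astype(float).copy()
    meta: dict = {
        "source": str(path),
        "season_months": tuple(config.season_months),
        "warnings": [],
    }
    if mv.attrs.get("dewpoint_fallback"):
        meta["warnings"].append("time-resolved dew point absent; daily mean used")
    for m in config.metrics:
        if m in mv.columns:
            frac = float(np.mean(~np.isfinite(mv[m].to_numpy(dtype=float))))
            if frac > 0.10:
                meta["warnings"].append(f"metric {m}: {frac:.0%} missing")
    cid = city_id or (str(df["city"].iloc[0]) if "city" in df.columns else "city")
    return CityPanel(
        city_id=cid,
        country_id=country_id,
        dates=pd.DatetimeIndex(df["date"]),
        deaths=deaths.to_numpy(),
        metric_values=mv.reset_index(drop=True),
        meta=meta,
    )


def write_city_panel(panel: CityPanel, path) -> None:
    """Write a panel in the canonical CSV dialect (deterministic formatting)."""
    df = panel.to_frame()
    df.to_csv(path, index=False, lineterminator="\n")


# re-exported pipeline driver (defined in pipeline.py to avoid a cycle)
from .pipeline import run_pipeline  # noqa: E402,F401
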