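"""Study configuration: baseline window, basis dimensions, search settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: Fixed, documented ordering of the eight temperature metrics.  Used for
#: deterministic tie-breaking in metric selection and for table row order.
METRIC_NAMES: tuple[str, ...] = (
    "tmean",
    "tmax",
    "tmax_day",
    "tmin",
    "tmin_night",
    "tmean_app",
    "tmax_app",
    "tmin_app",
)


@dataclass
class StudyConfig:
    """Analysis settings shared by every pipeline stage.

    Defaults correspond to a 21-warm-season (1995-2015, May-September)
    multi-city study with a 10-day lag cross-basis.
    """

    baseline_years: tuple[int, int] = (1995, 2015)
    season_months: tuple[int, ...] = (5, 6, 7, 8, 9)
    metrics: tuple[str, ...] = METRIC_NAMES
    max_lag: int = 10
    exposure_knot_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0)
    n_lag_knots: int = 2
    seasonal_df_per_year: int = 4
    mmt_search_percentiles: tuple[float, float] = (1.0, 99.0)
    rng_seed: int = 0
    #: "regional" knot placement: pooled per-country ("country") or per-city.
    knot_scope: str = "country"
    #: season-boundary lag handling: "pad" repeats the first observed day of
    #: each season; "drop" excludes rows with incomplete lag history.
    season_boundary: str = "pad"
    #: apparent-temperature formula: "kalkstein" (dew-point quadratic) or
    #: "steadman" (vapour-pressure form).
    apparent_formula: str = "kalkstein"
    #: which curve feeds per-city attribution: "blup", "city" or "pooled".
    attribution_curve: str = "blup"
    mmt_n_grid: int = 1000
    mmt_ci_draws: int = 0

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        kp = tuple(float(p) for p in self.exposure_knot_percentiles)
        if any(not 0.0 < p < 100.0 for p in kp):
            raise ValueError("knot percentiles must lie strictly inside (0, 100)")
        if any(b <= a for a, b in zip(kp, kp[1:])):
            raise ValueError("knot percentiles must be strictly increasing")
        if self.seasonal_df_per_year < 1:
            raise ValueError("seasonal_df_per_year must be >= 1")
        if self.knot_scope not in ("country", "city"):
            raise ValueError("knot_scope must be 'country' or 'city'")
        if self.season_boundary not in ("pad", "drop"):
            raise ValueError("season_boundary must be 'pad' or 'drop'")
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown metric names: {sorted(unknown)}")

    @property
    def years(self) -> range:
        lo, hi = self.baseline_years
        return range(lo, hi + 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("baseline_years", "season_months", "metrics",
                    "exposure_knot_percentiles", "mmt_search_percentiles"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
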