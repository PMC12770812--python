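"""Annual covariates from daily weather series and life-cycle windows.

Breeding-season windows are anchored on the annual mean nest-initiation
date of each site: the nest-initiation/incubation window starts 14 days
before that date and spans 6 laying plus 14 incubation days (34 days in
total); the hatchling window is the following 16 days; the post-fledging
window starts 10 days after the hatchling window ends and runs to the end
of August.  Temperature covariates average the daily values inside a
window, precipitation accumulates them.  All covariates are z-standardized
across years before entering a model, and pairs with |Pearson r| above a
threshold (0.50 by default) are barred from appearing in the same model.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PERIODS = ("nest_init_incub", "hatchling", "post_fledging")

#: statistic name -> (daily column, aggregation)
STATISTICS = {
    "mean": ("tmean", "mean"),
    "min-mean": ("tmin", "mean"),
    "max-mean": ("tmax", "mean"),
    "cumulative": ("precip", "sum"),
}


class ConstantSeriesError(ValueError):
    """A series without variation cannot be standardized."""


@dataclass(frozen=True)
class WindowSpec:
    """One life-cycle period of one site-year, as an inclusive date range."""

    site: str
    year: int
    period: str
    start: dt.date
    end: dt.date

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class CovariateSeries:
    """A named annual covariate, optionally tied to a demographic rate."""

    name: str
    years: np.ndarray
    values: np.ndarray            # NaN = missing year
    target: str | None = None     # e.g. "survival:juv" or "fledging:ad"
    standardized: bool = False
    period: str | None = None
    window_days: dict = field(default_factory=dict)

    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class WindowConfig:
    """Window-construction constants (days), configurable but fixed by default."""

    pre_initiation_days: int = 14
    laying_days: int = 6
    incubation_days: int = 14
    hatchling_days: int = 16
    post_fledging_gap_days: int = 10
    post_fledging_end: tuple = (8, 31)  # month, day

    @property
    def incubation_total(self) -> int:
        # 14 before initiation + 6 laying + 14 incubation = 34-day window
        return self.pre_initiation_days + self.laying_days + self.incubation_days


def derive_windows(init_dates, config: WindowConfig = WindowConfig()) -> list[WindowSpec]:
    """Build the three breeding-season windows for each site-year.

    ``init_dates`` maps ``(site, year) -> datetime.date`` (mean nest
    initiation, rounded to the day).  Dates outside March-August raise a
    warning, not an error: implausible phenology should be visible but must
    not halt a pipeline.
    """
    windows: list[WindowSpec] = []
    for (site, year), d in sorted(init_dates.items()):
        if isinstance(d, str):
            d = dt.date.fromisoformat(d)
        if not (3 <= d.month <= 8):
            warnings.warn(
                f"mean nest initiation {d} for {site}/{year} outside March-August",
                stacklevel=2,
            )
        nii_start = d - dt.timedelta(days=config.pre_initiation_days)
        nii_end = nii_start + dt.timedelta(days=config.incubation_total - 1)
        hat_start = nii_end + dt.timedelta(days=1)
        hat_end = hat_start + dt.timedelta(days=config.hatchling_days - 1)
        pf_start = hat_end + dt.timedelta(days=config.post_fledging_gap_days)
        pf_end = dt.date(year, *config.post_fledging_end)
        windows.append(WindowSpec(site, year, "nest_init_incub", nii_start, nii_end))
        windows.append(WindowSpec(site, year, "hatchling", hat_start, hat_end))
        windows.append(WindowSpec(site, year, "post_fledging", pf_start, pf_end))
    return windows


def summarize_daily(
    daily: pd.DataFrame,
    windows: list[WindowSpec],
    statistic: str,
    period: str,
    name: str | None = None,
) -> CovariateSeries:
    """Summarize a daily weather table over the windows of one period.

    ``daily`` needs a ``date`` column plus ``tmean, tmin, tmax, precip``;
    summaries are pooled over sites sharing a year (windows from different
    sites are averaged).  Windows with no daily rows yield NaN and a warning.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {list(STATISTICS)}")
    column, how = STATISTICS[statistic]
    df = daily.copy()
    dates = pd.to_datetime(df["date"]).dt.date
    sel = [w for w in windows if w.period == period]
    if not sel:
        raise ValueError(f"no windows for period {period!r}")
    years = np.array(sorted({w.year for w in sel}))
    values = np.full(len(years), np.nan)
    ndays = {}
    for i, year in enumerate(years.tolist()):
        per_site = []
        for w in (w for w in sel if w.year == year):
            mask = (dates >= w.start) & (dates <= w.end)
            ndays[(w.site, year)] = w.n_days
            if not mask.any():
                warnings.warn(f"no daily data inside {w.period} window of {w.site}/{year}",
                              stacklevel=2)
                continue
            vals = df.loc[mask.to_numpy(), column]
            per_site.append(vals.sum() if how == "sum" else vals.mean())
        if per_site:
            values[i] = float(np.mean(per_site))
    return CovariateSeries(
        name=name or f"{column}_{statistic}_{period}",
        years=years,
        values=values,
        period=period,
        window_days=ndays,
    )


def standardize(series: CovariateSeries) -> CovariateSeries:
    """z-standardize across non-missing years (sample SD, n-1 denominator)."""
    obs = series.observed()
    vals = series.values[obs]
    if len(np.unique(vals)) < 2:
        raise ConstantSeriesError(f"covariate {series.name!r} is constant; cannot standardize")
    out = series.values.copy()
    out[obs] = (vals - vals.mean()) / vals.std(ddof=1)
    return replace(series, values=out, standardized=True)


def correlation_screen(series: list[CovariateSeries], threshold: float = 0.50) -> list[frozenset]:
    """All unordered covariate pairs whose |Pearson r| exceeds the threshold.

    Pairs with fewer than 3 overlapping years are skipped with a warning
    (a correlation from <3 points is meaningless).
    """
    excluded: list[frozenset] = []
    for i in range(len(series)):
        for k in range(i + 1, len(series)):
            a, b = series[i], series[k]
            common, ia, ib = np.intersect1d(a.years, b.years, return_indices=True)
            va, vb = a.values[ia], b.values[ib]
            ok = ~np.isnan(va) & ~np.isnan(vb)
            if ok.sum() < 3:
                warnings.warn(
                    f"pair ({a.name}, {b.name}): fewer than 3 overlapping years, skipped",
                    stacklevel=2,
                )
                continue
            r = np.corrcoef(va[ok], vb[ok])[0, 1]
            if abs(r) > threshold:
                excluded.append(frozenset((a.name, b.name)))
    return excluded


def windows_to_frame(windows: list[WindowSpec]) -> pd.DataFrame:
    """Audit export of the window table."""
    return pd.DataFrame(
        [
            {
                "site": w.site,
                "year": w.year,
                "period": w.period,
                "start": w.start.isoformat(),
                "end": w.end.isoformat(),
                "days": w.n_days,
            }
            for w in windows
        ]
    )
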