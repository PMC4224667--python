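"""Daily weather series: reading, synthetic generation, film-mulch adjustment.

Weather is the sole environmental driver of the model: daily minimum and
maximum air temperature (°C) determine the physiological clock and the
fibre-quality reduction factors.  Rainfall, sunshine and humidity are not
used.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "WeatherDay",
    "SeasonWeather",
    "SyntheticWeatherSpec",
    "WeatherFormatError",
    "read_weather",
    "generate_weather",
    "apply_film_mulch",
    "active_thermal_sum",
    "tune_annual_mean",
    "site_weather_spec",
    "SITE_THERMAL_SUMS",
]


class WeatherFormatError(ValueError):
    """Raised when a weather file violates the expected format or invariants."""


@dataclass(frozen=True)
class WeatherDay:
    """One calendar day of weather.

    Attributes
    ----------
    date : datetime.date
    t_min, t_max : float
        Daily minimum and maximum air temperature, °C.
    """

    date: dt.date
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValueError(
                f"{self.date}: t_min ({self.t_min}) exceeds t_max ({self.t_max})"
            )

    @property
    def t_mean(self) -> float:
        """Daily mean temperature, the average of minimum and maximum (°C)."""
        return 0.5 * (self.t_min + self.t_max)

    @property
    def t_range(self) -> float:
        """Diurnal temperature range t_max − t_min (°C), ≥ 0."""
        return self.t_max - self.t_min


@dataclass
class SeasonWeather:
    """An ordered, gap-free daily weather series for one site."""

    site_label: str
    days: list[WeatherDay]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.days, self.days[1:]):
            if cur.date != prev.date + dt.timedelta(days=1):
                raise ValueError(
                    f"dates must be consecutive: {prev.date} followed by {cur.date}"
                )
        self._by_date = {d.date: d for d in self.days}

    def __len__(self) -> int:
        return len(self.days)

    def __iter__(self):
        return iter(self.days)

    def __getitem__(self, date: dt.date) -> WeatherDay:
        return self._by_date[date]

    def __contains__(self, date: dt.date) -> bool:
        return date in self._by_date

    @property
    def start(self) -> dt.date:
        return self.days[0].date

    @property
    def end(self) -> dt.date:
        return self.days[-1].date

    def slice(self, start: dt.date, end: dt.date) -> "SeasonWeather":
        """Sub-series from ``start`` through ``end`` inclusive."""
        sel = [d for d in self.days if start <= d.date <= end]
        if not sel:
            raise ValueError(f"no weather between {start} and {end}")
        return SeasonWeather(self.site_label, sel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [d.date for d in self.days],
                "t_min": [d.t_min for d in self.days],
                "t_max": [d.t_max for d in self.days],
                "t_mean": [d.t_mean for d in self.days],
                "t_range": [d.t_range for d in self.days],
            }
        )


@dataclass(frozen=True)
class SyntheticWeatherSpec:
    """Parameters of the sinusoidal synthetic-weather generator.

    The daily mean follows an annual sinusoid peaking in late July
    (``peak_doy``); Tmin/Tmax sit half a diurnal range below/above it, each
    perturbed by independent Gaussian day-to-day noise.
    """

    annual_mean: float = 14.0
    amplitude: float = 14.0
    diurnal_range: float = 10.0
    noise_sd: float = 1.5
    seed: int = 0
    n_years: int = 1
    start_year: int = 2000
    peak_doy: int = 205  # late July
    site_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_years <= 0:
            raise ValueError("n_years must be positive")


_REQUIRED_COLUMNS = ("date", "t_min", "t_max")


def read_weather(path, site_label: str | None = None) -> SeasonWeather:
    """Read a daily weather CSV with columns ``date,t_min,t_max`` (ISO dates, °C).

    Rows must be in strictly increasing consecutive calendar order; violations
    are reported with the offending file row number (header = row 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherFormatError(f"missing column(s): {', '.join(missing)}")
    if df.empty:
        raise WeatherFormatError("no records")

    days: list[WeatherDay] = []
    prev_date: dt.date | None = None
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # header is row 1
        try:
            date = dt.date.fromisoformat(str(row.date))
        except ValueError as exc:
            raise WeatherFormatError(f"row {rownum}: unparseable date {row.date!r}") from exc
        if prev_date is not None and date <= prev_date:
            raise WeatherFormatError(
                f"row {rownum}: date {date} not after previous date {prev_date}"
            )
        try:
            day = WeatherDay(date, float(row.t_min), float(row.t_max))
        except ValueError as exc:
            raise WeatherFormatError(f"row {rownum}: {exc}") from exc
        days.append(day)
        prev_date = date

    # SeasonWeather re-checks gap-freeness; map its error to a row number.
    for i, (prev, cur) in enumerate(zip(days, days[1:])):
        if cur.date != prev.date + dt.timedelta(days=1):
            raise WeatherFormatError(
                f"row {i + 3}: gap in dates ({prev.date} -> {cur.date})"
            )
    return SeasonWeather(site_label or str(path), days)


def _sinusoid_mean(spec: SyntheticWeatherSpec, doy: np.ndarray) -> np.ndarray:
    phase = 2.0 * np.pi * (doy - spec.peak_doy) / 365.25
    return spec.annual_mean + spec.amplitude * np.cos(phase)


def generate_weather(spec: SyntheticWeatherSpec) -> SeasonWeather:
    """Generate a reproducible multi-year synthetic daily series.

    Identical spec (including seed) gives a bit-identical series.  Noise can
    occasionally invert the Tmin/Tmax ordering on low-range days; the pair is
    re-ordered so the WeatherDay invariant always holds.
    """
    rng = np.random.default_rng(spec.seed)
    days: list[WeatherDay] = []
    for year in range(spec.start_year, spec.start_year + spec.n_years):
        start = dt.date(year, 1, 1)
        n = (dt.date(year, 12, 31) - start).days + 1
        dates = [start + dt.timedelta(days=i) for i in range(n)]
        doy = np.arange(1, n + 1, dtype=float)
        t_mean = _sinusoid_mean(spec, doy)
        noise_lo = rng.normal(0.0, spec.noise_sd, size=n)
        noise_hi = rng.normal(0.0, spec.noise_sd, size=n)
        lo = t_mean - 0.5 * spec.diurnal_range + noise_lo
        hi = t_mean + 0.5 * spec.diurnal_range + noise_hi
        t_min = np.minimum(lo, hi)
        t_max = np.maximum(lo, hi)
        days.extend(
            WeatherDay(d, float(a), float(b)) for d, a, b in zip(dates, t_min, t_max)
        )
    return SeasonWeather(spec.site_label, days)


def apply_film_mulch(
    weather: SeasonWeather,
    mulch_delta: float,
    mulch_start: dt.date,
    mulch_end: dt.date,
) -> SeasonWeather:
    """Additive early-season film-mulch temperature increment.

    Plastic film mulch warms the seedbed; the model represents this as a
    constant increment ``mulch_delta`` (°C) added to Tmin and Tmax (hence the
    mean) from ``mulch_start`` (sowing) through ``mulch_end`` inclusive.
    """
    if mulch_delta < 0:
        raise ValueError("mulch_delta must be >= 0")
    if mulch_end < mulch_start:
        raise ValueError("mulch_end before mulch_start")
    out = [
        WeatherDay(d.date, d.t_min + mulch_delta, d.t_max + mulch_delta)
        if mulch_start <= d.date <= mulch_end
        else d
        for d in weather.days
    ]
    return SeasonWeather(weather.site_label, out)


def active_thermal_sum(
    weather: SeasonWeather,
    base: float = 12.0,
    start: dt.date | None = None,
    end: dt.date | None = None,
) -> float:
    """Active accumulated temperature: sum of daily means on days with mean ≥ base.

    This is the agro-climatological "above-base temperature sum" (degree-days)
    conventionally reported for the April–October cotton season.
    """
    total = 0.0
    for d in weather.days:
        if start is not None and d.date < start:
            continue
        if end is not None and d.date > end:
            continue
        if d.t_mean >= base:
            total += d.t_mean
    return total


# April–October active thermal sums (>12 °C, degree-days) for sites used in
# calibration/scenario work; used only to tune the synthetic generator.
SITE_THERMAL_SUMS: dict[str, float] = {
    "anyang": 4561.0,
    "huimin": 4518.0,
    "yueyang": 5245.0,
    "aksu": 4335.0,
}


def _season_window(year: int) -> tuple[dt.date, dt.date]:
    return dt.date(year, 4, 1), dt.date(year, 10, 31)


def tune_annual_mean(
    spec: SyntheticWeatherSpec, target_degree_days: float, base: float = 12.0
) -> SyntheticWeatherSpec:
    """Adjust ``annual_mean`` so the noise-free April–October active thermal sum
    matches ``target_degree_days``.

    Solved by bracketed root-finding on the (monotone) sum-vs-mean map of the
    deterministic sinusoid; noise averages out of the sum to first order.
    """

    def season_sum(mean: float) -> float:
        s = replace(spec, annual_mean=mean, noise_sd=0.0, n_years=1)
        w = generate_weather(s)
        start, end = _season_window(spec.start_year)
        return active_thermal_sum(w, base=base, start=start, end=end)

    lo, hi = -10.0, 40.0
    mean = brentq(lambda m: season_sum(m) - target_degree_days, lo, hi, xtol=1e-6)
    return replace(spec, annual_mean=float(mean))


def site_weather_spec(
    site: str, seed: int = 0, n_years: int = 1, start_year: int = 2000, **overrides
) -> SyntheticWeatherSpec:
    """Synthetic-weather spec tuned to a named site's seasonal thermal sum."""
    key = site.lower()
    if key not in SITE_THERMAL_SUMS:
        raise KeyError(f"unknown site {site!r}; known: {sorted(SITE_THERMAL_SUMS)}")
    base_spec = SyntheticWeatherSpec(
        seed=seed, n_years=n_years, start_year=start_year, site_label=key, **overrides
    )
    return tune_annual_mean(base_spec, SITE_THERMAL_SUMS[key])
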