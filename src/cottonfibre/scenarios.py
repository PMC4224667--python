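"""Scenario sweeps over management × site × year, and aggregation.

Region presets encode common farm practice (sowing, main-stem topping,
branch topping, plant density, film mulch).  A scenario perturbs one or more
practice dates by a day offset, runs a small stand of plants for each year,
and aggregates per-fruit fibre quality into plant means, per-CPN profiles
and quality-frequency histograms.  All aggregates are over *retained* fruits
(neither abscised nor removed by topping); abscised fruits carry no
harvestable fibre.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .architecture import ArchitectureParams, ManagementParams
from .fibre_quality import INDICES, QualityParams
from .simulate import INDEX_COLUMNS, fruits_to_frame, run_stand
from .thermal import ThermalParams
from .weather import SeasonWeather, SyntheticWeatherSpec, generate_weather, site_weather_spec

__all__ = [
    "RegionPreset",
    "REGION_PRESETS",
    "SOWING_OFFSETS",
    "MAIN_TOPPING_OFFSETS",
    "BRANCH_TOPPING_OFFSETS",
    "ScenarioSpec",
    "AggregateResult",
    "run_scenario",
    "cpn_profile",
    "quality_histogram",
    "default_bin_edges",
]


@dataclass(frozen=True)
class RegionPreset:
    """Farm-practice anchors for a cotton-growing region (month, day) tuples."""

    name: str
    site: str  # synthetic-weather site key
    sowing: tuple[int, int]
    main_topping: tuple[int, int]
    branch_topping: tuple[int, int]
    density: float  # plants m⁻²
    film_mulch: bool

    def management(self, year: int, spec: "ScenarioSpec") -> ManagementParams:
        off = dt.timedelta
        sow = dt.date(year, *self.sowing) + off(days=spec.sowing_offset)
        main = dt.date(year, *self.main_topping) + off(days=spec.main_topping_offset)
        branch = dt.date(year, *self.branch_topping) + off(days=spec.branch_topping_offset)
        mulch = self.film_mulch if spec.mulch is None else spec.mulch
        return ManagementParams(
            sowing_date=sow,
            main_topping_date=main,
            branch_topping_date=branch,
            density=self.density,
            mc_applied=spec.mc_applied,
            film_mulch=mulch,
        )


# Farmer-practice anchors per region; Xinjiang plants densely under film
# mulch, the Yellow and Yangtze River regions at lower density without mulch.
REGION_PRESETS: dict[str, RegionPreset] = {
    "xinjiang": RegionPreset("xinjiang", "aksu", (4, 10), (7, 20), (8, 5), 18.0, True),
    "yellow_river": RegionPreset("yellow_river", "huimin", (4, 25), (7, 30), (8, 15), 6.0, False),
    "yangtze": RegionPreset("yangtze", "yueyang", (4, 10), (8, 10), (8, 25), 6.0, False),
}

# Offset menus of the standard scenario design (days relative to practice).
SOWING_OFFSETS = (-20, -10, 0, 10, 20, 30)
MAIN_TOPPING_OFFSETS = (-10, -5, 0, 5, 10, 15)
BRANCH_TOPPING_OFFSETS = (0, 10, 20, 30)


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario cell: a region preset plus day offsets and a mulch flag."""

    region: str
    sowing_offset: int = 0
    main_topping_offset: int = 0
    branch_topping_offset: int = 0
    mulch: bool | None = None  # None = region default
    mc_applied: bool = False
    years: tuple[int, ...] = (2000,)
    n_plants: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region not in REGION_PRESETS:
            raise KeyError(f"unknown region {self.region!r}")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if not self.years:
            raise ValueError("at least one year required")


@dataclass
class AggregateResult:
    """Aggregated output of one scenario cell."""

    spec: ScenarioSpec
    fruits: pd.DataFrame  # all initiated fruits, all years
    means: dict[str, float]
    sds: dict[str, float]
    n_retained: int
    profile: pd.DataFrame  # per-CPN means and 2×SE
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # index -> (counts, edges)


WeatherSource = Callable[[int, int], SeasonWeather]


def synthetic_weather_source(site: str, **overrides) -> WeatherSource:
    """Weather source generating one tuned synthetic year per (year, seed) call."""

    def source(year: int, seed: int) -> SeasonWeather:
        spec = site_weather_spec(site, seed=seed, n_years=1, start_year=year, **overrides)
        return generate_weather(spec)

    return source


def run_scenario(
    spec: ScenarioSpec,
    weather_source: WeatherSource | Mapping[int, SeasonWeather] | None = None,
    arch: ArchitectureParams = ArchitectureParams(),
    quality: QualityParams = QualityParams(),
    thermal: ThermalParams = ThermalParams(),
) -> AggregateResult:
    """Run one scenario cell over its years and aggregate retained-fruit quality.

    ``weather_source`` is either a mapping year → SeasonWeather or a callable
    ``(year, seed) -> SeasonWeather``; by default the region's tuned synthetic
    climatology is generated per year.  Fully deterministic for a fixed spec.
    """
    preset = REGION_PRESETS[spec.region]
    if weather_source is None:
        weather_source = synthetic_weather_source(preset.site)

    frames = []
    for year in spec.years:
        if isinstance(weather_source, Mapping):
            if year not in weather_source:
                raise ValueError(f"no weather supplied for year {year}")
            weather = weather_source[year]
        else:
            weather = weather_source(year, spec.seed + year)
        mgmt = preset.management(year, spec)
        if mgmt.sowing_date not in weather:
            raise ValueError(
                f"weather for {year} does not cover sowing date {mgmt.sowing_date}"
            )
        plants = run_stand(
            weather, mgmt, n_plants=spec.n_plants,
            arch=arch, quality=quality, thermal=thermal,
            seed=spec.seed + year,
        )
        frame = fruits_to_frame(plants)
        frame.insert(0, "year", year)
        frames.append(frame)

    fruits = pd.concat(frames, ignore_index=True)
    retained = fruits[~fruits.abscised & ~fruits.removed]
    means = {i: float(retained[INDEX_COLUMNS[i]].mean()) for i in INDICES}
    sds = {i: float(retained[INDEX_COLUMNS[i]].std(ddof=1)) for i in INDICES}
    histograms = {
        i: quality_histogram(retained[INDEX_COLUMNS[i]].to_numpy(), default_bin_edges(i))
        for i in INDICES
    }
    return AggregateResult(
        spec=spec,
        fruits=fruits,
        means=means,
        sds=sds,
        n_retained=int(len(retained)),
        profile=cpn_profile(fruits),
        histograms=histograms,
    )


def cpn_profile(fruits: pd.DataFrame) -> pd.DataFrame:
    """Mean quality per cumulative phytomer number over retained fruits.

    Returns one row per CPN with the mean of each index, twice its standard
    error (the error bar convention of per-cohort profiles) and the cohort
    count.
    """
    retained = fruits[~fruits["abscised"] & ~fruits["removed"]]
    if retained.empty:
        raise ValueError("no retained fruits to profile")
    rows = []
    for cpn, grp in retained.groupby("cpn"):
        row: dict[str, float] = {"cpn": int(cpn), "n": int(len(grp))}
        for index, col in INDEX_COLUMNS.items():
            vals = grp[col].to_numpy(dtype=float)
            row[f"{index}_mean"] = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            row[f"{index}_2se"] = 2.0 * se
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cpn").reset_index(drop=True)


def default_bin_edges(index: str) -> np.ndarray:
    """Conventional reporting bins: 5-unit for length/strength, 0.75 for micronaire."""
    if index in ("length", "strength"):
        return np.arange(0.0, 45.0 + 5.0, 5.0)
    if index == "micronaire":
        return np.arange(0.0, 7.5 + 0.75, 0.75)
    raise KeyError(f"unknown quality index {index!r}")


def quality_histogram(
    values: np.ndarray, bin_edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of a quality index over fruits; conserves the total count.

    Values below the first or above the last edge are collected into the
    first/last bin respectively, so counts always sum to ``len(values)``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be a 1-D strictly increasing array")
    vals = np.asarray(values, dtype=float)
    counts, _ = np.histogram(np.clip(vals, edges[0], np.nextafter(edges[-1], -np.inf)), bins=edges)
    return counts, edges


def sweep_frame(results: list[AggregateResult]) -> pd.DataFrame:
    """Tidy table of a sweep: one row per scenario cell × index × statistic."""
    rows = []
    for res in results:
        s = res.spec
        for index in INDICES:
            for stat, value in (("mean", res.means[index]), ("sd", res.sds[index])):
                rows.append(
                    {
                        "region": s.region,
                        "sowing_offset": s.sowing_offset,
                        "main_topping_offset": s.main_topping_offset,
                        "branch_topping_offset": s.branch_topping_offset,
                        "mulch": s.mulch,
                        "index": index,
                        "statistic": stat,
                        "value": value,
                        "n_retained": res.n_retained,
                    }
                )
    return pd.DataFrame(rows)
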