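"""Whole-season simulation of one or more plants and per-fruit output tables."""

from __future__ import annotations

import datetime as dt

import pandas as pd

from .architecture import (
    ArchitectureParams,
    ManagementParams,
    PlantState,
    advance_plant,
)
from .fibre_quality import QualityParams
from .thermal import ThermalParams
from .weather import SeasonWeather, apply_film_mulch

__all__ = ["run_season", "run_stand", "fruits_to_frame"]


def run_season(
    weather: SeasonWeather,
    mgmt: ManagementParams,
    arch: ArchitectureParams = ArchitectureParams(),
    quality: QualityParams = QualityParams(),
    thermal: ThermalParams = ThermalParams(),
    seed: int = 0,
    plant_id: int = 0,
    end_date: dt.date | None = None,
) -> PlantState:
    """Simulate one plant from sowing to ``end_date`` (default: series end).

    If film mulch is applied, the mulch-adjusted weather drives both the
    physiological clock and the quality reduction factors.
    """
    if mgmt.sowing_date not in weather:
        raise ValueError(f"sowing date {mgmt.sowing_date} outside weather series")
    end = end_date or weather.end
    season = weather.slice(mgmt.sowing_date, end)
    if mgmt.film_mulch and mgmt.mulch_delta > 0:
        season = apply_film_mulch(
            season,
            mgmt.mulch_delta,
            mgmt.sowing_date,
            min(mgmt.mulch_end, season.end),
        )
    plant = PlantState(plant_id=plant_id)
    for day in season:
        advance_plant(plant, day, mgmt, arch, quality, thermal, seed=seed)
    return plant


def run_stand(
    weather: SeasonWeather,
    mgmt: ManagementParams,
    n_plants: int = 6,
    arch: ArchitectureParams = ArchitectureParams(),
    quality: QualityParams = QualityParams(),
    thermal: ThermalParams = ThermalParams(),
    seed: int = 0,
    end_date: dt.date | None = None,
) -> list[PlantState]:
    """Simulate ``n_plants`` plants under identical weather and management.

    Plants differ only in their abscission random streams (keyed by plant id).
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    return [
        run_season(
            weather, mgmt, arch, quality, thermal,
            seed=seed, plant_id=pid, end_date=end_date,
        )
        for pid in range(n_plants)
    ]


def fruits_to_frame(plants: list[PlantState] | PlantState) -> pd.DataFrame:
    """Per-fruit results table (one row per initiated fruit, all fates)."""
    if isinstance(plants, PlantState):
        plants = [plants]
    rows = []
    for plant in plants:
        for f in plant.fruits:
            rows.append(
                {
                    "plant_id": f.plant_id,
                    "branch_rank": f.branch_rank,
                    "node": f.node_on_branch,
                    "cpn": f.cpn,
                    "squaring_date": f.squaring_date,
                    "final_stage": f.stage,
                    "abscised": f.abscised,
                    "removed": f.removed,
                    "length_mm": f.quality.actual["length"],
                    "strength_cN_tex": f.quality.actual["strength"],
                    "micronaire": f.quality.actual["micronaire"],
                }
            )
    columns = [
        "plant_id", "branch_rank", "node", "cpn", "squaring_date",
        "final_stage", "abscised", "removed",
        "length_mm", "strength_cN_tex", "micronaire",
    ]
    return pd.DataFrame(rows, columns=columns)


INDEX_COLUMNS = {
    "length": "length_mm",
    "strength": "strength_cN_tex",
    "micronaire": "micronaire",
}
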