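"""Plant architecture: phytomer appearance, fruit cohorts, topping, abscission.

The plant is represented as a main stem of phytomers appearing at a fixed
plastochron (in physiological days), each phytomer above a configurable rank
bearing a fruiting branch with a small number of fruiting nodes.  A fruit's
position is summarised by its cumulative phytomer number (CPN): the phytomer
count from the cotyledon node along the main stem to the subtending branch,
plus its node rank along the branch.  Organs sharing a CPN appear
simultaneously and therefore form a same-age cohort — the model clocks every
organ's appearance as ``emergence_lag + (CPN − 1) × plastochron``.

Topping (manual apex removal) terminates phytomer appearance on the affected
axes and removes the top two phytomers, per common farm practice.  Fruit
abscission is an age-dependent daily Bernoulli event with a per-fruit random
stream, so a given fruit's fate is reproducible and invariant across
management scenarios sharing a seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

from .fibre_quality import INDICES, QualityParams, QualityState
from .thermal import PhysiologicalClock, ThermalParams, daily_temperature_effect
from .weather import WeatherDay

__all__ = [
    "STAGES",
    "Phytomer",
    "FruitRecord",
    "PlantState",
    "ManagementParams",
    "ArchitectureParams",
    "plastochron",
    "assign_cpn",
    "stage_transition",
    "abscission_probability",
    "abscission_step",
    "apply_topping",
    "advance_plant",
]

STAGES = ("square", "flower", "boll", "open-boll")


@dataclass
class Phytomer:
    """One repeating structural unit on an axis."""

    rank_on_axis: int
    axis: str | int  # "main" or the subtending main-stem rank of the branch
    appearance_clock: float  # plant physiological days at appearance


@dataclass
class FruitRecord:
    """One fruit (square → flower → boll → open boll) and its fibre state."""

    plant_id: int
    branch_rank: int
    node_on_branch: int
    cpn: int
    squaring_clock: float  # plant physiological days at squaring
    squaring_date: dt.date
    age: float = 0.0  # physiological days since squaring
    stage: str = "square"
    abscised: bool = False
    removed: bool = False  # cut off by topping
    quality: QualityState = field(default_factory=QualityState)
    open_date: dt.date | None = None
    abscission_date: dt.date | None = None
    rng: np.random.Generator | None = None

    @property
    def alive(self) -> bool:
        return not (self.abscised or self.removed)

    @property
    def growing(self) -> bool:
        """Still accumulating age and fibre quality."""
        return self.alive and self.stage != "open-boll"


@dataclass
class ManagementParams:
    """Agronomic management for one season."""

    sowing_date: dt.date
    main_topping_date: dt.date | None = None
    branch_topping_date: dt.date | None = None
    density: float = 6.0  # plants m⁻²
    mc_applied: bool = False  # mepiquat chloride growth regulator
    film_mulch: bool = False
    mulch_delta: float = 2.0  # °C added to Tmin/Tmax while mulched
    mulch_duration_days: int = 60  # calendar days of mulch effect after sowing

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.main_topping_date is not None and self.main_topping_date <= self.sowing_date:
            raise ValueError("main topping must fall after sowing")
        if (
            self.main_topping_date is not None
            and self.branch_topping_date is not None
            and self.branch_topping_date < self.main_topping_date
        ):
            raise ValueError("branch topping must not precede main-stem topping")

    @property
    def mulch_end(self) -> dt.date:
        return self.sowing_date + dt.timedelta(days=self.mulch_duration_days)


@dataclass
class ArchitectureParams:
    """Structural and developmental constants (config-overridable).

    Plastochron map and the abscission table are placeholders in the spirit
    of the upstream process-based parameterisation, not authoritative values;
    both are plain config data.
    """

    plastochron_min: float = 3.0  # pd, at/below density_lo
    plastochron_max: float = 3.5  # pd, at/above density_hi
    density_lo: float = 0.75  # plants m⁻²
    density_hi: float = 6.0  # plants m⁻²
    mc_plastochron_delta: float = 0.25  # pd added when MC applied (capped)
    emergence_lag: float = 8.0  # pd from sowing to first phytomer
    first_branch_rank: int = 7  # main-stem rank bearing the first fruiting branch
    nodes_per_branch: int = 3
    squaring_lag: float = 0.0  # pd from node appearance to squaring
    square_to_flower: float = 23.0  # pd
    flower_duration: float = 3.0  # pd in the flower stage
    flower_to_open: float = 50.0  # pd from flowering to boll opening
    # (age_upper_bound, daily probability) pairs, ascending; last row is open-ended.
    abscission_table: tuple[tuple[float, float], ...] = (
        (10.0, 0.005),
        (23.0, 0.010),
        (33.0, 0.020),
        (math.inf, 0.002),
    )

    @property
    def open_age(self) -> float:
        """Fruit age at boll opening (pd after squaring)."""
        return self.square_to_flower + self.flower_to_open


@dataclass
class PlantState:
    """Topology, fruit inventory and physiological clock of one plant."""

    plant_id: int
    main_stem: list[Phytomer] = field(default_factory=list)
    branches: dict[int, list[Phytomer]] = field(default_factory=dict)
    fruits: list[FruitRecord] = field(default_factory=list)
    main_apex_active: bool = True
    branch_apices_active: bool = True
    clock: PhysiologicalClock = field(default_factory=PhysiologicalClock)
    emerged: bool = False
    last_date: dt.date | None = None
    # per-branch cap on node count once branches are topped
    _branch_node_caps: dict[int, int] = field(default_factory=dict)
    # nodes that have appeared but whose square has not yet emerged
    _pending_squares: list[tuple[int, int, int, float]] = field(default_factory=list)

    def fruit_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STAGES}
        counts["abscised"] = 0
        counts["removed"] = 0
        for f in self.fruits:
            if f.removed:
                counts["removed"] += 1
            elif f.abscised:
                counts["abscised"] += 1
            else:
                counts[f.stage] += 1
        return counts

    def retained_fruits(self) -> list[FruitRecord]:
        """Fruits neither abscised nor removed by topping."""
        return [f for f in self.fruits if f.alive]


def plastochron(
    density: float, mc_applied: bool, params: ArchitectureParams = ArchitectureParams()
) -> float:
    """Phytomer-appearance interval (physiological days).

    Linear in log(density) between the low- and high-density anchors, clamped
    to [plastochron_min, plastochron_max]; applying the growth regulator MC
    slows development, adding a fixed increment (capped at the maximum).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    span = math.log(params.density_hi / params.density_lo)
    frac = math.log(density / params.density_lo) / span
    frac = min(1.0, max(0.0, frac))
    p = params.plastochron_min + frac * (params.plastochron_max - params.plastochron_min)
    if mc_applied:
        p = min(params.plastochron_max, p + params.mc_plastochron_delta)
    return p


def assign_cpn(branch_rank: int, node_on_branch: int, plant: PlantState | None = None) -> int:
    """Cumulative phytomer number of a fruit position.

    Counts phytomers from the cotyledon node up the main stem to the
    subtending branch (= ``branch_rank``), then along the branch to the fruit
    node.
    """
    if branch_rank < 1 or node_on_branch < 1:
        raise ValueError("branch_rank and node_on_branch must be >= 1")
    if plant is not None:
        nodes = plant.branches.get(branch_rank)
        if nodes is None or node_on_branch > len(nodes):
            raise KeyError(
                f"no node {node_on_branch} on branch at rank {branch_rank}"
            )
    return branch_rank + node_on_branch


def stage_transition(fruit: FruitRecord, params: ArchitectureParams) -> FruitRecord:
    """Advance the fruit's stage according to its physiological age.

    square → flower at ``square_to_flower``; flower → boll after
    ``flower_duration`` more; boll → open-boll at
    ``square_to_flower + flower_to_open``.  Open-boll is absorbing.
    """
    if not fruit.alive or fruit.stage == "open-boll":
        return fruit
    if fruit.age >= params.open_age:
        fruit.stage = "open-boll"
    elif fruit.age >= params.square_to_flower + params.flower_duration:
        fruit.stage = "boll"
    elif fruit.age >= params.square_to_flower:
        fruit.stage = "flower"
    else:
        fruit.stage = "square"
    return fruit


def abscission_probability(age: float, params: ArchitectureParams) -> float:
    """Daily abscission probability for a fruit of the given age."""
    for upper, p in params.abscission_table:
        if age < upper:
            return p
    return params.abscission_table[-1][1]


def abscission_step(
    fruit: FruitRecord, params: ArchitectureParams, date: dt.date | None = None
) -> FruitRecord:
    """One daily Bernoulli abscission trial on a growing fruit.

    Open bolls and already-abscised or removed fruits are left untouched.
    Uses the fruit's own random stream for scenario-invariant reproducibility.
    """
    if not fruit.growing:
        return fruit
    p = abscission_probability(fruit.age, params)
    if p > 0 and fruit.rng is not None and fruit.rng.random() < p:
        fruit.abscised = True
        fruit.abscission_date = date
    elif p >= 1.0:
        fruit.abscised = True
        fruit.abscission_date = date
    return fruit


def _remove_top_phytomers(plant: PlantState, axis_key: str | int, n: int = 2) -> None:
    if axis_key == "main":
        axis = plant.main_stem
    else:
        axis = plant.branches.get(axis_key, [])
    removed = axis[-n:] if len(axis) >= n else axis[:]
    del axis[len(axis) - len(removed):]
    removed_ranks = {p.rank_on_axis for p in removed}
    # only unset fruits (squares, flowers) are discarded with the cut
    # phytomers; bolls already set are harvested regardless
    unset = ("square", "flower")
    if axis_key == "main":
        # branches subtended by removed main-stem phytomers go with them
        for r in list(plant.branches):
            if r in removed_ranks:
                del plant.branches[r]
        for f in plant.fruits:
            if f.alive and f.branch_rank in removed_ranks and f.stage in unset:
                f.removed = True
    else:
        for f in plant.fruits:
            if (
                f.alive
                and f.branch_rank == axis_key
                and f.node_on_branch in removed_ranks
                and f.stage in unset
            ):
                f.removed = True


def apply_topping(plant: PlantState, which: str) -> PlantState:
    """Top the main stem or all fruiting branches.

    Removes the apex and the top two phytomers of each affected axis (fewer
    if fewer exist); fruits on removed phytomers are cut off with them.
    Repeat topping of an already-topped axis is a no-op.
    """
    if which == "main-stem":
        if plant.main_apex_active:
            plant.main_apex_active = False
            _remove_top_phytomers(plant, "main", 2)
    elif which == "branches":
        if plant.branch_apices_active:
            plant.branch_apices_active = False
            for rank in list(plant.branches):
                _remove_top_phytomers(plant, rank, 2)
                plant._branch_node_caps[rank] = len(plant.branches[rank])
    else:
        raise ValueError("which must be 'main-stem' or 'branches'")
    return plant


def _fruit_rng(seed: int, plant_id: int, branch_rank: int, node: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, plant_id, branch_rank, node])
    )


def _organ_threshold(cpn: int, plast: float, params: ArchitectureParams) -> float:
    """Plant physiological-day reading at which the organ of a given CPN appears."""
    return params.emergence_lag + (cpn - 1) * plast


def advance_plant(
    plant: PlantState,
    day: WeatherDay,
    mgmt: ManagementParams,
    arch: ArchitectureParams = ArchitectureParams(),
    quality: QualityParams = QualityParams(),
    thermal: ThermalParams = ThermalParams(),
    seed: int = 0,
) -> PlantState:
    """Advance one plant by one day of weather.

    The daily order of events is: calendar topping events; physiological
    clock advance; organ appearance (main-stem phytomers, branch nodes, new
    squares); fruit ageing and fibre-quality accumulation; stage
    transitions; abscission trials.
    """
    if plant.last_date is not None and day.date <= plant.last_date:
        raise ValueError(f"day {day.date} does not follow {plant.last_date}")
    plant.last_date = day.date

    if mgmt.main_topping_date is not None and day.date == mgmt.main_topping_date:
        apply_topping(plant, "main-stem")
    if mgmt.branch_topping_date is not None and day.date == mgmt.branch_topping_date:
        apply_topping(plant, "branches")

    effect = daily_temperature_effect(day.t_mean, thermal)
    plant.clock.accumulate(effect)
    now = plant.clock.accumulated_days

    if not plant.emerged and now >= arch.emergence_lag:
        plant.emerged = True

    plast = plastochron(mgmt.density, mgmt.mc_applied, arch)

    if plant.emerged:
        # main-stem phytomers: rank r appears when the clock reaches
        # emergence_lag + (r − 1)·plastochron
        while plant.main_apex_active:
            next_rank = len(plant.main_stem) + 1
            if now < _organ_threshold(next_rank, plast, arch):
                break
            plant.main_stem.append(Phytomer(next_rank, "main", now))
            if next_rank >= arch.first_branch_rank:
                plant.branches[next_rank] = []

        # branch fruiting nodes appear in CPN order (cohorts of equal CPN
        # appear simultaneously) while branch apices are active
        if plant.branch_apices_active:
            for rank, nodes in plant.branches.items():
                cap = plant._branch_node_caps.get(rank, arch.nodes_per_branch)
                while len(nodes) < cap:
                    node = len(nodes) + 1
                    cpn = assign_cpn(rank, node)
                    if now < _organ_threshold(cpn, plast, arch):
                        break
                    nodes.append(Phytomer(node, rank, now))
                    squaring_clock = (
                        _organ_threshold(cpn, plast, arch) + arch.squaring_lag
                    )
                    plant._pending_squares.append((rank, node, cpn, squaring_clock))

        # squares emerge once the clock passes node appearance + squaring lag,
        # provided the node still exists (not cut off by topping meanwhile)
        still_pending: list[tuple[int, int, int, float]] = []
        for rank, node, cpn, squaring_clock in plant._pending_squares:
            nodes = plant.branches.get(rank)
            if nodes is None or node > len(nodes):
                continue
            if now >= squaring_clock:
                plant.fruits.append(
                    FruitRecord(
                        plant_id=plant.plant_id,
                        branch_rank=rank,
                        node_on_branch=node,
                        cpn=cpn,
                        squaring_clock=squaring_clock,
                        squaring_date=day.date,
                        age=now - squaring_clock,
                        rng=_fruit_rng(seed, plant.plant_id, rank, node),
                    )
                )
            else:
                still_pending.append((rank, node, cpn, squaring_clock))
        plant._pending_squares = still_pending

    # fruit ageing + fibre accumulation
    for fruit in plant.fruits:
        if not fruit.growing:
            continue
        if fruit.squaring_date == day.date:
            # appeared mid-day: quality accrues over its partial first-day age
            age_before, age_after = 0.0, fruit.age
        else:
            age_before = fruit.age
            age_after = fruit.age + effect
            fruit.age = age_after
        if age_after > age_before:
            fruit.quality.update(age_before, age_after, day, quality)
        stage_transition(fruit, arch)
        if fruit.stage == "open-boll" and fruit.open_date is None:
            fruit.open_date = day.date
        else:
            abscission_step(fruit, arch, day.date)

    return plant
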