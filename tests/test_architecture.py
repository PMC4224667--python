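import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cottonfibre.architecture import (
    ArchitectureParams,
    FruitRecord,
    ManagementParams,
    Phytomer,
    PlantState,
    abscission_probability,
    abscission_step,
    advance_plant,
    apply_topping,
    assign_cpn,
    plastochron,
    stage_transition,
)
from cottonfibre.simulate import fruits_to_frame, run_season
from cottonfibre.weather import WeatherDay

from conftest import make_constant_weather


def make_fruit(age=0.0, stage="square", seed=0, **kw):
    rng = np.random.default_rng(seed)
    return FruitRecord(
        plant_id=0, branch_rank=7, node_on_branch=1, cpn=8,
        squaring_clock=30.0, squaring_date=dt.date(2000, 6, 15),
        age=age, stage=stage, rng=rng, **kw,
    )


class TestPlastochron:
    def test_reference_density_without_mc(self):
        assert plastochron(6.0, False) == pytest.approx(3.5)

    @given(density=st.floats(0.01, 100), mc=st.booleans())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_always_within_range(self, density, mc):
        assert 3.0 <= plastochron(density, mc) <= 3.5

    @given(density=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mc_never_accelerates_development(self, density):
        assert plastochron(density, True) >= plastochron(density, False)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            plastochron(0.0, False)


class TestCpn:
    def test_first_node_of_first_branch(self):
        arch = ArchitectureParams()
        r0 = arch.first_branch_rank
        assert assign_cpn(r0, 1) == r0 + 1

    def test_adjacent_nodes_differ_by_one(self):
        assert assign_cpn(9, 3) - assign_cpn(9, 2) == 1

    def test_unknown_position_rejected(self):
        plant = PlantState(plant_id=0)
        plant.branches[7] = [Phytomer(1, 7, 30.0)]
        with pytest.raises(KeyError):
            assign_cpn(7, 2, plant)
        with pytest.raises(KeyError):
            assign_cpn(8, 1, plant)

    def test_equal_cpn_fruits_share_squaring_clock(self, optimal_weather):
        mgmt = ManagementParams(sowing_date=optimal_weather.start, density=6.0)
        plant = run_season(optimal_weather, mgmt, seed=0)
        clocks = {}
        for f in plant.fruits:
            clocks.setdefault(f.cpn, set()).add(f.squaring_clock)
        assert clocks, "season produced no fruits"
        assert all(len(v) == 1 for v in clocks.values())


class TestStageTransition:
    def test_young_fruit_is_square(self):
        arch = ArchitectureParams()
        f = make_fruit(age=10.0)
        assert stage_transition(f, arch).stage == "square"

    def test_age_80_with_default_thresholds_is_open(self):
        arch = ArchitectureParams()  # flowering at 23, opening at 23 + 50 = 73
        f = make_fruit(age=80.0)
        assert stage_transition(f, arch).stage == "open-boll"

    def test_stage_order_and_boundaries(self):
        arch = ArchitectureParams()
        expectations = [
            (22.9, "square"), (23.0, "flower"),
            (26.0, "boll"), (72.9, "boll"), (73.0, "open-boll"),
        ]
        for age, stage in expectations:
            assert stage_transition(make_fruit(age=age), arch).stage == stage

    def test_open_boll_is_absorbing(self):
        arch = ArchitectureParams()
        f = make_fruit(age=80.0, stage="open-boll")
        f.age = 5.0  # even a bogus age rollback cannot reopen development
        assert stage_transition(f, arch).stage == "open-boll"


class TestAbscission:
    def test_all_zero_table_never_abscises(self):
        arch = ArchitectureParams(abscission_table=((math.inf, 0.0),))
        f = make_fruit()
        for _ in range(500):
            abscission_step(f, arch)
            f.age += 0.5
        assert not f.abscised

    def test_probability_one_abscises_immediately(self):
        arch = ArchitectureParams(abscission_table=((math.inf, 1.0),))
        f = make_fruit()
        abscission_step(f, arch)
        assert f.abscised

    def test_open_boll_never_abscises(self):
        arch = ArchitectureParams(abscission_table=((math.inf, 1.0),))
        f = make_fruit(age=80.0, stage="open-boll")
        abscission_step(f, arch)
        assert not f.abscised

    def test_monte_carlo_matches_analytic_survival(self):
        """Empirical retention over 1000 fruits vs the survival product."""
        arch = ArchitectureParams()
        n_days = 73
        survival = 1.0
        for a in range(n_days):
            survival *= 1.0 - abscission_probability(float(a), arch)
        retained = 0
        for i in range(1000):
            f = make_fruit(seed=i)
            for a in range(n_days):
                f.age = float(a)
                abscission_step(f, arch)
                if f.abscised:
                    break
            retained += not f.abscised
        sd = math.sqrt(1000 * survival * (1.0 - survival))
        assert abs(retained - 1000 * survival) <= 3 * sd


class TestTopping:
    def build_plant(self, n_main=15, n_branches=0, nodes=0):
        plant = PlantState(plant_id=0)
        plant.main_stem = [Phytomer(r, "main", r * 3.5) for r in range(1, n_main + 1)]
        for b in range(7, 7 + n_branches):
            plant.branches[b] = [Phytomer(n, b, 0.0) for n in range(1, nodes + 1)]
        return plant

    def test_main_topping_removes_top_two_and_stops_apex(self):
        plant = self.build_plant(n_main=15)
        apply_topping(plant, "main-stem")
        assert len(plant.main_stem) == 13
        assert not plant.main_apex_active

    def test_repeat_topping_is_noop(self):
        plant = self.build_plant(n_main=15)
        apply_topping(plant, "main-stem")
        apply_topping(plant, "main-stem")
        assert len(plant.main_stem) == 13

    def test_branch_topping_trims_every_branch(self):
        plant = self.build_plant(n_main=20, n_branches=10, nodes=4)
        apply_topping(plant, "branches")
        assert all(len(nodes) == 2 for nodes in plant.branches.values())
        assert not plant.branch_apices_active

    def test_single_phytomer_axis_removes_what_exists(self):
        plant = self.build_plant(n_main=1)
        apply_topping(plant, "main-stem")
        assert plant.main_stem == []

    def test_fruits_on_removed_phytomers_are_cut(self):
        plant = self.build_plant(n_main=15, n_branches=5, nodes=3)
        # fruit on the branch subtended by main-stem rank 14 (to be removed)
        plant.fruits.append(make_fruit())
        plant.fruits[-1].branch_rank = 14
        apply_topping(plant, "main-stem")
        assert plant.fruits[-1].removed
        assert 14 not in plant.branches


class TestAdvancePlant:
    def test_cold_day_advances_nothing_but_calendar(self):
        plant = PlantState(plant_id=0)
        mgmt = ManagementParams(sowing_date=dt.date(2000, 4, 1))
        day = WeatherDay(dt.date(2000, 4, 1), 4.0, 12.0)  # t_mean 8 < base
        advance_plant(plant, day, mgmt)
        assert plant.clock.accumulated_days == 0.0
        assert plant.main_stem == [] and plant.fruits == []
        assert plant.last_date == day.date

    def test_out_of_order_day_rejected(self):
        plant = PlantState(plant_id=0)
        mgmt = ManagementParams(sowing_date=dt.date(2000, 4, 1))
        day = WeatherDay(dt.date(2000, 4, 2), 20.0, 30.0)
        advance_plant(plant, day, mgmt)
        with pytest.raises(ValueError):
            advance_plant(plant, day, mgmt)

    def test_phytomer_count_at_constant_optimum(self):
        """35 optimal days at plastochron 3.5 add floor(35/3.5) = 10 phytomers."""
        arch = ArchitectureParams(emergence_lag=0.0)
        w = make_constant_weather(20.0, 30.0, n_days=35)
        mgmt = ManagementParams(sowing_date=w.start, density=6.0)  # plastochron 3.5
        plant = run_season(w, mgmt, arch=arch)
        # initial phytomer (threshold 0) + 10 from 35 physiological days
        assert len(plant.main_stem) == 10 + 1

    def test_no_main_growth_after_topping(self, optimal_weather):
        mgmt = ManagementParams(
            sowing_date=optimal_weather.start,
            main_topping_date=optimal_weather.start + dt.timedelta(days=60),
            density=6.0,
        )
        plant = PlantState(plant_id=0)
        counts = []
        for day in optimal_weather:
            advance_plant(plant, day, mgmt)
            counts.append(len(plant.main_stem))
        topped_idx = 60
        assert max(counts[topped_idx:]) == counts[topped_idx]

    def test_fruit_conservation_every_day(self, cold_autumn_weather):
        mgmt = ManagementParams(
            sowing_date=dt.date(2000, 4, 15),
            main_topping_date=dt.date(2000, 7, 20),
            branch_topping_date=dt.date(2000, 8, 15),
            density=6.0,
        )
        season = cold_autumn_weather.slice(mgmt.sowing_date, cold_autumn_weather.end)
        plant = PlantState(plant_id=0)
        for day in season:
            advance_plant(plant, day, mgmt, seed=3)
            counts = plant.fruit_counts()
            alive = sum(counts[s] for s in ("square", "flower", "boll", "open-boll"))
            assert alive + counts["abscised"] + counts["removed"] == len(plant.fruits)

    def test_no_ageing_after_abscission_or_opening(self, optimal_weather):
        mgmt = ManagementParams(sowing_date=optimal_weather.start, density=6.0)
        plant = run_season(optimal_weather, mgmt, seed=1)
        frozen = {}
        for f in plant.fruits:
            if f.abscised or f.stage == "open-boll":
                frozen[id(f)] = (f.age, dict(f.quality.actual))
        day = WeatherDay(optimal_weather.end + dt.timedelta(days=1), 20.0, 30.0)
        advance_plant(plant, day, mgmt, seed=1)
        for f in plant.fruits:
            if id(f) in frozen:
                age0, q0 = frozen[id(f)]
                assert f.age == age0
                assert f.quality.actual == q0

    def test_hand_computed_timeline_at_constant_optimum(self):
        """Event dates under E(T) ≡ 1 match the closed-form thresholds."""
        arch = ArchitectureParams()  # emergence 8 pd, plastochron 3.5 at density 6
        w = make_constant_weather(20.0, 30.0, start=dt.date(2000, 5, 1), n_days=80)
        mgmt = ManagementParams(sowing_date=w.start, density=6.0)
        plant = PlantState(plant_id=0)
        for day in w:
            advance_plant(plant, day, mgmt, arch=arch)
        # phytomer rank r appears once clock >= 8 + (r-1)*3.5; clock = day count
        for phy in plant.main_stem:
            threshold = 8 + (phy.rank_on_axis - 1) * 3.5
            assert phy.appearance_clock == math.ceil(threshold)
        # first fruit: branch rank 7 node 1, CPN 8, squares at clock 8 + 7*3.5 = 32.5
        first = min(plant.fruits, key=lambda f: f.cpn)
        assert (first.branch_rank, first.node_on_branch, first.cpn) == (7, 1, 8)
        assert first.squaring_clock == 32.5
        assert first.squaring_date == dt.date(2000, 5, 1) + dt.timedelta(days=32)

    def test_earlier_topping_never_yields_more_phytomers(self, optimal_weather):
        def final_count(top_day):
            mgmt = ManagementParams(
                sowing_date=optimal_weather.start,
                main_topping_date=optimal_weather.start + dt.timedelta(days=top_day),
                density=6.0,
            )
            return len(run_season(optimal_weather, mgmt, seed=0).main_stem)

        counts = [final_count(d) for d in (40, 60, 80, 100)]
        assert counts == sorted(counts)
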