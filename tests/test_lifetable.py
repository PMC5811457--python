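"""Schedule construction, trait extraction and mortality summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoichdemo.config import DesignConfig
from stoichdemo.lifetable import (
    build_schedule,
    extract_traits,
    mortality_summary,
    traits_table,
)
from stoichdemo.records import EggEvent, IndividualRecord
from stoichdemo.simulate import simulate_individuals

from conftest import noiseless


def record(ind="x", end=50.0, reason="censored_horizon", eggs=()):
    return IndividualRecord(
        individual_id=ind, clone="D12", treatment="HP",
        chemostat_replicate="chemo1", birth_time=0.0,
        end_time=end, end_reason=reason,
        eggs=[EggEvent(*e) for e in eggs],
    )


class TestBuildSchedule:
    def test_single_neonate_in_class_five(self):
        # 10 survivors, each one neonate hatching in the fifth class [8,10)
        recs = [
            record(f"i{k}", end=20.0, eggs=((1, 2.0, "hatched", 8.0),))
            for k in range(10)
        ]
        sched = build_schedule(recs, age_class_width=2.0)
        assert np.all(sched.lx == 1.0)
        assert sched.mx[4] == 1.0
        assert sched.mx.sum() == 1.0

    def test_one_death_entering_class_three(self):
        # death at age 4 h = start of the third 2-h class
        recs = [record(f"i{k}", end=10.0) for k in range(3)]
        recs.append(record("dead", end=4.0, reason="death"))
        sched = build_schedule(recs, age_class_width=2.0)
        assert list(sched.lx[:3]) == [1.0, 1.0, 0.75]

    def test_censoring_leaves_risk_set_without_death(self):
        recs = [record(f"i{k}", end=10.0) for k in range(3)]
        recs.append(record("cens", end=4.0, reason="censored_male_egg",
                           eggs=((1, 4.0, "male", 4.0),)))
        sched = build_schedule(recs, age_class_width=2.0)
        assert np.all(sched.lx == 1.0)  # no deaths, censoring is not death

    def test_noiseless_cohort_reproduces_maturation_class(self, params):
        d = DesignConfig(n_chemostat_replicates=2,
                         n_individuals_per_replicate=50)
        p = noiseless(params, "HP", maturation_time_mean=21.0,
                      egg_development_time_mean=11.0)
        recs = simulate_individuals(d, {"HP": p}, seed=0)
        sched = build_schedule(recs, age_class_width=2.0)
        # first hatches observed at 32 h -> class index 16
        first = int(np.nonzero(sched.mx)[0][0])
        assert first == 16
        assert np.all(sched.lx == 1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            build_schedule([], 2.0)
        with pytest.raises(ValueError):
            build_schedule([record(end=10.0)], 0.0)
        with pytest.raises(ValueError):
            build_schedule([record(end=0.0)], 2.0)

    @given(st.lists(
        st.tuples(
            st.booleans(),                                  # died?
            st.floats(min_value=0.5, max_value=100.0),      # end age
            st.integers(min_value=0, max_value=5),          # hatched neonates
        ),
        min_size=1, max_size=30,
    ))
    @settings(max_examples=60, deadline=None)
    def test_lx_bounds_and_monotonicity_hold(self, spec):
        recs = []
        for k, (died, end, n_eggs) in enumerate(spec):
            end = round(end, 3)
            eggs = []
            for j in range(n_eggs):
                lay = round(end * (j + 1) / (n_eggs + 1), 3)
                if lay <= 0:
                    continue
                eggs.append((len(eggs) + 1, lay, "hatched",
                             round(min(end, lay + 1.0), 3)))
            recs.append(record(
                f"i{k}", end=end,
                reason="death" if died else "censored_horizon",
                eggs=tuple(eggs),
            ))
        sched = build_schedule(recs, age_class_width=2.0)
        assert np.all((sched.lx >= 0) & (sched.lx <= 1))
        assert np.all(np.diff(sched.lx) <= 1e-12)
        assert np.all(sched.mx >= 0)

    def test_halving_width_preserves_total_reproduction(self, design, params):
        recs = simulate_individuals(design, params, seed=21)
        hp = [r for r in recs if r.treatment == "HP"]
        wide = build_schedule(hp, 2.0, denominator="initial")
        narrow = build_schedule(hp, 1.0, denominator="initial")
        # initial-cohort mx sums to total neonates per starting individual
        assert wide.mx.sum() * len(hp) == pytest.approx(
            narrow.mx.sum() * len(hp)
        )


class TestExtractTraits:
    def test_two_eggs_rate(self):
        rec = record(eggs=((1, 20.0, "hatched", 32.0), (2, 30.0, "hatched", 42.0)))
        t = extract_traits(rec)
        assert t.age_at_first_egg == 20.0
        assert t.egg_production_rate == pytest.approx(0.2)  # 2 eggs / 10 h

    def test_four_eggs_rate(self):
        eggs = tuple((k + 1, 20.0 + 6 * k, "hatched", 40.0 + 6 * k)
                     for k in range(4))
        t = extract_traits(record(eggs=eggs))
        assert t.egg_production_rate == pytest.approx(4 / 18)

    def test_single_egg_rate_unavailable(self):
        t = extract_traits(record(eggs=((1, 20.0, "hatched", 32.0),)))
        assert t.egg_production_rate is None
        assert t.age_at_first_egg == 20.0

    def test_development_times_per_hatched_egg(self):
        eggs = ((1, 20.0, "hatched", 32.0), (2, 26.0, "died", 38.0))
        t = extract_traits(record(eggs=eggs))
        assert t.development_times == {1: 12.0}
        assert t.eggs_died == 1

    def test_traits_table_shape(self, design, params):
        recs = simulate_individuals(design, params, seed=2)
        df = traits_table(recs)
        assert len(df) == len(recs)
        assert set(df.treatment) == {"HP", "LP", "LP+P"}


class TestMortalitySummary:
    def test_six_deaths_of_75_is_8_percent(self):
        recs = [record(f"i{k}", reason="death" if k < 6 else "censored_horizon")
                for k in range(75)]
        out = mortality_summary(recs)
        assert out.individual_mortality_pct.iloc[0] == 8.0

    def test_three_of_13_resolved_eggs_is_23_1_percent(self):
        eggs = tuple(
            (j + 1, 2.0 + j, "died" if j < 3 else "hatched", 20.0 + j)
            for j in range(13)
        )
        out = mortality_summary([record(eggs=eggs)])
        assert out.egg_mortality_pct.iloc[0] == 23.1

    def test_zero_deaths_is_zero_percent(self):
        out = mortality_summary([record(f"i{k}") for k in range(10)])
        assert out.individual_mortality_pct.iloc[0] == 0.0

    def test_male_and_unresolved_excluded_from_denominator(self):
        eggs = ((1, 2.0, "hatched", 14.0), (2, 4.0, "unresolved", None),
                (3, 6.0, "male", 6.0), (4, 8.0, "died", 20.0))
        out = mortality_summary([record(eggs=eggs)])
        assert out.n_resolved_eggs.iloc[0] == 2
        assert out.egg_mortality_pct.iloc[0] == 50.0

    def test_no_resolved_eggs_flagged_unavailable(self):
        out = mortality_summary([record(eggs=((1, 2.0, "unresolved", None),))])
        assert out.egg_mortality_pct.iloc[0] is None
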