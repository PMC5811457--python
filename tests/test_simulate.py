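"""Generator behaviour: design conservation, observation model, determinism."""

import dataclasses
import math

import numpy as np
import pytest

from stoichdemo.config import ConfigurationError, DesignConfig
from stoichdemo.demography import census_growth_rate
from stoichdemo.records import records_to_events
from stoichdemo.simulate import (
    simulate_census,
    simulate_composition_tables,
    simulate_individuals,
)

from conftest import noiseless


class TestDesignConservation:
    def test_default_life_table_design_has_225_units(self, design, params):
        records = simulate_individuals(design, params, seed=3)
        assert len(records) == 225  # 3 treatments x 5 replicates x 15

    def test_default_census_design_has_45_units(self, design, params):
        series = simulate_census(design, params, seed=3)
        assert len(series) == 45  # 3 clones x 3 treatments x 5 replicates
        assert all(len(s.observations) == design.census_days for s in series)

    def test_composition_tables_match_design(self, design, params):
        morpho, elem, algal = simulate_composition_tables(design, params, seed=3)
        assert len(morpho) == 75   # 3 x 5 x 5 shortened design
        assert len(elem) == 30     # 2 clones x 3 treatments x 5 replicates
        assert len(algal) == 75    # 3 treatments x 5 replicates x 5 occasions

    def test_record_count_scales_with_design(self, params):
        d = DesignConfig(n_chemostat_replicates=2, n_individuals_per_replicate=3)
        assert len(simulate_individuals(d, params, seed=0)) == 2 * 3 * 3

    @pytest.mark.parametrize("field,value", [
        ("n_chemostat_replicates", 0),
        ("observation_interval", 0.0),
        ("census_days", 1),
    ])
    def test_invalid_design_rejected(self, params, field, value):
        d = DesignConfig(**{field: value})
        with pytest.raises(ConfigurationError):
            simulate_individuals(d, params, seed=0)

    def test_unknown_treatment_label_rejected(self, design, params):
        bad = {"XX": dataclasses.replace(params["HP"], treatment_label="XX")}
        with pytest.raises(ConfigurationError):
            simulate_individuals(design, bad, seed=0)


class TestObservationModel:
    def test_event_times_on_observation_grid(self, design, params):
        w = design.observation_interval
        for rec in simulate_individuals(design, params, seed=5):
            times = [rec.end_time] + [e.lay_time for e in rec.eggs]
            times += [e.fate_time for e in rec.eggs if e.fate_time is not None]
            assert all(abs(t / w - round(t / w)) < 1e-9 for t in times)

    def test_event_ordering_invariants(self, design, params):
        for rec in simulate_individuals(design, params, seed=5):
            for egg in rec.eggs:
                assert rec.birth_time < egg.lay_time <= rec.end_time
                if egg.fate_time is not None:
                    assert egg.lay_time <= egg.fate_time <= rec.end_time

    def test_noiseless_individual_reports_means_rounded_up(self, params):
        d = DesignConfig(n_chemostat_replicates=1, n_individuals_per_replicate=1)
        p = noiseless(params, "HP", maturation_time_mean=21.0,
                      inter_egg_interval_mean=4.0,
                      egg_development_time_mean=11.0)
        (rec,) = simulate_individuals(d, {"HP": p}, seed=0)
        # lays at 21, 25, 29, ... observed at the next 2-h check: 22, 26, 30...
        assert [e.lay_time for e in rec.eggs[:4]] == [22.0, 26.0, 30.0, 34.0]
        # hatches at lay + 11 latent -> 32, 36, 40, 44 observed
        hatched = [e.fate_time for e in rec.eggs if e.fate == "hatched"]
        assert hatched[:4] == [32.0, 36.0, 40.0, 44.0]
        assert rec.end_reason == "completed_k_neonates"
        assert rec.end_time == 44.0  # fourth neonate ends monitoring

    def test_lp_monitoring_ends_at_62h_horizon(self, design, params):
        lp = [r for r in simulate_individuals(design, params, seed=8)
              if r.treatment == "LP"]
        assert all(r.end_time <= design.lp_horizon for r in lp)
        assert any(r.end_reason == "censored_horizon" for r in lp)

    def test_male_egg_censors_monitoring(self, params):
        d = DesignConfig(n_chemostat_replicates=2, n_individuals_per_replicate=50)
        p = noiseless(params, "HP", male_egg_prob=0.5)
        recs = simulate_individuals(d, {"HP": p}, seed=2)
        censored = [r for r in recs if r.end_reason == "censored_male_egg"]
        assert censored, "male eggs should occur at this probability"
        for r in censored:
            assert r.eggs[-1].fate == "male"
            assert r.eggs[-1].lay_time == r.end_time

    def test_egg_mortality_matches_configured_probability(self, params):
        # >= 10,000 eggs; binomial 3-sigma Monte-Carlo bound
        d = DesignConfig(n_chemostat_replicates=5,
                         n_individuals_per_replicate=500)
        p = noiseless(params, "HP", egg_mortality_prob=0.231,
                      maturation_time_sd=1.0)
        recs = simulate_individuals(d, {"HP": p}, seed=11)
        resolved = [e for r in recs for e in r.eggs
                    if e.fate in ("hatched", "died")]
        n = len(resolved)
        assert n >= 10_000
        frac = sum(e.fate == "died" for e in resolved) / n
        se = math.sqrt(0.231 * 0.769 / n)
        assert abs(frac - 0.231) <= 3 * se


class TestCensus:
    def test_zero_rate_zero_noise_is_flat(self, params):
        d = DesignConfig(n_clones=1, n_chemostat_replicates=1, census_days=10)
        p = noiseless(params, "HP", census_growth_rate=0.0)
        (s,) = simulate_census(d, {"HP": p}, seed=0)
        assert all(nt == n0 for _, n0, nt in s.observations)
        assert census_growth_rate(s, window=5).r == 0.0

    def test_rate_recovery_within_three_se(self, params):
        d = DesignConfig(n_clones=1, n_chemostat_replicates=5, census_days=22)
        p = noiseless(params, "HP", census_growth_rate=0.5, census_log_sd=0.15)
        series = simulate_census(d, {"HP": p}, seed=4,
                                 clone_rate_offsets={})
        ests = [census_growth_rate(s, window=16).r for s in series]
        se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.5) <= 3 * se


class TestComposition:
    def test_zero_variance_algal_cp_is_exact(self, design, params):
        p = {k: noiseless(params, k) for k in params}
        _, _, algal = simulate_composition_tables(design, p, seed=0)
        hp = algal[algal.treatment == "HP"].molar_cp
        assert (hp == 112.0).all()

    def test_hp_algal_cp_mean_within_three_se(self, design, params):
        _, _, algal = simulate_composition_tables(design, params, seed=9)
        hp = algal[algal.treatment == "HP"].molar_cp
        assert len(hp) == 25
        # generator dispersion implies SE of the 25-batch mean = configured se
        assert abs(hp.mean() - 112.0) <= 3 * params["HP"].algal_cp_se


class TestDeterminism:
    def test_identical_seed_reproduces_everything(self, design, params):
        a = records_to_events(simulate_individuals(design, params, seed=7))
        b = records_to_events(simulate_individuals(design, params, seed=7))
        assert a.equals(b)
        ca = simulate_census(design, params, seed=7)
        cb = simulate_census(design, params, seed=7)
        assert all(x.observations == y.observations for x, y in zip(ca, cb))

    def test_different_seed_differs(self, design, params):
        a = records_to_events(simulate_individuals(design, params, seed=7))
        b = records_to_events(simulate_individuals(design, params, seed=8))
        assert not a.equals(b)

    def test_subsetting_design_preserves_retained_units(self, params):
        big = DesignConfig(n_chemostat_replicates=3, n_individuals_per_replicate=10)
        small = DesignConfig(n_chemostat_replicates=3, n_individuals_per_replicate=4)
        recs_big = {r.individual_id: r for r in
                    simulate_individuals(big, params, seed=13)}
        for r in simulate_individuals(small, params, seed=13):
            assert recs_big[r.individual_id] == r
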