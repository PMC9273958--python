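"""Population layer: hatching, the five mortalities, spawning, the hourly
scheduler and whole-run behaviour."""

import math

import numpy as np
import pytest

from debibm import (Cohort, DEBState, PopulationState, Stage,
                    ageing_mortality, background_mortality, density_mortality,
                    egg_mortality, fish_density, run_simulation,
                    step_population, summarize)
from debibm.deb import embryo_state
from debibm.forcing import ForcingConfig, synthesize_forcings
from debibm.population import (apply_survival, egg_energy, hatch,
                               seed_cohorts, spawn, update_degree_days)


def _egg_cohort(n=1000.0, dd=0.0, E_H=1.0):
    deb = embryo_state(E_0=1.38)
    deb.E_H = E_H  # past the maturity-at-birth threshold unless overridden
    return Cohort(stage=Stage.EGG_LARVA, n=n, deb=deb, dd=dd)


def _adult_cohort(n=1000.0, L=3.0, age=400.0, stage=Stage.FEMALE, E_R=0.0):
    # reserve at its maximum density: energetically comfortable fish
    deb = DEBState(L=L, E=12059.5 * L**3, E_H=5435.0, E_R=E_R, age=age,
                   L_b=0.0428, L_j=0.0841)
    return Cohort(stage=stage, n=n, deb=deb)


class TestDegreeDays:
    def test_no_accumulation_at_or_below_threshold(self, ibm_pars):
        c = _egg_cohort(dd=5.0)
        assert update_degree_days(c, 10.0, 1.0, ibm_pars).dd == 5.0
        assert update_degree_days(c, 8.0, 100.0, ibm_pars).dd == 5.0

    def test_accumulates_excess_above_threshold(self, ibm_pars):
        # at a constant 20 deg C the 51.5 deg C d threshold takes 5.15 d
        c = _egg_cohort(dd=0.0)
        for day in range(6):
            for _ in range(24):
                c = update_degree_days(c, 20.0, 1.0 / 24.0, ibm_pars)
            if day == 4:
                assert c.dd < ibm_pars.DD_min   # 50 deg C d after 5 d
        assert c.dd == pytest.approx(60.0)      # 5.15 d falls inside day 6

    def test_rejects_non_egg_stage(self, ibm_pars):
        with pytest.raises(ValueError):
            update_degree_days(_adult_cohort(), 20.0, 1.0, ibm_pars)


class TestHatch:
    def test_hatching_applies_success_probability(self, ibm_pars):
        c = hatch(_egg_cohort(n=1000.0, dd=51.5), ibm_pars)
        assert c.n == pytest.approx(900.0)
        assert c.stage == Stage.JUVENILE

    def test_below_threshold_nothing_happens(self, ibm_pars):
        c = hatch(_egg_cohort(n=1000.0, dd=51.49), ibm_pars)
        assert c.n == 1000.0
        assert c.stage == Stage.EGG_LARVA

    def test_idempotent_after_hatching(self, ibm_pars):
        c = hatch(_egg_cohort(n=1000.0, dd=60.0), ibm_pars)
        again = hatch(c, ibm_pars)
        assert again.n == c.n == pytest.approx(900.0)


class TestMortalities:
    def test_background_at_zero_anomalies(self, ibm_pars):
        assert background_mortality(0.0, 0.0, ibm_pars) == \
            pytest.approx(9.73e-4)

    def test_background_reduced_by_positive_anomalies(self, ibm_pars):
        assert background_mortality(1.0, 1.0, ibm_pars) == \
            pytest.approx(9.73e-4 - 4.03e-4 - 6.03e-5)

    def test_background_clamped_at_zero(self, ibm_pars):
        assert background_mortality(10.0, 10.0, ibm_pars) == 0.0

    def test_density_half_saturation(self, ibm_pars):
        assert density_mortality(2.2e3, ibm_pars) == pytest.approx(0.0035)

    def test_density_limits(self, ibm_pars):
        assert density_mortality(0.0, ibm_pars) == 0.0
        assert density_mortality(1e12, ibm_pars) == \
            pytest.approx(0.007, rel=1e-6)

    def test_density_monotone(self, ibm_pars):
        grid = np.linspace(0, 1e5, 50)
        z = density_mortality(grid, ibm_pars)
        assert np.all(np.diff(z) > 0)
        assert np.all((z >= 0) & (z < ibm_pars.M_d))

    def test_egg_predation_values(self, ibm_pars):
        assert egg_mortality(2.0e3, ibm_pars) == pytest.approx(0.0415)
        assert egg_mortality(0.0, ibm_pars) == 0.0
        assert egg_mortality(6.0e3, ibm_pars) == pytest.approx(0.06225)

    def test_ageing_threshold_and_slope(self, ibm_pars):
        assert ageing_mortality(730.0, ibm_pars) == 0.0
        assert ageing_mortality(365.0, ibm_pars) == 0.0
        assert ageing_mortality(1095.0, ibm_pars) == pytest.approx(7.3e-4)


class TestApplySurvival:
    def test_no_mortality_no_change(self, ibm_pars):
        c = apply_survival(_adult_cohort(n=1234.0), 0, 0, 0, 0, 0, 1.0)
        assert c.n == 1234.0

    def test_exponential_decay_worked_value(self, ibm_pars):
        c = apply_survival(_adult_cohort(n=1000.0), 0.001, 0, 0, 0, 0, 1.0)
        assert c.n == pytest.approx(1000.0 * math.exp(-0.001))

    def test_semigroup_composition(self, ibm_pars):
        full = apply_survival(_adult_cohort(n=500.0), 0.01, 0.002, 0.003,
                              0.001, 0.0, 2.0)
        half = apply_survival(
            apply_survival(_adult_cohort(n=500.0), 0.01, 0.002, 0.003,
                           0.001, 0.0, 1.0),
            0.01, 0.002, 0.003, 0.001, 0.0, 1.0)
        assert full.n == pytest.approx(half.n, rel=1e-14)

    def test_stage_dependent_rate_selection(self, ibm_pars):
        egg = apply_survival(_egg_cohort(n=1000.0), 0.01, 0.001, 0.005,
                             0.002, 0.04, 1.0)
        assert egg.n == pytest.approx(1000.0 * math.exp(-(0.04 + 0.001)))
        juv = apply_survival(
            Cohort(stage=Stage.JUVENILE, n=1000.0,
                   deb=DEBState(L=1.0, E=1e3, E_H=100.0)),
            0.01, 0.001, 0.005, 0.002, 0.04, 1.0)
        assert juv.n == pytest.approx(
            1000.0 * math.exp(-(0.001 + 0.005 + 0.01)))
        adult = apply_survival(_adult_cohort(n=1000.0), 0.01, 0.001, 0.005,
                               0.002, 0.04, 1.0)
        assert adult.n == pytest.approx(
            1000.0 * math.exp(-(0.001 + 0.005 + 0.002 + 0.01)))

    def test_negative_rate_rejected(self, ibm_pars):
        with pytest.raises(ValueError):
            apply_survival(_adult_cohort(), -0.1, 0, 0, 0, 0, 1.0)


class TestFishDensity:
    def test_empty_population(self, ibm_pars, deb_pars):
        assert fish_density(PopulationState(), ibm_pars, deb_pars) == 0.0

    def test_single_cohort_survey_conversion(self, ibm_pars, deb_pars):
        # one million fish of 140 g on 1000 km^2 -> 140 kg/km^2
        L = (140.0 / deb_pars.d_V) ** (1.0 / 3.0)
        deb = DEBState(L=L, E=0.0, E_H=deb_pars.E_Hp, L_b=0.0428, L_j=0.0841)
        pop = PopulationState.from_cohorts(
            [Cohort(stage=Stage.FEMALE, n=1e6, deb=deb)])
        assert fish_density(pop, ibm_pars, deb_pars) == pytest.approx(140.0)

    def test_linearity_in_abundance(self, ibm_pars, deb_pars):
        single = PopulationState.from_cohorts([_adult_cohort(n=1e5)])
        double = PopulationState.from_cohorts([_adult_cohort(n=2e5)])
        assert fish_density(double, ibm_pars, deb_pars) == pytest.approx(
            2 * fish_density(single, ibm_pars, deb_pars))

    def test_eggs_do_not_contribute(self, ibm_pars, deb_pars):
        pop = PopulationState.from_cohorts([_egg_cohort(n=1e9)])
        assert fish_density(pop, ibm_pars, deb_pars) == 0.0


class TestSpawn:
    def test_insufficient_buffer_produces_no_cohort(self, ibm_pars, deb_pars):
        E_0 = egg_energy(deb_pars)
        pop = PopulationState.from_cohorts(
            [_adult_cohort(E_R=0.5 * E_0 / deb_pars.kappa_R)])
        spawn(pop, T=20.0, date=150.0, pars=ibm_pars, deb_pars=deb_pars)
        assert pop.n_cohorts == 1

    def test_buffer_converts_to_eggs(self, ibm_pars, deb_pars):
        E_0 = egg_energy(deb_pars)
        pop = PopulationState.from_cohorts(
            [_adult_cohort(n=10.0, E_R=100.0 * E_0 / deb_pars.kappa_R)])
        spawn(pop, T=20.0, date=150.0, pars=ibm_pars, deb_pars=deb_pars)
        assert pop.n_cohorts == 2
        egg = pop.cohort(1)
        assert egg.stage == Stage.EGG_LARVA
        assert egg.n == pytest.approx(100.0 * 10.0)
        assert pop.cohort(0).deb.E_R == pytest.approx(0.0, abs=1e-9)

    def test_outside_window_no_change(self, ibm_pars, deb_pars):
        E_0 = egg_energy(deb_pars)
        pop = PopulationState.from_cohorts(
            [_adult_cohort(E_R=100.0 * E_0)])
        spawn(pop, T=20.0, date=10.0, pars=ibm_pars, deb_pars=deb_pars)
        assert pop.n_cohorts == 1

    def test_below_temperature_no_change(self, ibm_pars, deb_pars):
        E_0 = egg_energy(deb_pars)
        pop = PopulationState.from_cohorts(
            [_adult_cohort(E_R=100.0 * E_0)])
        spawn(pop, T=12.0, date=150.0, pars=ibm_pars, deb_pars=deb_pars)
        assert pop.n_cohorts == 1

    def test_males_do_not_spawn(self, ibm_pars, deb_pars):
        E_0 = egg_energy(deb_pars)
        pop = PopulationState.from_cohorts(
            [_adult_cohort(E_R=100.0 * E_0, stage=Stage.MALE)])
        spawn(pop, T=20.0, date=150.0, pars=ibm_pars, deb_pars=deb_pars)
        assert pop.n_cohorts == 1


class TestSummarize:
    def test_single_cohort_mean_age(self, ibm_pars, deb_pars):
        pop = PopulationState.from_cohorts([_adult_cohort(age=365.0)])
        rec = summarize(pop, deb_pars, ibm_pars)
        assert rec.mean_age == pytest.approx(1.0)

    def test_abundance_weighted_mean_age(self, ibm_pars, deb_pars):
        pop = PopulationState.from_cohorts([
            _adult_cohort(n=100.0, age=365.0),
            _adult_cohort(n=300.0, age=730.0)])
        rec = summarize(pop, deb_pars, ibm_pars)
        assert rec.mean_age == pytest.approx(1.75)

    def test_stage_counts_sum_to_post_egg_total(self, ibm_pars, deb_pars):
        pop = PopulationState.from_cohorts([
            _egg_cohort(n=5000.0), _adult_cohort(n=100.0),
            _adult_cohort(n=50.0, stage=Stage.MALE)])
        rec = summarize(pop, deb_pars, ibm_pars)
        assert rec.n_juv + rec.n_female + rec.n_male == \
            pytest.approx(rec.total_abundance)
        assert rec.n_egg == 5000.0

    def test_biomass_equals_fish_density(self, ibm_pars, deb_pars):
        pop = PopulationState.from_cohorts([_adult_cohort(n=1e5)])
        rec = summarize(pop, deb_pars, ibm_pars)
        assert rec.biomass_density == pytest.approx(
            fish_density(pop, ibm_pars, deb_pars))

    def test_empty_population_gives_zeros(self, ibm_pars, deb_pars):
        rec = summarize(PopulationState(), deb_pars, ibm_pars)
        assert rec.total_abundance == 0.0
        assert rec.mean_age == 0.0
        assert rec.biomass_density == 0.0


class TestStepPopulation:
    def test_conservation_without_mortality_or_spawning(
            self, short_forcings, ibm_pars, deb_pars):
        quiet = ibm_pars.replace(M_egg=0.0, M_d=0.0, M_cm=0.0, M_flow=0.0,
                                 M_rain=0.0, e_age=0.0,
                                 spawn_window=(1, 1), spawn_T_min=99.0)
        pop = PopulationState.from_cohorts([_adult_cohort(n=1000.0)])
        forcings = short_forcings
        zero_f = type(forcings)(**{**forcings.__dict__,
                                   "Z_F_annual": forcings.Z_F_annual * 0.0})
        total0 = pop.total_abundance()
        for _ in range(24 * 10):
            step_population(pop, zero_f, quiet, deb_pars)
        assert pop.total_abundance() == pytest.approx(total0, rel=1e-12)

    def test_pure_fishing_decay_is_exponential(
            self, short_forcings, ibm_pars, deb_pars):
        only_f = ibm_pars.replace(M_egg=0.0, M_d=0.0, M_cm=0.0, M_flow=0.0,
                                  M_rain=0.0, e_age=0.0,
                                  spawn_window=(1, 1), spawn_T_min=99.0)
        pop = PopulationState.from_cohorts([_adult_cohort(n=1000.0, L=3.0)])
        z = float(short_forcings.Z_F_annual[0])
        days = 20
        for _ in range(24 * days):
            step_population(pop, short_forcings, only_f, deb_pars)
        assert pop.total_abundance() == pytest.approx(
            1000.0 * math.exp(-z * days), rel=1e-9)

    def test_forcing_gap_reported(self, short_forcings, ibm_pars, deb_pars):
        pop = PopulationState.from_cohorts([_adult_cohort()])
        pop.t = 5000.0  # outside the 2-year window
        with pytest.raises(ValueError, match="forcing"):
            step_population(pop, short_forcings, ibm_pars, deb_pars)

    def test_scalar_and_engine_survival_agree(
            self, short_forcings, ibm_pars, deb_pars):
        """One engine step must multiply abundance by the same exponential
        factor as the per-cohort apply_survival operation."""
        pop = PopulationState.from_cohorts([_adult_cohort(n=1000.0, L=3.0)])
        B = fish_density(pop, ibm_pars, deb_pars)
        flow = float(short_forcings.flow_index_annual()[0])
        rain = float(short_forcings.rain_index_annual()[0])
        expected = apply_survival(
            _adult_cohort(n=1000.0, L=3.0),
            Z_F=float(short_forcings.Z_F_annual[0]),
            Z_B=background_mortality(flow, rain, ibm_pars),
            Z_D=density_mortality(B, ibm_pars),
            Z_age=ageing_mortality(400.0, ibm_pars),
            Z_egg=0.0, dt=1.0 / 24.0)
        step_population(pop, short_forcings, ibm_pars, deb_pars)
        assert pop.cols["n"][0] == pytest.approx(expected.n, rel=1e-12)


@pytest.fixture(scope="module")
def one_year(ibm_pars, deb_pars):
    cfg = ForcingConfig(years=1)
    forc = synthesize_forcings(cfg, seed=11)
    return run_simulation(forc, ibm_pars, deb_pars, spin_up_years=0.5)


class TestRunSimulation:
    def test_records_daily_with_spinup_flag(self, one_year):
        # 365 daily records plus the closing state of the run
        assert len(one_year) == 366
        assert one_year["spin_up"].iloc[0]
        assert not one_year["spin_up"].iloc[-1]

    def test_population_persists_and_reproduces(self, one_year):
        assert one_year["total_abundance"].iloc[-1] > 0
        assert one_year["n_egg"].max() > 0

    def test_identical_seed_bitwise_reproducible(self, ibm_pars, deb_pars):
        cfg = ForcingConfig(years=1)
        a = run_simulation(synthesize_forcings(cfg, seed=5), ibm_pars,
                           deb_pars)
        b = run_simulation(synthesize_forcings(cfg, seed=5), ibm_pars,
                           deb_pars)
        assert a.equals(b)

    def test_extinction_logs_warning_and_writes_full_output(
            self, ibm_pars, deb_pars, caplog):
        """Under extreme fishing the run keeps emitting records to the end
        of the window, with zeros once the stock is gone."""
        import logging
        cfg = ForcingConfig(years=1, Z_F_base=0.5)  # annihilating effort
        forc = synthesize_forcings(cfg, seed=3)
        with caplog.at_level(logging.WARNING, logger="debibm.population"):
            frame = run_simulation(forc, ibm_pars, deb_pars,
                                   spin_up_years=0.0)
        assert len(frame) == 366
        assert frame["total_abundance"].iloc[-1] == 0.0
        assert any("extinct" in r.message for r in caplog.records)

    def test_seeding_reaches_expected_stages(self, deb_pars):
        cohorts = seed_cohorts(deb_pars, ages_years=(0.5, 1.5),
                               abundances=(100.0, 10.0))
        stages = {c.stage for c in cohorts}
        assert Stage.JUVENILE in stages
        assert Stage.FEMALE in stages and Stage.MALE in stages
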