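"""Cohort micro-simulation: determinism, conservation, CRN, closed-form checks."""

import numpy as np
import pytest

import bcscreen as bc
from bcscreen import natural_history as nh
from bcscreen.screening import StrategySpec
from bcscreen.synthetic import MAX_AGE, LifeTable


def cohort_at_40(n, seed=1):
    return bc.Cohort(entry_ages=np.full(n, 40, dtype=np.int16), seed=seed)


def settings(n, seed=1, **kw):
    return bc.SimulationSettings(n_individuals=n, master_seed=seed, **kw)


@pytest.fixture(scope="module")
def zero_incidence():
    return bc.IncidenceCurve(ages=np.arange(0, MAX_AGE + 1), incidence=np.zeros(MAX_AGE + 1))


@pytest.fixture(scope="module")
def no_screening():
    return StrategySpec(id="none", label="no screening", schedule=[],
                        participation_source="fixed", participation=0.0)


class TestDeterminism:
    def test_identical_runs(self, params, life_table, incidence, strategies):
        cohort = cohort_at_40(2_000)
        a = bc.run_strategy(cohort, strategies["B"], params, life_table, incidence, settings(2_000))
        b = bc.run_strategy(cohort, strategies["B"], params, life_table, incidence, settings(2_000))
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)
        assert a.event_counts == b.event_counts

    def test_seed_changes_outcome(self, params, life_table, incidence, strategies):
        cohort = cohort_at_40(2_000)
        a = bc.run_strategy(cohort, strategies["B"], params, life_table, incidence, settings(2_000, seed=1))
        b = bc.run_strategy(cohort, strategies["B"], params, life_table, incidence, settings(2_000, seed=2))
        assert not np.array_equal(a.costs, b.costs)

    def test_single_woman_trajectory_reproducible(self, params, life_table, incidence, strategies):
        t1 = bc.simulate_individual(40, strategies["F"], params, life_table, incidence, seed=11)
        t2 = bc.simulate_individual(40, strategies["F"], params, life_table, incidence, seed=11)
        assert t1.discounted_cost == t2.discounted_cost
        assert t1.discounted_qaly == t2.discounted_qaly


class TestDegenerateInputs:
    def test_certain_death_accrues_half_cycle(self, params, zero_incidence, no_screening):
        q = np.ones(MAX_AGE + 1)
        lethal = LifeTable(ages=np.arange(MAX_AGE + 1), q=q)
        cohort = cohort_at_40(500)
        res = bc.run_strategy(cohort, no_screening, params, lethal, zero_incidence, settings(500))
        np.testing.assert_allclose(res.life_years, 0.5)
        # half a cycle of healthy utility, discounted at mid-cycle
        expected = 0.5 * 0.800 * 1.05 ** -0.5
        np.testing.assert_allclose(res.qalys, expected, rtol=1e-12)
        assert res.mean_cost == 0.0

    def test_disease_off_qaly_equals_lifespan(self, params, life_table, zero_incidence, no_screening):
        """With utility 1 and rate 0, discounted QALY is the realized lifespan."""
        ps = bc.load_parameters({
            "econ": {"discount_rate": {"point_estimate": 0.0}},
            "utilities": {"healthy": {"point_estimate": 1.0}},
        })
        cohort = cohort_at_40(2_000)
        res = bc.run_strategy(cohort, no_screening, ps, life_table, zero_incidence, settings(2_000))
        np.testing.assert_allclose(res.qalys, res.life_years, rtol=1e-12)


class TestClosedFormCost:
    def test_usual_care_screening_cost(self, params, zero_incidence):
        """Disease off, immortal until closure, rate 0: expected cost is
        participation x (SFM + visit) per offered year (ages 40-69)."""
        q = np.zeros(MAX_AGE + 1)
        q[-1] = 1.0
        immortal = LifeTable(ages=np.arange(MAX_AGE + 1), q=q)
        ps = bc.load_parameters({
            "econ": {"discount_rate": {"point_estimate": 0.0}},
            "test_performance": {
                "recall_rate": {m: {r: {"family": "point", "point_estimate": 0.0}
                                    for r in ("prevalence", "incidence")}
                                for m in ("SFM", "FFDM")}},
        })
        n = 4_000
        strategy = StrategySpec(id="A", schedule=[], participation_source="opportunistic")
        res = bc.run_strategy(cohort_at_40(n), strategy, ps, immortal, zero_incidence, settings(n))
        expected = 30 * 0.18 * (45 + 10)  # 30 offered years
        se = res.costs.std(ddof=1) / np.sqrt(n)
        assert abs(res.mean_cost - expected) < 3 * se

    def test_se_shrinks_as_root_n(self, params, life_table, incidence, strategies):
        small = bc.run_strategy(cohort_at_40(2_000), strategies["A"], params,
                                life_table, incidence, settings(2_000))
        large = bc.run_strategy(cohort_at_40(8_000, seed=2), strategies["A"], params,
                                life_table, incidence, settings(8_000, seed=2))
        ratio = small.se_qaly / large.se_qaly
        assert 1.5 < ratio < 2.6  # expect ~2 with MC noise


class TestCommonRandomNumbers:
    def test_identical_strategies_identical_results(self, params, life_table, incidence, strategies):
        clone = strategies["B"].model_copy(update={"id": "B"})
        cohort = cohort_at_40(3_000)
        res = bc.run_all_strategies(cohort, [strategies["B"], clone], params,
                                    life_table, incidence, settings(3_000))
        np.testing.assert_array_equal(res[0].costs, res[1].costs)
        np.testing.assert_array_equal(res[0].qalys, res[1].qalys)

    def test_crn_reduces_paired_variance(self, params, life_table, incidence, strategies):
        n = 10_000
        cohort = cohort_at_40(n)
        pair = [strategies["A"], strategies["B"]]
        on = bc.run_all_strategies(cohort, pair, params, life_table, incidence,
                                   settings(n, common_random_numbers=True))
        off = bc.run_all_strategies(cohort, pair, params, life_table, incidence,
                                    settings(n, common_random_numbers=False))
        var_on = np.var(on[1].qalys - on[0].qalys)
        var_off = np.var(off[1].qalys - off[0].qalys)
        assert var_off / var_on > 1.0

    def test_crn_off_still_deterministic(self, params, life_table, incidence, strategies):
        cohort = cohort_at_40(1_000)
        a = bc.run_strategy(cohort, strategies["C"], params, life_table, incidence,
                            settings(1_000, common_random_numbers=False))
        b = bc.run_strategy(cohort, strategies["C"], params, life_table, incidence,
                            settings(1_000, common_random_numbers=False))
        np.testing.assert_array_equal(a.qalys, b.qalys)


class TestConservationAndTraces:
    def test_every_woman_ends_absorbed(self, params, life_table, incidence, strategies):
        n = 5_000
        res = bc.run_strategy(cohort_at_40(n), strategies["B"], params,
                              life_table, incidence, settings(n))
        c = res.event_counts
        assert c["bc_deaths"] + c["other_deaths"] == n
        assert res.life_years.max() <= MAX_AGE - 40 + 1

    def test_workup_counts_internally_consistent(self, params, life_table, incidence, strategies):
        n = 20_000
        res = bc.run_strategy(cohort_at_40(n), strategies["D"], params,
                              life_table, incidence, settings(n))
        c = res.event_counts
        assert c["fna"] + c["surgical_biopsies"] <= c["recalls"]
        assert c["false_positive_recalls"] <= c["recalls"]
        assert c["screen_detected"] <= c["cancers"]
        assert sum(c["cancers_by_stage"].values()) == c["cancers"]

    def test_no_screens_outside_40_69(self, params, life_table, incidence, strategies):
        n = 300
        res = bc.run_strategy(cohort_at_40(n), strategies["B"], params, life_table,
                              incidence, settings(n, trace=True))
        assert res.cycle_summary is not None
        traj = bc.simulate_individual(45, strategies["B"], params, life_table, incidence, seed=4)
        assert traj.entry_age == 45

    def test_screening_advances_stage_at_diagnosis(self, params, life_table, incidence, strategies):
        """With CRN, screen-era diagnoses fall at earlier stages than usual care."""
        n = 50_000
        cohort = cohort_at_40(n)
        res = bc.run_all_strategies(cohort, [strategies["A"], strategies["B"]],
                                    params, life_table, incidence, settings(n))
        def mean_stage(r):
            byst = r.event_counts["cancers_by_stage"]
            w = np.array([byst[k] for k in ("DCIS", "S1", "S2", "S3", "S4")], dtype=float)
            return np.average(np.arange(5), weights=w)
        assert mean_stage(res[1]) < mean_stage(res[0])

    def test_qaly_bounded_by_discounted_life_expectancy(self, params, life_table, incidence, strategies):
        n = 3_000
        res = bc.run_strategy(cohort_at_40(n), strategies["C"], params,
                              life_table, incidence, settings(n))
        assert res.mean_qaly <= res.mean_life_years  # utilities <= 1, discount >= 0

    def test_entry_age_contract(self, params, life_table, incidence, strategies):
        with pytest.raises(ValueError):
            bc.simulate_individual(39, strategies["B"], params, life_table, incidence)


class TestLifeExpectancyHarness:
    def test_disease_free_cohort_matches_analytic_e40(self, life_table):
        report = bc.validate_life_expectancy(life_table, n=30_000, seed=5)
        assert abs(report["z"]) < 3.0
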