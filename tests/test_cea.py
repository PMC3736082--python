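"""Dominance, frontier ICERs, NMB, CEAC and sensitivity-analysis layers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import bcscreen as bc
from bcscreen.cea import (
    UndefinedICER,
    ceac_from_draws,
    efficiency_frontier,
    icer,
    nmb,
    one_way_sa,
    run_psa,
    set_point,
)
from bcscreen.reference import REFERENCE_BASE_CASE


def brute_force_frontier(entries):
    """Independent oracle: a strategy is on the frontier iff no single
    strategy weakly dominates it and no blend of two strategies achieves
    at least its QALYs at lower cost."""
    keep = []
    for i, (si, ci, qi) in enumerate(entries):
        dominated = False
        for j, (_, cj, qj) in enumerate(entries):
            if j != i and cj <= ci and qj >= qi and (cj < ci or qj > qi):
                dominated = True
        for j, (_, cj, qj) in enumerate(entries):
            for k, (_, ck, qk) in enumerate(entries):
                if i in (j, k) or j == k or not qj < qi < qk:
                    continue
                lam = (qi - qj) / (qk - qj)
                if cj + lam * (ck - cj) < ci:
                    dominated = True
        if not dominated:
            keep.append(si)
    return set(keep)


class TestICER:
    def test_reference_arithmetic(self):
        value = icer((2075, 14.498), (2125, 14.532))
        assert value == pytest.approx(50 / 0.034)

    def test_simple_case(self):
        assert icer((0, 1), (10, 2)) == 10

    def test_equal_qalys_undefined(self):
        with pytest.raises(UndefinedICER):
            icer((0, 1), (10, 1))


class TestFrontier:
    def test_published_base_case_ordering(self):
        res = efficiency_frontier(REFERENCE_BASE_CASE)
        assert res.frontier == ["A", "C", "B", "F"]
        assert res.order_of("A") == 1
        assert res.order_of("C") == 2
        assert res.order_of("B") == 3
        assert res.order_of("F") == 4
        flags = dict(zip(res.table["strategy"], res.table["dominated"]))
        assert flags["D"] == "simple" and flags["E"] == "simple"
        assert flags["G"] == "extended"

    def test_frontier_icers_strictly_increase(self):
        res = efficiency_frontier(REFERENCE_BASE_CASE)
        chain = [res.icers()[s] for s in res.frontier[1:]]
        assert all(a < b for a, b in zip(chain, chain[1:]))

    def test_single_strategy(self):
        res = efficiency_frontier([("only", 100.0, 1.0)])
        assert res.frontier == ["only"]
        assert res.order_of("only") == 1
        assert res.icers() == {}

    def test_duplicate_pairs_tie_broken_deterministically(self):
        res = efficiency_frontier([("x", 10.0, 1.0), ("y", 10.0, 1.0)])
        assert res.frontier == ["x"]
        flags = dict(zip(res.table["strategy"], res.table["dominated"]))
        assert flags["y"] == "simple"

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(424242)
        for trial in range(1_000):
            k = rng.integers(2, 9)
            entries = [(f"s{i}", float(rng.uniform(0, 1000)), float(rng.uniform(10, 20)))
                       for i in range(k)]
            res = efficiency_frontier(entries)
            assert set(res.frontier) == brute_force_frontier(entries), entries

    @hyp_settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1e6), st.floats(0, 50)), min_size=1, max_size=8))
    def test_oracle_equivalence_property(self, pairs):
        entries = [(f"s{i}", c, q) for i, (c, q) in enumerate(pairs)]
        res = efficiency_frontier(entries)
        # weaker check under arbitrary ties: frontier is a subset of the
        # oracle's non-dominated set and is itself a strictly increasing chain
        fr = res.table[res.table["dominated"] == "none"].sort_values("cost")
        costs, qalys = fr["cost"].to_numpy(), fr["qaly"].to_numpy()
        assert np.all(np.diff(costs) >= 0) and np.all(np.diff(qalys) > 0) or len(fr) == 1

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(7)
        entries = [(f"s{i}", float(rng.uniform(0, 100)), float(rng.uniform(0, 10)))
                   for i in range(7)]
        res1 = efficiency_frontier(entries)
        res2 = efficiency_frontier(list(reversed(entries)))
        assert res1.frontier == res2.frontier

    def test_currency_rescaling_scales_icers_linearly(self):
        res_brl = efficiency_frontier(REFERENCE_BASE_CASE)
        usd = [(s, c / 1.67, q) for s, c, q in REFERENCE_BASE_CASE]
        res_usd = efficiency_frontier(usd)
        assert res_usd.frontier == res_brl.frontier
        for s, v in res_brl.icers().items():
            assert res_usd.icers()[s] == pytest.approx(v / 1.67)

    def test_accepts_dataframe_and_results(self):
        df = pd.DataFrame([{"strategy": s, "cost": c, "qaly": q}
                           for s, c, q in REFERENCE_BASE_CASE])
        assert efficiency_frontier(df).frontier == ["A", "C", "B", "F"]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            efficiency_frontier([("a", np.nan, 1.0)])


class TestNMB:
    def test_closed_forms(self):
        assert nmb(0, 1, 50_000) == 50_000
        assert nmb(123.0, 1.0, 0) == -123.0

    def test_argmax_at_huge_wtp_is_max_qaly(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            entries = [(i, rng.uniform(0, 1e4), rng.uniform(0, 30)) for i in range(6)]
            best = max(entries, key=lambda e: nmb(e[1], e[2], 1e12))
            assert best[2] == max(e[2] for e in entries)


class TestCEAC:
    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(12)
        costs = rng.uniform(0, 1000, size=(200, 4))
        qalys = rng.uniform(10, 20, size=(200, 4))
        ceac = ceac_from_draws(list("wxyz"), costs, qalys, [0, 10_000, 50_000])
        sums = ceac.groupby("wtp")["probability"].sum()
        assert np.allclose(sums, 1.0)

    def test_point_mass_psa_gives_step_function(self):
        # degenerate draws: every draw identical -> probabilities are 0/1
        costs = np.tile([100.0, 200.0, 400.0], (50, 1))
        qalys = np.tile([1.0, 1.02, 1.03], (50, 1))
        grid = np.arange(0, 40_001, 1_000.0)
        grid = grid[~np.isin(grid, [5_000.0, 20_000.0])]  # exact crossovers tie 50/50
        ceac = ceac_from_draws(["a", "b", "c"], costs, qalys, grid)
        assert set(np.round(ceac["probability"], 12)) <= {0.0, 1.0}
        # and the winner switches at the closed-form NMB crossovers
        wide = ceac.pivot(index="wtp", columns="strategy", values="probability")
        crossover_ab = (200 - 100) / 0.02  # 5,000
        crossover_bc = (400 - 200) / 0.01  # 20,000
        assert wide.loc[4_000, "a"] == 1.0
        assert wide.loc[6_000, "b"] == 1.0
        assert wide.loc[19_000, "b"] == 1.0
        assert wide.loc[21_000, "c"] == 1.0
        assert crossover_ab < 6_000 and crossover_bc < 21_000

    def test_exact_ties_split_equally(self):
        costs = np.tile([100.0, 100.0], (10, 1))
        qalys = np.tile([1.0, 1.0], (10, 1))
        ceac = ceac_from_draws(["a", "b"], costs, qalys, [10_000])
        assert np.allclose(ceac["probability"], 0.5)

    def test_matches_naive_argmax_recount(self):
        rng = np.random.default_rng(31)
        costs = rng.uniform(0, 1000, size=(500, 5))
        qalys = rng.uniform(10, 20, size=(500, 5))
        wtp = 30_000.0
        ceac = ceac_from_draws(list("abcde"), costs, qalys, [wtp])
        naive = np.bincount(np.argmax(wtp * qalys - costs, axis=1), minlength=5) / 500
        got = ceac.sort_values("strategy")["probability"].to_numpy()
        assert np.allclose(got, naive)


class TestPSA:
    def test_small_psa_end_to_end(self, params, life_table, incidence, strategies):
        cohort = bc.make_cohort(300, bc.single_age_scenario(40), seed=3)
        subset = [strategies["A"], strategies["C"], strategies["B"]]
        out = run_psa(params, cohort, subset, life_table, incidence,
                      n_draws=5, seed=21, inner_n=300, wtp_grid=[0, 20_000, 60_000])
        assert out.costs.shape == (5, 3)
        assert np.all(np.isfinite(out.costs)) and np.all(np.isfinite(out.qalys))
        sums = out.ceac.groupby("wtp")["probability"].sum()
        assert np.allclose(sums, 1.0)
        # draws genuinely vary with the sampled parameters
        assert out.costs.std(axis=0).max() > 0

    def test_psa_reproducible(self, params, life_table, incidence, strategies):
        cohort = bc.make_cohort(200, bc.single_age_scenario(40), seed=3)
        subset = [strategies["A"], strategies["B"]]
        kw = dict(n_draws=3, seed=5, inner_n=200, wtp_grid=[10_000])
        a = run_psa(params, cohort, subset, life_table, incidence, **kw)
        b = run_psa(params, cohort, subset, life_table, incidence, **kw)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)


class TestOneWaySA:
    def test_zero_width_grid_reproduces_base_case(self, params, life_table, incidence, strategies):
        cohort = bc.Cohort(entry_ages=np.full(1_000, 40, dtype=np.int16), seed=1)
        sim = bc.SimulationSettings(n_individuals=1_000, master_seed=1)
        subset = [strategies["A"], strategies["C"]]
        sa = one_way_sa(params, "coverage.opportunistic", cohort, subset,
                        life_table, incidence, sim, values=[0.18])
        base = bc.run_all_strategies(cohort, subset, params, life_table, incidence, sim)
        base_costs = {r.strategy_id: r.mean_cost for r in base}
        for _, row in sa.iterrows():
            assert row["cost"] == pytest.approx(base_costs[row["strategy"]])

    def test_discount_rate_raises_screening_icer(self, params, life_table, incidence, strategies):
        """Benefits of screening arrive late, so a higher discount rate
        weakly increases the ICER of annual SFM versus usual care."""
        cohort = bc.Cohort(entry_ages=np.full(20_000, 40, dtype=np.int16), seed=2)
        sim = bc.SimulationSettings(n_individuals=20_000, master_seed=2)
        icers = []
        for r in (0.0, 0.05, 0.10):
            ps_r = set_point(params, "econ.discount_rate", r)
            res = bc.run_all_strategies(cohort, [strategies["A"], strategies["B"]],
                                        ps_r, life_table, incidence, sim)
            icers.append(icer((res[0].mean_cost, res[0].mean_qaly),
                              (res[1].mean_cost, res[1].mean_qaly)))
        assert icers[0] < icers[1] < icers[2]

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(KeyError):
            set_point(params, "econ.currency", 1.0)

    def test_out_of_range_value_rejected(self, params):
        with pytest.raises(ValueError):
            set_point(params, "coverage.opportunistic", 0.5)
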