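"""Cost-effectiveness layer: dominance, frontier, ICERs, one-way SA, PSA, CEAC.

Given mean discounted cost and QALY per strategy, the efficiency
frontier is built by sorting in ascending cost, removing simply
dominated strategies (costlier and no more effective than another),
then removing extendedly dominated ones until the incremental
cost-effectiveness ratios (ICERs) along the frontier strictly increase.
Probabilistic sensitivity analysis resamples the full parameter vector,
reruns all strategies per draw with common random numbers, and summarises
decision uncertainty as cost-effectiveness acceptability curves (CEACs):
the probability each strategy has the highest net monetary benefit
(NMB = WTP x QALY - cost) at each willingness-to-pay (WTP) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SimulationSettings, StrategyResult, run_all_strategies
from .parameters import ParameterSet, sample_psa_draw
from .screening import StrategySpec
from .synthetic import Cohort, IncidenceCurve, LifeTable


class UndefinedICER(ValueError):
    """Raised when an ICER is requested between equal-QALY strategies."""


def icer(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Incremental cost-effectiveness ratio of b versus a: dCost / dQALY."""
    d_cost = b[0] - a[0]
    d_qaly = b[1] - a[1]
    if d_qaly == 0.0:
        raise UndefinedICER("strategies have equal QALYs; the ICER is undefined")
    return d_cost / d_qaly


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay `wtp` per QALY."""
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    return wtp * qaly - cost


@dataclass
class CEAResult:
    """Frontier ordering, dominance flags and ICERs for a strategy set."""

    table: pd.DataFrame  # strategy, cost, qaly, dominated, order, icer
    frontier: list[str]

    def order_of(self, strategy_id: str):
        row = self.table.loc[self.table["strategy"] == strategy_id]
        if row.empty:
            raise KeyError(strategy_id)
        v = row["order"].iloc[0]
        return None if pd.isna(v) else int(v)

    def icers(self) -> dict[str, float]:
        out = {}
        for _, row in self.table.iterrows():
            if not pd.isna(row["icer"]):
                out[row["strategy"]] = float(row["icer"])
        return out


def _as_entries(cea_input) -> list[tuple[str, float, float]]:
    if isinstance(cea_input, pd.DataFrame):
        return [(str(r["strategy"]), float(r["cost"]), float(r["qaly"]))
                for _, r in cea_input.reset_index().iterrows()]
    entries = []
    for item in cea_input:
        if isinstance(item, StrategyResult):
            entries.append((item.strategy_id, item.mean_cost, item.mean_qaly))
        else:
            sid, cost, qaly = item
            entries.append((str(sid), float(cost), float(qaly)))
    return entries


def efficiency_frontier(cea_input) -> CEAResult:
    """Simple and extended dominance elimination with frontier ICERs.

    Accepts a list of (id, cost, qaly) tuples, StrategyResults, or a
    DataFrame with strategy/cost/qaly columns.  Ties are broken by
    sorting on (cost, -qaly, id); an exact duplicate of an earlier
    (cost, qaly) pair is flagged as simply dominated.  Invariant,
    asserted on every call: frontier ICERs strictly increase.
    """
    entries = _as_entries(cea_input)
    if not entries:
        raise ValueError("need at least one strategy")
    for sid, cost, qaly in entries:
        if not (np.isfinite(cost) and np.isfinite(qaly)):
            raise ValueError(f"non-finite cost/QALY for strategy {sid}")

    order = sorted(range(len(entries)), key=lambda i: (entries[i][1], -entries[i][2], entries[i][0]))
    dominated = {i: "none" for i in range(len(entries))}

    # simple dominance (weak dominance for exact duplicates, earlier sort wins)
    for pos, i in enumerate(order):
        ci, qi = entries[i][1], entries[i][2]
        for pos2, j in enumerate(order):
            if i == j:
                continue
            cj, qj = entries[j][1], entries[j][2]
            strict = (cj < ci) or (qj > qi)
            duplicate = (cj == ci) and (qj == qi) and pos2 < pos
            if (cj <= ci and qj >= qi and strict) or duplicate:
                dominated[i] = "simple"
                break

    candidates = [i for i in order if dominated[i] == "none"]

    # extended dominance: enforce strictly increasing frontier ICERs
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for k in range(1, len(candidates) - 1):
            prev_, mid, nxt = candidates[k - 1], candidates[k], candidates[k + 1]
            icer_mid = icer(entries[prev_][1:], entries[mid][1:])
            icer_nxt = icer(entries[mid][1:], entries[nxt][1:])
            if icer_nxt <= icer_mid:
                dominated[mid] = "extended"
                del candidates[k]
                changed = True
                break

    rows = []
    frontier_ids = []
    icer_by_idx: dict[int, float] = {}
    for rank, idx in enumerate(candidates):
        frontier_ids.append(entries[idx][0])
        if rank > 0:
            icer_by_idx[idx] = icer(entries[candidates[rank - 1]][1:], entries[idx][1:])
    chain = [icer_by_idx[i] for i in candidates if i in icer_by_idx]
    assert all(a < b for a, b in zip(chain, chain[1:])), "frontier ICERs must strictly increase"

    rank_of = {idx: r + 1 for r, idx in enumerate(candidates)}
    for i, (sid, cost, qaly) in enumerate(entries):
        rows.append({
            "strategy": sid, "cost": cost, "qaly": qaly,
            "dominated": dominated[i],
            "order": rank_of.get(i, np.nan),
            "icer": icer_by_idx.get(i, np.nan),
        })
    table = pd.DataFrame(rows)
    return CEAResult(table=table, frontier=frontier_ids)


# ---------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------


def set_point(ps: ParameterSet, path: str, value: float) -> ParameterSet:
    """Copy of `ps` with the parameter at dotted `path` fixed at `value`."""
    raw = ps.model_dump()
    node = raw
    parts = path.split(".")
    for p in parts[:-1]:
        node = node[p]
    spec = node[parts[-1]]
    if not (isinstance(spec, dict) and "point_estimate" in spec):
        raise KeyError(f"{path} is not a distribution-valued parameter")
    lo, hi = spec.get("low"), spec.get("high")
    spec.update(point_estimate=float(value), family="point",
                low=None, high=None, alpha=None, beta=None,
                mu=None, sigma=None, rate=None, sd=None)
    if lo is not None and hi is not None and not (lo <= value <= hi):
        raise ValueError(f"{path}={value} outside its plausible range [{lo}, {hi}]")
    return ParameterSet.model_validate(raw)


def parameter_range(ps: ParameterSet, path: str) -> tuple[float, float]:
    raw = ps.model_dump()
    node = raw
    for p in path.split("."):
        node = node[p]
    if node.get("low") is None or node.get("high") is None:
        raise ValueError(f"parameter {path} has no printed range")
    return float(node["low"]), float(node["high"])


def one_way_sa(
    ps: ParameterSet,
    param_path: str,
    cohort: Cohort,
    strategies: dict[str, StrategySpec] | list[StrategySpec],
    life_table: LifeTable,
    incidence: IncidenceCurve,
    settings: SimulationSettings,
    values=None,
    n_points: int = 3,
) -> pd.DataFrame:
    """Rerun the base case across a grid of one parameter (CRN throughout).

    ``values`` defaults to a grid over the parameter's printed min..max;
    a zero-width range yields a single row identical to the base case.
    Returns one row per (value, strategy) with frontier flags and ICERs.
    """
    if values is None:
        lo, hi = parameter_range(ps, param_path)
        values = [lo] if lo == hi else list(np.linspace(lo, hi, n_points))
    rows = []
    for v in values:
        ps_v = set_point(ps, param_path, float(v))
        results = run_all_strategies(cohort, strategies, ps_v, life_table, incidence, settings)
        cea = efficiency_frontier(results)
        for _, r in cea.table.iterrows():
            rows.append({"parameter": param_path, "value": float(v), **r.to_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------


@dataclass
class PSAOutput:
    """Joint cost/QALY draws per strategy plus acceptability curves."""

    strategy_ids: list[str]
    costs: np.ndarray  # (n_draws, k)
    qalys: np.ndarray  # (n_draws, k)
    wtp_grid: np.ndarray
    ceac: pd.DataFrame = field(repr=False)  # wtp, strategy, probability

    def ce_plane(self) -> pd.DataFrame:
        rows = []
        for j, sid in enumerate(self.strategy_ids):
            rows.append(pd.DataFrame({
                "strategy": sid, "cost": self.costs[:, j], "qaly": self.qalys[:, j]}))
        return pd.concat(rows, ignore_index=True)


def ceac_from_draws(strategy_ids, costs: np.ndarray, qalys: np.ndarray,
                    wtp_grid) -> pd.DataFrame:
    """P(highest NMB) per strategy per WTP; exact ties split equally."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    n_draws, k = costs.shape
    rows = []
    for wtp in wtp_grid:
        benefit = wtp * qalys - costs
        best = benefit.max(axis=1, keepdims=True)
        is_best = benefit == best
        share = is_best / is_best.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for j, sid in enumerate(strategy_ids):
            rows.append({"wtp": float(wtp), "strategy": sid, "probability": float(probs[j])})
    return pd.DataFrame(rows)


def run_psa(
    ps: ParameterSet,
    cohort: Cohort,
    strategies: dict[str, StrategySpec] | list[StrategySpec],
    life_table: LifeTable,
    incidence: IncidenceCurve,
    n_draws: int = 10_000,
    seed: int = 0,
    inner_n: int = 2_000,
    wtp_grid=None,
    settings: SimulationSettings | None = None,
) -> PSAOutput:
    """Monte Carlo PSA: parameter draw -> all strategies -> (cost, QALY).

    Each draw samples the full parameter vector, then reruns every
    strategy on a reduced inner cohort (default 2,000 women) with common
    random numbers shared across draws and strategies, so between-draw
    variation reflects parameter uncertainty.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    specs = list(strategies.values()) if isinstance(strategies, dict) else list(strategies)
    ids = [s.id for s in specs]
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 120_001.0, 5_000.0)
    inner = Cohort(entry_ages=cohort.entry_ages[:inner_n] if cohort.n >= inner_n
                   else cohort.entry_ages, seed=cohort.seed)
    sim = settings or SimulationSettings(n_individuals=inner.n, master_seed=seed)
    costs = np.zeros((n_draws, len(specs)))
    qalys = np.zeros((n_draws, len(specs)))
    for d in range(n_draws):
        draw_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(d,)).generate_state(1)[0] % (2**31))
        ps_d = sample_psa_draw(ps, draw_seed)
        results = run_all_strategies(inner, specs, ps_d, life_table, incidence, sim)
        for j, r in enumerate(results):
            costs[d, j] = r.mean_cost
            qalys[d, j] = r.mean_qaly
    ceac = ceac_from_draws(ids, costs, qalys, wtp_grid)
    return PSAOutput(strategy_ids=ids, costs=costs, qalys=qalys,
                     wtp_grid=np.asarray(wtp_grid, dtype=float), ceac=ceac)


# ---------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------


def plot_ce_plane(psa: PSAOutput, ax=None):
    """Scatter of PSA (QALY, cost) draws per strategy."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for j, sid in enumerate(psa.strategy_ids):
        ax.scatter(psa.qalys[:, j], psa.costs[:, j], s=4, alpha=0.4, label=sid)
    ax.set_xlabel("discounted QALYs")
    ax.set_ylabel("discounted cost (R$)")
    ax.legend(title="strategy", fontsize="small")
    return ax


def plot_ceac(psa: PSAOutput, ax=None):
    """Cost-effectiveness acceptability curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for sid in psa.strategy_ids:
        sub = psa.ceac[psa.ceac["strategy"] == sid]
        ax.plot(sub["wtp"], sub["probability"], label=sid)
    ax.set_xlabel("willingness to pay (R$/QALY)")
    ax.set_ylabel("P(highest net monetary benefit)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(title="strategy", fontsize="small")
    return ax
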