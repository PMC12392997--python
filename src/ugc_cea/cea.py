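"""Cost-utility comparison: CUR, ICUR, dominance and the efficient frontier.

Strategies are compared by their cost-utility ratio (CUR = cost/QALYs), by
pairwise incremental cost-utility ratios (ICUR = Δcost/ΔQALY), and along the
efficient frontier: strategies sorted by cost with strongly dominated ones
(more costly, no more effective) removed, then extended-dominated ones
(neighbour ICUR not increasing) removed iteratively until the ICURs of
adjacent frontier members strictly increase.  A strategy is classed highly
cost-effective when its ICUR against the relevant comparator falls below the
willingness-to-pay threshold of one per-capita GDP (¥70,653/QALY); 2x and 3x
multiples are conventional context thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class StrategyOutcome:
    """One (cost, QALY) point on the cost-effectiveness plane."""

    code: str
    cost: float    # CNY
    qalys: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cost) and math.isfinite(self.qalys)):
            raise ValueError(f"{self.code}: non-finite outcome")
        if self.cost < 0:
            raise ValueError(f"{self.code}: negative cost")
        if self.qalys <= 0:
            raise ValueError(f"{self.code}: non-positive QALYs")


def cost_utility_ratio(o: StrategyOutcome) -> float:
    """CUR in CNY per QALY."""
    if o.qalys <= 0:
        raise ValueError("CUR undefined for non-positive QALYs")
    return o.cost / o.qalys


@dataclass(frozen=True)
class IncrementalResult:
    delta_cost: float
    delta_qalys: float
    icur: float | None      # CNY/QALY; None when a dominance verdict applies
    verdict: str            # "icur" | "dominates" | "dominated" | "tie"


def incremental_ratio(a: StrategyOutcome, b: StrategyOutcome) -> IncrementalResult:
    """Incremental comparison of ``a`` against comparator ``b``.

    Returns a dominance verdict when the signs decide the comparison
    outright: ``a`` dominates when it is cheaper and at least as effective
    (or as cheap and strictly more effective), and vice versa.
    """
    dc = a.cost - b.cost
    dq = a.qalys - b.qalys
    if dc == 0.0 and dq == 0.0:
        return IncrementalResult(0.0, 0.0, None, "tie")
    if dc <= 0.0 and dq >= 0.0:
        return IncrementalResult(dc, dq, None, "dominates")
    if dc >= 0.0 and dq <= 0.0:
        return IncrementalResult(dc, dq, None, "dominated")
    return IncrementalResult(dc, dq, dc / dq, "icur")


STRONGLY_DOMINATED = "strongly-dominated"
EXTENDED_DOMINATED = "extended-dominated"


@dataclass
class FrontierEntry:
    outcome: StrategyOutcome
    cur: float
    delta_cost_vs_baseline: float | None = None
    delta_qalys_vs_baseline: float | None = None
    icur_vs_baseline: float | None = None
    delta_cost_vs_previous: float | None = None
    delta_qalys_vs_previous: float | None = None
    icur_vs_previous: float | None = None


@dataclass
class FrontierResult:
    """Ordered dominant strategies with incremental columns, plus the
    excluded strategies tagged by the dominance type that removed them."""

    frontier: list[FrontierEntry]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def codes(self) -> list[str]:
        return [e.outcome.code for e in self.frontier]

    def neighbor_icurs(self) -> list[float]:
        return [e.icur_vs_previous for e in self.frontier if e.icur_vs_previous is not None]


def _sort_key(o: StrategyOutcome):
    # ascending cost; cost ties keep the higher-QALY first, then lexicographic
    return (o.cost, -o.qalys, o.code)


def efficient_frontier(outcomes: list[StrategyOutcome],
                       baseline: str | None = None) -> FrontierResult:
    """Dominance screening over a set of strategy outcomes.

    Sort ascending by cost; drop strongly dominated points (>= cost and
    <= QALYs of another, at least one strict, with deterministic
    tie-breaking); then iteratively drop extended-dominated points until the
    ICURs between adjacent survivors strictly increase.
    """
    codes = [o.code for o in outcomes]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate strategy codes in outcome set")
    if len(outcomes) < 2:
        raise ValueError("need at least two outcomes to compare")

    ordered = sorted(outcomes, key=_sort_key)
    excluded: dict[str, str] = {}

    # strong dominance: after the cost sort, a point is dominated iff some
    # retained cheaper-or-tied point has at least as many QALYs
    survivors: list[StrategyOutcome] = []
    best_q = -math.inf
    for o in ordered:
        if o.qalys <= best_q:
            excluded[o.code] = STRONGLY_DOMINATED
        else:
            survivors.append(o)
            best_q = o.qalys

    # extended dominance: neighbour ICURs must strictly increase
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        icurs = [(survivors[k + 1].cost - survivors[k].cost)
                 / (survivors[k + 1].qalys - survivors[k].qalys)
                 for k in range(len(survivors) - 1)]
        for k in range(len(icurs) - 1):
            if icurs[k] >= icurs[k + 1]:
                excluded[survivors[k + 1].code] = EXTENDED_DOMINATED
                del survivors[k + 1]
                changed = True
                break

    base = None
    if baseline is not None:
        base = next((o for o in outcomes if o.code == baseline), None)
        if base is None:
            raise ValueError(f"baseline {baseline!r} not among outcomes")

    entries: list[FrontierEntry] = []
    prev: StrategyOutcome | None = None
    for o in survivors:
        e = FrontierEntry(outcome=o, cur=cost_utility_ratio(o))
        if base is not None and o.code != base.code:
            inc = incremental_ratio(o, base)
            e.delta_cost_vs_baseline = inc.delta_cost
            e.delta_qalys_vs_baseline = inc.delta_qalys
            e.icur_vs_baseline = inc.icur
        if prev is not None:
            inc = incremental_ratio(o, prev)
            e.delta_cost_vs_previous = inc.delta_cost
            e.delta_qalys_vs_previous = inc.delta_qalys
            e.icur_vs_previous = inc.icur
        entries.append(e)
        prev = o

    icurs = [e.icur_vs_previous for e in entries if e.icur_vs_previous is not None]
    assert all(x < y for x, y in zip(icurs, icurs[1:])), \
        "frontier ICURs must strictly increase"
    return FrontierResult(frontier=entries, excluded=excluded)


def net_monetary_benefit(o: StrategyOutcome, wtp: float,
                         baseline: StrategyOutcome) -> float:
    """NMB = λ·ΔQALY − Δcost against the designated baseline."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * (o.qalys - baseline.qalys) - (o.cost - baseline.cost)


def optimal_strategy(outcomes: list[StrategyOutcome], wtp: float,
                     baseline: StrategyOutcome) -> StrategyOutcome:
    """Argmax-NMB strategy at the given willingness-to-pay."""
    return max(outcomes, key=lambda o: (net_monetary_benefit(o, wtp, baseline), o.code))


def frontier_frame(result: FrontierResult):
    """Frontier as a table mirroring the published 10-column layout."""
    import pandas as pd
    rows = []
    for e in result.frontier:
        rows.append({
            "code": e.outcome.code,
            "cost_10k_cny": e.outcome.cost / 1e4,
            "qalys": e.outcome.qalys,
            "cur_cny_per_qaly": e.cur,
            "inc_cost_10k_vs_baseline": None if e.delta_cost_vs_baseline is None
                else e.delta_cost_vs_baseline / 1e4,
            "inc_qalys_vs_baseline": e.delta_qalys_vs_baseline,
            "icur_vs_baseline": e.icur_vs_baseline,
            "inc_cost_10k_vs_neighbor": None if e.delta_cost_vs_previous is None
                else e.delta_cost_vs_previous / 1e4,
            "inc_qalys_vs_neighbor": e.delta_qalys_vs_previous,
            "icur_vs_neighbor": e.icur_vs_previous,
        })
    return pd.DataFrame(rows)
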